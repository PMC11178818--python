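"""Synthetic generators: fixtures, planted fields, planted surfaces, and the
toy bone model."""

import numpy as np
import pytest

import bcdirect as bd
from bcdirect import fem
from bcdirect.kinematics import RingMotion, fit_ring_motion
from bcdirect.synthetic import SynthError, _ogrid_layout
from bcdirect.volume import total_vd

ZERO = RingMotion(w_bar=0.0, gamma_bar=0.0, phi_bar=0.0)


class TestMakeRWFixture:
    def test_default_counts(self, rw_fixture):
        ring, mesh = rw_fixture
        assert ring.n_triangles == 16
        assert len(mesh.quads) == 218 and len(mesh.triangles) == 436
        assert np.all(mesh.areas > 0)

    def test_small_ring(self):
        ring, _ = bd.make_rw_fixture(n_edge=6, n_quads=8)
        assert ring.n_triangles == 2

    def test_determinism(self):
        r1, m1 = bd.make_rw_fixture(seed=5, jitter=0.01)
        r2, m2 = bd.make_rw_fixture(seed=5, jitter=0.01)
        assert np.array_equal(r1.xy, r2.xy) and np.array_equal(m1.nodes, m2.nodes)
        r3, _ = bd.make_rw_fixture(seed=6, jitter=0.01)
        assert not np.array_equal(r1.xy, r3.xy)

    def test_unachievable_quad_count_warns_and_nears(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="bcdirect"):
            # 7 is not representable as ab + 2(a+b)L with L >= 1
            _, mesh = bd.make_rw_fixture(n_edge=6, n_quads=7)
        assert "cannot produce exactly" in caplog.text
        assert abs(len(mesh.quads) - 7) <= 2

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(SynthError):
            bd.make_rw_fixture(n_edge=47)

    def test_layout_search_exact_for_default(self):
        a, b, L = _ogrid_layout(218)
        assert a * b + 2 * (a + b) * L == 218


class TestMakeField:
    def test_piston_closed_form(self, rw_fixture):
        ring, mesh = rw_fixture
        truth = bd.FieldGroundTruth(ring_motion=ZERO, profile="piston", d=1.0)
        fld = bd.make_field(ring, mesh, truth)
        vd = total_vd(mesh, fld.membrane_wz, fit_ring_motion(ring, fld.ring_wz))
        assert vd.V == pytest.approx(truth.expected_vd(mesh), rel=1e-10)
        assert truth.expected_vd(mesh) == pytest.approx(mesh.total_area)

    def test_rigid_only_field(self, rw_fixture, rng):
        ring, mesh = rw_fixture
        planted = RingMotion(*(rng.normal(size=3) + 1j * rng.normal(size=3)))
        truth = bd.FieldGroundTruth(ring_motion=planted, profile="zero")
        fld = bd.make_field(ring, mesh, truth)
        got = fit_ring_motion(ring, fld.ring_wz)
        assert got.w_bar == pytest.approx(planted.w_bar, abs=1e-12)
        assert got.gamma_bar == pytest.approx(planted.gamma_bar, abs=1e-12)
        vd = total_vd(mesh, fld.membrane_wz, got)
        assert abs(vd.V) < 1e-10 * mesh.total_area * max(1.0, abs(planted.w_bar))

    def test_paraboloid_matches_subdivision_oracle(self, rw_fixture):
        from test_volume import subdivision_oracle

        ring, mesh = rw_fixture
        truth = bd.FieldGroundTruth(ring_motion=ZERO, profile="paraboloid", d=2 - 1j)
        assert truth.expected_vd(mesh) is None
        fld = bd.make_field(ring, mesh, truth)
        vd = total_vd(mesh, fld.membrane_wz, fit_ring_motion(ring, fld.ring_wz))
        assert vd.V == pytest.approx(subdivision_oracle(mesh, fld.membrane_wz), rel=1e-10)

    def test_noisy_ring_recovery_averages_down(self):
        """With near-equilateral fit triangles, nodal noise of std sigma leaves
        the 48-node averaged translation within ~3 sigma/sqrt(48) of truth."""
        ring, mesh = bd.make_rw_fixture(grouping="spread")
        planted = RingMotion(w_bar=1.0 + 0.5j, gamma_bar=0.1j, phi_bar=-0.2)
        sigma = 1e-3
        errs = []
        for seed in range(5):
            truth = bd.FieldGroundTruth(ring_motion=planted, profile="zero", seed=seed)
            fld = bd.make_field(ring, mesh, truth, ring_sigma=sigma)
            got = fit_ring_motion(ring, fld.ring_wz)
            errs.append(abs(got.w_bar - planted.w_bar))
        assert np.median(errs) < 3 * sigma / np.sqrt(48)

    def test_unknown_profile_rejected(self, rw_fixture):
        ring, mesh = rw_fixture
        with pytest.raises(SynthError, match="profile"):
            bd.make_field(ring, mesh, bd.FieldGroundTruth(ring_motion=ZERO, profile="dome"))


class TestPlantedSurface:
    def test_on_grid_extremum_found(self, frame):
        d_star = bd.direction_vector(frame, (45.0, 60.0))
        grid = bd.angle_grid(15.0)
        planted = bd.PlantedSurface(d_star=d_star, c=(1.0, 2.0), p=4.0, eps=0.0)
        surf = bd.make_surface(frame, grid, (500.0, 1000.0), planted)
        cmap = bd.criterion_map(surf)
        recs = {(r.criterion, r.kind): r for r in bd.coarse_extremes(cmap)}
        assert recs[("V", "max")].angles.as_tuple() == (45.0, 60.0)

    def test_constant_scale_zero_floor_gives_mu_one(self, frame):
        d_star = bd.direction_vector(frame, (10.0, 20.0))
        grid = bd.angle_grid(30.0)
        planted = bd.PlantedSurface(d_star=d_star, c=(1.0, 1.0, 1.0), p=2.0, eps=0.0)
        surf = bd.make_surface(frame, grid, (500.0, 1000.0, 2000.0), planted)
        mu = bd.weight_coefficients(surf.v_amp, surf.frequencies)
        assert np.allclose(mu, 1.0)

    def test_determinism_with_noise(self, frame):
        d_star = bd.direction_vector(frame, (0.0, 0.0))
        grid = bd.angle_grid(45.0)
        kw = dict(d_star=d_star, c=(1.0,), p=3.0, eps=0.1, sigma=0.05, seed=11)
        a = bd.PlantedSurface(**kw).amplitudes(frame, grid)
        b = bd.PlantedSurface(**kw).amplitudes(frame, grid)
        assert np.array_equal(a, b)


class TestMakeToyBone:
    def test_model_passes_invariants(self, toy_model):
        model, rw_frame, ops = toy_model
        assert len(model.node_sets["rw_edge"]) == 12
        assert len(model.node_sets["rw_membrane"]) == 16
        assert model.attachment_nodes.size >= 5
        assert model.attachment_mass_kg == pytest.approx(0.16e-3)
        # window frame z points into the fluid cavity
        assert np.allclose(rw_frame.z_hat, [0, 0, -1.0])

    def test_determinism_hash(self):
        m1, _ = bd.make_toy_bone(seed=0)
        m2, _ = bd.make_toy_bone(seed=0)
        assert m1.content_hash() == m2.content_hash()

    def test_rigid_window_kills_volume_displacement(self, toy_model):
        """Setting the membrane as stiff as bone drops |V| by >= 20 dB."""
        from bcdirect.pipeline import _rw_projection
        from bcdirect.kinematics import RingTriangulation, build_ring
        from bcdirect.volume import MembraneMesh

        model, rw_frame, ops = toy_model
        cfg = bd.ToyBoneConfig()
        stiff, _ = bd.make_toy_bone(
            bd.ToyBoneConfig(membrane=cfg.bone), seed=0
        )

        def vd_amp(m, operators=None):
            operators = operators or fem.assemble(m)
            d = bd.direction_vector(bd.STIMULATION_FRAME, (0.0, 0.0))
            fld = fem.solve_harmonic(
                m, fem.HarmonicLoad(amplitude=0.1, direction=d, frequency=1000.0),
                operators,
            )
            ring_ids = m.node_sets["rw_edge"]
            mem_ids = m.node_sets["rw_membrane"]
            ring = build_ring(ring_ids, _rw_projection(m, rw_frame, ring_ids))
            k = len(ring.node_ids) // 3
            ring = RingTriangulation(
                node_ids=ring.node_ids, xy=ring.xy,
                triangles=tuple((i, i + k, i + 2 * k) for i in range(k)),
            )
            remap = {int(n): i for i, n in enumerate(mem_ids)}
            quads = np.vectorize(remap.get)(m.face_sets["rw_membrane_quads"])
            mesh = MembraneMesh(nodes=_rw_projection(m, rw_frame, mem_ids), quads=quads)
            order = [list(ring_ids).index(n) for n in ring.node_ids]
            wz_ring = (fld.u_mm[ring_ids] @ rw_frame.z_hat)[order]
            wz_mem = fld.u_mm[mem_ids] @ rw_frame.z_hat
            rm = bd.fit_ring_motion(ring, wz_ring)
            return total_vd(mesh, wz_mem, rm).amplitude

        soft = vd_amp(model, ops)
        hard = vd_amp(stiff)
        assert 20 * np.log10(soft / hard) >= 20.0

    def test_bad_geometry_rejected(self):
        with pytest.raises(SynthError):
            bd.make_toy_bone(bd.ToyBoneConfig(cavity_lo=(0, 4, 4)))
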