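"""Harmonic hex8 solver: assembly oracles, statics, resonance, reciprocity."""

import numpy as np
import pytest

import bcdirect as bd
from bcdirect import fem
from conftest import make_rod


def single_cube(E=1.0, nu=0.0, rho=1.0, eta=0.0):
    nodes, elems, _ = fem.box_mesh((1, 1, 1), (1000.0, 1000.0, 1000.0))  # 1 m cube
    return fem.FEModel(
        nodes=nodes, elements=elems, material_ids=np.zeros(1, dtype=int),
        materials={0: fem.Material(E=E, nu=nu, rho=rho, eta=eta)},
        fixed_nodes=[0], attachment_mass_kg=0.0, attachment_nodes=[7],
    )


def tensor_stiffness_oracle(nodes, conn, E, nu):
    """Independent single-element stiffness: tensor elasticity C_ipjq with
    explicit component loops and 3-point Gauss quadrature."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    d = np.eye(3)
    C = np.zeros((3, 3, 3, 3))
    for i in range(3):
        for p in range(3):
            for j in range(3):
                for q in range(3):
                    C[i, p, j, q] = (
                        lam * d[i, p] * d[j, q]
                        + mu * (d[i, j] * d[p, q] + d[i, q] * d[j, p])
                    )
    gp = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
    gw = np.array([5.0, 8.0, 5.0]) / 9.0
    corners = np.array(
        [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
         [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
    )
    K = np.zeros((24, 24))
    coords = nodes[conn]
    for ix, x in enumerate(gp):
        for iy, y in enumerate(gp):
            for iz, z in enumerate(gp):
                dN = np.empty((8, 3))
                for a in range(8):
                    cx, cy, cz = corners[a]
                    dN[a] = 0.125 * np.array(
                        [cx * (1 + cy * y) * (1 + cz * z),
                         cy * (1 + cx * x) * (1 + cz * z),
                         cz * (1 + cx * x) * (1 + cy * y)]
                    )
                J = dN.T @ coords
                grad = dN @ np.linalg.inv(J).T
                wgt = gw[ix] * gw[iy] * gw[iz] * np.linalg.det(J)
                for a in range(8):
                    for b in range(8):
                        for i in range(3):
                            for j in range(3):
                                K[3 * a + i, 3 * b + j] += wgt * np.einsum(
                                    "p,pq,q->", grad[a], C[i, :, j, :], grad[b]
                                )
    return K


class TestAssembly:
    def test_single_element_matches_tensor_oracle(self):
        model = single_cube(E=1.0, nu=0.3)
        mat = model.materials[0]
        Ke, _, vol = fem._element_matrices(model.nodes[model.elements[0]], mat)
        Ko = tensor_stiffness_oracle(model.nodes, model.elements[0], 1.0, 0.3)
        assert vol == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(Ke, Ko, atol=1e-10)

    def test_zero_damping_gives_real_stiffness(self):
        ops = fem.assemble(single_cube(eta=0.0))
        assert np.abs(ops.K.imag).max() == 0.0
        ops2 = fem.assemble(single_cube(eta=0.05))
        assert np.abs(ops2.K.imag).max() > 0.0

    def test_operators_symmetric(self, toy_model):
        _, _, ops = toy_model
        assert abs(ops.K - ops.K.T).max() < 1e-6 * abs(ops.K).max()
        assert abs(ops.M - ops.M.T).max() < 1e-12 * abs(ops.M).max()

    def test_mass_conservation_toy_model(self, toy_model):
        model, _, ops = toy_model
        # bone/fluid/membrane volumes from the element grid (mm^3 -> m^3)
        counts = np.bincount(model.material_ids, minlength=3)
        vol = counts * 1e-9
        rho = np.array([model.materials[m].rho for m in range(3)])
        surface = 5 * 144e-6 * 2.5e3 * 1e-3  # 5 faces x 144 mm^2 x 2.5e-3 g/mm^2
        expected = float(vol @ rho) + surface + model.attachment_mass_kg
        assert fem.total_mass(ops) == pytest.approx(expected, rel=1e-9)

    def test_inverted_element_rejected(self):
        nodes, elems, _ = fem.box_mesh((1, 1, 1), (1.0, 1.0, 1.0))
        elems = elems[:, [1, 0, 3, 2, 5, 4, 7, 6]]  # mirrored connectivity
        model = fem.FEModel(
            nodes=nodes, elements=elems, material_ids=np.zeros(1, dtype=int),
            materials={0: fem.Material(E=1e9, nu=0.0, rho=1e3)},
            fixed_nodes=[0], attachment_mass_kg=0.0, attachment_nodes=[7],
        )
        with pytest.raises(fem.FEError, match="element"):
            fem.assemble(model)


class TestStatics:
    def test_uniaxial_patch_test(self):
        """Static tension of a nu=0 rod: exact uniform-strain solution."""
        model = make_rod(n_z=4, L_mm=4.0, E=1e9, nu=0.0)
        fld = fem.solve_harmonic(
            model, fem.HarmonicLoad(amplitude=1.0, direction=np.array([0, 0, 1.0]),
                                    frequency=0.0)
        )
        # sigma = F/A = 1e6 Pa; u_z(z) = sigma z / E
        for nid, pos in enumerate(model.nodes):
            expect = 1e6 * pos[2] / 1e9
            assert fld.u[nid, 2].real == pytest.approx(expect, abs=1e-8 * 4e-6)
            assert abs(fld.u[nid, 2].imag) < 1e-20

    def test_linearity_in_force_amplitude(self, toy_model):
        model, _, ops = toy_model
        d = np.array([0.0, 0.0, 1.0])
        u1 = fem.solve_harmonic(
            model, fem.HarmonicLoad(amplitude=0.1, direction=d, frequency=700.0), ops
        ).u
        u2 = fem.solve_harmonic(
            model, fem.HarmonicLoad(amplitude=0.2, direction=d, frequency=700.0), ops
        ).u
        assert np.allclose(u2, 2.0 * u1, rtol=1e-10)


class TestDynamics:
    def test_rod_resonance_matches_quarter_wave(self):
        """Fixed-free rod: first longitudinal peak at f1 = (1/4L) sqrt(E/rho)."""
        E, rho, L = 1e9, 1000.0, 0.02
        f1 = np.sqrt(E / rho) / (4 * L)  # 12.5 kHz
        model = make_rod(n_z=20, L_mm=20.0, E=E, rho=rho, eta=0.02)
        ops = fem.assemble(model)
        tip = model.attachment_nodes
        freqs = f1 * np.linspace(0.9, 1.1, 41)
        amp = []
        for f in freqs:
            fld = fem.solve_harmonic(
                model,
                fem.HarmonicLoad(amplitude=1.0, direction=np.array([0, 0, 1.0]),
                                 frequency=float(f)),
                ops,
            )
            amp.append(np.abs(fld.u[tip, 2]).mean())
        f_peak = freqs[int(np.argmax(amp))]
        assert abs(f_peak - f1) / f1 < 0.02

    def test_reciprocity_undamped(self):
        """Response at b to force at a equals response at a to force at b."""
        model = make_rod(n_z=6, L_mm=6.0, eta=0.0)
        ops = fem.assemble(model)
        solver = fem.FrequencySolver(model, ops, 500.0)
        free = set(ops.free.tolist())
        dof_a, dof_b = None, None
        for d in range(ops.n_dof):
            if d in free:
                if dof_a is None:
                    dof_a = d
                elif d >= dof_a + 40:
                    dof_b = d
                    break
        Fa = np.zeros(ops.n_dof, dtype=complex); Fa[dof_a] = 1.0
        Fb = np.zeros(ops.n_dof, dtype=complex); Fb[dof_b] = 1.0
        u_ab = solver.solve(Fa).u.ravel()[dof_b]
        u_ba = solver.solve(Fb).u.ravel()[dof_a]
        assert u_ab == pytest.approx(u_ba, rel=1e-8)

    def test_response_continuous_off_resonance(self, toy_model):
        model, _, ops = toy_model
        d = np.array([1.0, 0.0, 0.0])
        amps = []
        for f in (900.0, 905.0, 910.0):
            u = fem.solve_harmonic(
                model, fem.HarmonicLoad(amplitude=0.1, direction=d, frequency=f), ops
            ).u
            amps.append(np.abs(u).max())
        assert np.isfinite(amps).all()
        assert max(amps) / min(amps) < 1.5  # no jump on a fine local sweep


class TestSweep:
    def test_cardinality_and_determinism(self):
        model = make_rod(n_z=4, L_mm=4.0)
        dirs = [np.array([0, 0, 1.0]), np.array([1.0, 0, 0])]
        out = list(fem.sweep(model, dirs, [100.0, 200.0], amplitude=1.0))
        assert len(out) == 4
        again = list(fem.sweep(model, dirs, [100.0, 200.0], amplitude=1.0))
        for (i, f, a), (j, g, b) in zip(out, again):
            assert (i, f) == (j, g) and np.array_equal(a.u, b.u)

    def test_antiparallel_directions_opposite_fields(self):
        model = make_rod(n_z=4, L_mm=4.0)
        d = np.array([0.0, 0.6, 0.8])
        out = list(fem.sweep(model, [d, -d], [300.0], amplitude=1.0))
        assert np.allclose(out[0][2].u, -out[1][2].u, rtol=1e-12)


class TestModelValidation:
    def test_empty_fixed_set_rejected(self):
        nodes, elems, _ = fem.box_mesh((1, 1, 1), (1.0, 1.0, 1.0))
        with pytest.raises(fem.FEError, match="fixed"):
            fem.FEModel(
                nodes=nodes, elements=elems, material_ids=np.zeros(1, dtype=int),
                materials={0: fem.Material(E=1e9, nu=0.0, rho=1e3)},
                fixed_nodes=[], attachment_mass_kg=0.0, attachment_nodes=[7],
            )

    def test_orphan_nodes_rejected(self):
        nodes, elems, _ = fem.box_mesh((1, 1, 1), (1.0, 1.0, 1.0))
        nodes = np.vstack([nodes, [9.0, 9.0, 9.0]])
        with pytest.raises(fem.FEError, match="orphan"):
            fem.FEModel(
                nodes=nodes, elements=elems, material_ids=np.zeros(1, dtype=int),
                materials={0: fem.Material(E=1e9, nu=0.0, rho=1e3)},
                fixed_nodes=[0], attachment_mass_kg=0.0, attachment_nodes=[7],
            )
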