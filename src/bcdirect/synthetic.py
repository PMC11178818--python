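"""Synthetic fixtures: window geometry, harmonic fields with known ground
truth, planted response surfaces, and the toy temporal-bone FE model.

Everything the pipeline consumes can be generated here as a pure function of
(config, seed), so tests and end-to-end runs need no external data.  The
generators plant known quantities — a rigid ring motion, a membrane
deflection with closed-form volume displacement, an off-grid extremum
direction — so that every downstream stage can be checked against ground
truth.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import fem
from .frames import DirectionAngles, Frame, direction_vector
from .criteria import ResponseSurface, validate_frequency_set
from .kinematics import RingMotion, RingTriangulation, build_ring
from .volume import MembraneMesh

logger = logging.getLogger("bcdirect")


class SynthError(ValueError):
    pass


# ------------------------------------------------------------ RW geometry

def _ogrid_layout(n_quads: int, max_core: int = 12) -> tuple[int, int, int]:
    """Pick an O-grid disc layout (core a×b cells, L layers) whose quad count
    ab + 2(a+b)L matches ``n_quads`` exactly, preferring a square-ish core;
    falls back to the nearest achievable count with a warning."""
    exact = []
    for a in range(1, max_core + 1):
        for b in range(a, max_core + 1):
            per = 2 * (a + b)
            rest = n_quads - a * b
            if rest >= per and rest % per == 0:
                exact.append((b - a, abs(rest // per - (a + b)), a, b, rest // per))
    if exact:
        _, _, a, b, L = min(exact)
        return a, b, L
    # nearest achievable
    best = None
    for a in range(1, max_core + 1):
        for b in range(a, max_core + 1):
            per = 2 * (a + b)
            L = max(1, round((n_quads - a * b) / per))
            tot = a * b + per * L
            key = (abs(tot - n_quads), b - a, a)
            if best is None or key < best[0]:
                best = (key, a, b, L, tot)
    _, a, b, L, tot = best
    logger.warning(
        "disc template cannot produce exactly %d quads; using %d (core %d×%d, %d layers)",
        n_quads, tot, a, b, L,
    )
    return a, b, L


def _disc_mesh(radius: float, n_quads: int) -> tuple[np.ndarray, np.ndarray]:
    """Structured all-quad disc: rectangular core plus concentric O-grid
    layers blended to the circle.  Returns (nodes (n, 2), quads (m, 4)),
    counterclockwise winding."""
    a, b, L = _ogrid_layout(n_quads)
    scale = 0.45 * radius / max(a, b)
    xs = (np.arange(a + 1) - a / 2.0) * 2 * scale
    ys = (np.arange(b + 1) - b / 2.0) * 2 * scale
    core_id = np.full((a + 1, b + 1), -1, dtype=int)
    nodes: list[tuple[float, float]] = []
    for i in range(a + 1):
        for j in range(b + 1):
            core_id[i, j] = len(nodes)
            nodes.append((xs[i], ys[j]))
    quads = []
    for i in range(a):
        for j in range(b):
            quads.append(
                (core_id[i, j], core_id[i + 1, j], core_id[i + 1, j + 1], core_id[i, j + 1])
            )
    # CCW walk around the core perimeter
    perim: list[int] = []
    for i in range(a):
        perim.append(core_id[i, 0])
    for j in range(b):
        perim.append(core_id[a, j])
    for i in range(a, 0, -1):
        perim.append(core_id[i, b])
    for j in range(b, 0, -1):
        perim.append(core_id[0, j])
    P = len(perim)
    inner_pts = np.array([nodes[p] for p in perim])
    ang = np.arctan2(inner_pts[:, 1], inner_pts[:, 0])
    outer_pts = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    rings = [list(perim)]
    for ell in range(1, L + 1):
        t = ell / L
        layer_pts = inner_pts * (1 - t) + outer_pts * t
        ring_ids = []
        for p in layer_pts:
            ring_ids.append(len(nodes))
            nodes.append((p[0], p[1]))
        rings.append(ring_ids)
    for ell in range(L):
        inner, outer = rings[ell], rings[ell + 1]
        for s in range(P):
            sn = (s + 1) % P
            # CCW: out along the radius, along the outer arc, back inward
            quads.append((inner[s], outer[s], outer[sn], inner[sn]))
    # core winding: cells above were (i,j)->(i+1,j)->(i+1,j+1)->(i,j+1), CCW ✓
    return np.asarray(nodes, dtype=float), np.asarray(quads, dtype=int)


def make_rw_fixture(
    n_edge: int = 48,
    n_quads: int = 218,
    radius: float = 1.0,
    seed: int = 0,
    jitter: float = 0.0,
    grouping: str = "consecutive",
) -> tuple[RingTriangulation, MembraneMesh]:
    """Circular edge ring plus a structured all-quad membrane disc.

    ``n_edge`` ring nodes (divisible by 3) sit on the circle of ``radius``
    mm; ``jitter`` adds uniform angular noise (radians, seeded) to the ring
    nodes.  The membrane disc hits ``n_quads`` quadrilaterals exactly when
    the O-grid template allows (the 218 default does).  ``grouping`` selects
    how ring nodes combine into fit triangles: "consecutive" disjoint triples
    in angular order, or "spread" triples (i, i+n/3, i+2n/3) whose
    near-equilateral shape is better conditioned against nodal noise.
    """
    if n_edge % 3 != 0:
        raise SynthError(f"n_edge = {n_edge} not divisible by 3")
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_edge) / n_edge
    if jitter > 0:
        ang = ang + rng.uniform(-jitter, jitter, size=n_edge)
    xy = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    ring = build_ring(list(range(n_edge)), xy)
    if grouping == "spread":
        m = n_edge // 3
        tris = tuple((i, i + m, i + 2 * m) for i in range(m))
        ring = RingTriangulation(node_ids=ring.node_ids, xy=ring.xy, triangles=tris)
    elif grouping != "consecutive":
        raise SynthError(f"unknown grouping {grouping!r}")
    nodes, quads = _disc_mesh(radius, n_quads)
    return ring, MembraneMesh(nodes=nodes, quads=quads)


# --------------------------------------------------------- planted fields

#: membrane deflection profiles as functions of (r/R, theta); unit amplitude
_PROFILES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "piston": lambda rr, th: np.ones_like(rr),
    "paraboloid": lambda rr, th: 1.0 - rr**2,
    "zero": lambda rr, th: np.zeros_like(rr),
}


def _profile_fn(profile: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    if profile in _PROFILES:
        return _PROFILES[profile]
    m = re.fullmatch(r"mode\((\d+),(\d+)\)", profile)
    if m:
        mm, nn = int(m.group(1)), int(m.group(2))
        return lambda rr, th: (1.0 - rr**2) ** nn * np.cos(mm * th)
    raise SynthError(f"unknown membrane profile {profile!r}")


@dataclass(frozen=True)
class FieldGroundTruth:
    """Planted harmonic field: rigid ring motion plus a membrane deflection
    profile of complex amplitude d (mm) and optional nodal noise."""

    ring_motion: RingMotion
    profile: str = "piston"
    d: complex = 1.0
    sigma: float = 0.0
    seed: int = 0

    def expected_vd(self, mesh: MembraneMesh) -> complex | None:
        """Closed-form volume displacement where one exists (piston:
        V = A_total·d; zero profile: 0); None otherwise."""
        if self.profile == "piston":
            return mesh.total_area * self.d
        if self.profile == "zero":
            return 0.0 + 0.0j
        return None


@dataclass(frozen=True)
class SyntheticField:
    """Nodal z-displacements (mm, complex) on the ring and membrane."""

    ring_wz: np.ndarray
    membrane_wz: np.ndarray


def make_field(
    ring: RingTriangulation,
    mesh: MembraneMesh,
    truth: FieldGroundTruth,
    ring_sigma: float = 0.0,
) -> SyntheticField:
    """Planted harmonic field over the fixture.

    Ring nodes carry exactly the planted rigid field (optionally perturbed by
    complex gaussian noise of per-part std ``ring_sigma`` for robustness
    studies); membrane nodes carry rigid field + profile·d + complex gaussian
    noise of per-part std ``truth.sigma``.  Reproducible from the seed.
    """
    rng = np.random.default_rng(truth.seed)
    rm = truth.ring_motion
    ring_wz = rm.rigid_field(ring.xy[:, 0], ring.xy[:, 1]).astype(complex)
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    r = np.hypot(x, y)
    radius = max(np.max(np.hypot(ring.xy[:, 0], ring.xy[:, 1])), r.max())
    th = np.arctan2(y, x)
    prof = _profile_fn(truth.profile)(r / radius, th)
    mem_wz = rm.rigid_field(x, y) + truth.d * prof
    if truth.sigma > 0:
        mem_wz = mem_wz + truth.sigma * (
            rng.standard_normal(len(mem_wz)) + 1j * rng.standard_normal(len(mem_wz))
        )
    if ring_sigma > 0:
        ring_wz = ring_wz + ring_sigma * (
            rng.standard_normal(len(ring_wz)) + 1j * rng.standard_normal(len(ring_wz))
        )
    return SyntheticField(ring_wz=ring_wz, membrane_wz=mem_wz)


# ------------------------------------------------------- planted surfaces

@dataclass(frozen=True)
class PlantedSurface:
    """Direction-response generator with a planted extremum.

    amp(α, β, f) = c(f) · (ε + max(0, ẑ_αβ·d*)^p): the continuum argmax over
    directions is exactly d* for any sharpness p > 0 and floor ε ≥ 0.
    """

    d_star: np.ndarray
    c: tuple
    p: float = 6.0
    eps: float = 0.05
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.d_star, dtype=float)
        if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise SynthError("d_star must be a unit 3-vector")
        object.__setattr__(self, "d_star", d)
        object.__setattr__(self, "c", tuple(float(x) for x in self.c))
        if any(x <= 0 for x in self.c):
            raise SynthError("per-frequency scales c(f) must be positive")
        if self.p <= 0 or self.eps < 0:
            raise SynthError("need sharpness p > 0 and floor ε ≥ 0")

    def amplitudes(self, frame: Frame, grid: Sequence[DirectionAngles]) -> np.ndarray:
        """(n_directions, n_frequencies) amplitude table, optionally noisy."""
        rng = np.random.default_rng(self.seed)
        dots = np.array(
            [float(direction_vector(frame, g) @ self.d_star) for g in grid]
        )
        base = self.eps + np.maximum(0.0, dots) ** self.p
        amp = np.outer(base, np.asarray(self.c))
        if self.sigma > 0:
            amp = amp * (1.0 + self.sigma * rng.standard_normal(amp.shape))
            amp = np.maximum(amp, 0.0)
        return amp


def make_surface(
    frame: Frame,
    grid: Sequence[DirectionAngles],
    frequencies: Sequence[float],
    planted_v: PlantedSurface,
    planted_w: PlantedSurface | None = None,
) -> ResponseSurface:
    """Response surface from planted generators (w defaults to the V rule)."""
    freqs = validate_frequency_set(frequencies)
    if len(planted_v.c) != len(freqs):
        raise SynthError("planted c(f) length must match the frequency set")
    v_amp = planted_v.amplitudes(frame, grid)
    w_amp = (planted_w or planted_v).amplitudes(frame, grid)
    return ResponseSurface(
        angles=tuple(grid), frequencies=freqs, v_amp=v_amp, w_amp=w_amp
    )


# ---------------------------------------------------------- toy bone model

@dataclass(frozen=True)
class ToyBoneConfig:
    """Non-anatomical block-with-cavity stand-in for the temporal bone.

    A bone cube holds a fluid cavity (the cochlear duct system, modeled as a
    nearly incompressible low-shear solid) sitting just under the top
    surface; the one-element wall between the cavity and the outside is
    membrane material (the round window), so the membrane has a free outer
    face and can deflect.  A circle of nodes on the +x face carries the
    implant mass and the harmonic force; the bottom face is fixed.
    Dimensions in mm; element size 1 mm.
    """

    n_elems: tuple = (12, 12, 12)
    size_mm: tuple = (12.0, 12.0, 12.0)
    cavity_lo: tuple = (4, 4, 6)       # element index ranges, inclusive lo
    cavity_hi: tuple = (9, 9, 11)      # exclusive hi
    window_k: int = 11                 # element layer above cavity = membrane
    window_lo: tuple = (5, 5)          # membrane patch (i, j) range over the
    window_hi: tuple = (8, 8)          # cavity roof; rest of the roof is bone
    patch_center_mm: tuple = (12.0, 6.0, 6.0)
    patch_radius_mm: float = 1.5
    attachment_mass_g: float = 0.16
    surface_density_g_mm2: float = 2.5e-3
    bone: fem.Material = fem.Material(E=14.1e9, nu=0.30, rho=1900.0, eta=0.05)
    fluid: fem.Material = fem.Material(E=1.3e7, nu=0.499, rho=1000.0, eta=0.05)
    membrane: fem.Material = fem.Material(E=1.0e6, nu=0.45, rho=1200.0, eta=0.10)


BONE, FLUID, MEMBRANE = 0, 1, 2


def make_toy_bone(config: ToyBoneConfig | None = None, seed: int = 0) -> tuple[fem.FEModel, Frame]:
    """Build the toy FE model and its window-local (RW) frame.

    Returns (model, rw_frame).  Named node sets: ``rw_edge`` (window rim on
    the outer membrane surface), ``rw_membrane`` (outer membrane surface
    nodes), ``stimulation_patch``; face set ``rw_membrane_quads`` carries the
    membrane surface connectivity.  Deterministic given (config, seed).
    """
    cfg = config or ToyBoneConfig()
    nx, ny, nz = cfg.n_elems
    lo, hi = cfg.cavity_lo, cfg.cavity_hi
    if not all(0 < lo[i] and hi[i] < (nx, ny, nz)[i] for i in range(3)):
        raise SynthError("cavity must be strictly interior to the block")
    if cfg.window_k != hi[2]:
        raise SynthError("membrane window layer must sit on the cavity's +z wall")
    if cfg.window_k != nz - 1:
        raise SynthError(
            "membrane layer must be the outermost +z wall so its outer face is free"
        )
    wlo, whi = cfg.window_lo, cfg.window_hi
    if not (lo[0] <= wlo[0] and whi[0] <= hi[0] and lo[1] <= wlo[1] and whi[1] <= hi[1]):
        raise SynthError("window patch must lie over the cavity roof")
    wn = whi[0] - wlo[0]  # window width in elements (x)
    if (whi[1] - wlo[1]) != wn or wn < 1:
        raise SynthError("window patch must be square")
    if (4 * wn) % 3 != 0:
        raise SynthError(
            f"window rim has {4 * wn} nodes, not divisible by 3; "
            f"choose a window width that is a multiple of 3"
        )
    nodes, elems, nid = fem.box_mesh(cfg.n_elems, cfg.size_mm)
    dx = cfg.size_mm[0] / nx  # element size, mm (assumed uniform)

    mat_ids = np.full(len(elems), BONE, dtype=int)
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if lo[0] <= i < hi[0] and lo[1] <= j < hi[1] and lo[2] <= k < hi[2]:
                    mat_ids[e] = FLUID
                elif wlo[0] <= i < whi[0] and wlo[1] <= j < whi[1] and k == cfg.window_k:
                    mat_ids[e] = MEMBRANE
                e += 1

    # window surface (outer face of the membrane layer, z = (window_k+1)·dx)
    ktop = cfg.window_k + 1
    mem_nodes = [nid[i, j, ktop] for i in range(wlo[0], whi[0] + 1)
                 for j in range(wlo[1], whi[1] + 1)]
    mem_quads = np.array(
        [
            (nid[i, j, ktop], nid[i + 1, j, ktop], nid[i + 1, j + 1, ktop], nid[i, j + 1, ktop])
            for i in range(wlo[0], whi[0])
            for j in range(wlo[1], whi[1])
        ],
        dtype=int,
    )
    rim = []
    for i in range(wlo[0], whi[0] + 1):
        for j in range(wlo[1], whi[1] + 1):
            if i in (wlo[0], whi[0]) or j in (wlo[1], whi[1]):
                rim.append(nid[i, j, ktop])
    rim = np.array(sorted(rim), dtype=int)

    # stimulation patch on the +x face
    cx, cy, cz = (c * 1e-3 for c in cfg.patch_center_mm)
    on_face = np.isclose(nodes[:, 0], cfg.size_mm[0] * 1e-3)
    dist = np.hypot(nodes[:, 1] - cy, nodes[:, 2] - cz)
    patch = np.nonzero(on_face & (dist <= cfg.patch_radius_mm * 1e-3 + 1e-12))[0]
    if patch.size == 0:
        raise SynthError("stimulation patch circle contains no surface nodes")

    fixed = np.nonzero(np.isclose(nodes[:, 2], 0.0))[0]

    # soft-tissue surface mass on outer faces except the fixed bottom
    faces = []
    for i in range(nx):
        for j in range(ny):
            faces.append((nid[i, j, nz], nid[i + 1, j, nz], nid[i + 1, j + 1, nz], nid[i, j + 1, nz]))
    for j in range(ny):
        for k in range(nz):
            faces.append((nid[0, j, k], nid[0, j, k + 1], nid[0, j + 1, k + 1], nid[0, j + 1, k]))
            faces.append((nid[nx, j, k], nid[nx, j + 1, k], nid[nx, j + 1, k + 1], nid[nx, j, k + 1]))
    for i in range(nx):
        for k in range(nz):
            faces.append((nid[i, 0, k], nid[i + 1, 0, k], nid[i + 1, 0, k + 1], nid[i, 0, k + 1]))
            faces.append((nid[i, ny, k], nid[i, ny, k + 1], nid[i + 1, ny, k + 1], nid[i + 1, ny, k]))
    surface_masses = [(np.array(faces, dtype=int), cfg.surface_density_g_mm2)]
    # g/mm² → kg/m²:  1 g/mm² = 1e-3 kg / 1e-6 m² = 1e3 kg/m²
    surface_masses = [(surface_masses[0][0], cfg.surface_density_g_mm2 * 1e3)]

    model = fem.FEModel(
        nodes=nodes,
        elements=elems,
        material_ids=mat_ids,
        materials={BONE: cfg.bone, FLUID: cfg.fluid, MEMBRANE: cfg.membrane},
        fixed_nodes=fixed,
        attachment_mass_kg=cfg.attachment_mass_g * 1e-3,
        attachment_nodes=patch,
        surface_masses=surface_masses,
        node_sets={
            "rw_edge": rim,
            "rw_membrane": np.array(sorted(mem_nodes), dtype=int),
            "stimulation_patch": patch,
        },
        face_sets={"rw_membrane_quads": mem_quads},
    )

    # window-local frame: origin at the window center on the outer membrane
    # surface, z toward the fluid cavity (the "cochlea"), mm
    center = nodes[rim].mean(axis=0) * 1e3
    rw_frame = Frame(
        origin=center,
        x_hat=np.array([1.0, 0.0, 0.0]),
        y_hat=np.array([0.0, -1.0, 0.0]),
        z_hat=np.array([0.0, 0.0, -1.0]),
    )
    return model, rw_frame
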