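"""Fluid volume displacement of the round-window membrane.

The membrane surface is post-processed as quadrilaterals split along one
diagonal into triangles.  The volume displaced through the membrane per
cycle is the integral of the nodal z-displacement *relative to the rigid
motion of the bony rim*, evaluated triangle-wise as projected area times the
mean of the three relative vertex displacements:

    Δw_s = w_s − (w̄ + γ̄·y_s − φ̄·x_s)
    V    = Σ_t (A_t / 3) (Δw_A + Δw_B + Δw_C)

Areas are signed (shoelace) projections onto the window plane; the canonical
winding is counterclockwise viewed from +z (toward the cochlea), so outward
deflection gives positive V.  V is complex; amplitude and phase are reported
as |V| and atan2(Im, Re) in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinematics import RingMotion

logger = logging.getLogger("bcdirect")


class MembraneError(ValueError):
    pass


def projected_area(tri: Sequence[Sequence[float]]) -> float:
    """Signed shoelace area of a triangle projected on the xy-plane, mm²."""
    (xa, ya), (xb, yb), (xc, yc) = np.asarray(tri, dtype=float)
    return 0.5 * (xa * yb + xb * yc + xc * ya - xa * yc - xb * ya - xc * yb)


def _tri_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]  # (m, 3, 2)
    return 0.5 * (
        p[:, 0, 0] * p[:, 1, 1]
        + p[:, 1, 0] * p[:, 2, 1]
        + p[:, 2, 0] * p[:, 0, 1]
        - p[:, 0, 0] * p[:, 2, 1]
        - p[:, 1, 0] * p[:, 0, 1]
        - p[:, 2, 0] * p[:, 1, 1]
    )


def split_quads(quads: Sequence[Sequence[int]]) -> np.ndarray:
    """Split each quad (A, B, C, D) into triangles (A, B, C) and (A, C, D).

    The two triangle areas sum to the quad's shoelace area for any winding.
    """
    q = np.asarray(quads, dtype=int)
    if q.ndim != 2 or q.shape[1] != 4:
        raise MembraneError(f"quads must be (m, 4), got {q.shape}")
    tris = np.empty((2 * len(q), 3), dtype=int)
    tris[0::2] = q[:, [0, 1, 2]]
    tris[1::2] = q[:, [0, 2, 3]]
    return tris


@dataclass(frozen=True)
class MembraneMesh:
    """Membrane surface: planar node coordinates (mm, window frame) and
    quadrilateral faces; triangles derived by the (ABC, ACD) diagonal split.

    Quads wound clockwise are re-wound on construction (logged); quads whose
    two triangles have opposite-sign areas are self-intersecting and warned.
    Node z-coordinates play no role: areas are xy-plane projections.
    """

    nodes: np.ndarray   # (n, 2)
    quads: np.ndarray   # (m, 4)
    alt_diagonal: bool = False  # split along (ABD, BCD) instead — sensitivity switch

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] not in (2, 3):
            raise MembraneError(f"nodes must be (n, 2) or (n, 3), got {nodes.shape}")
        nodes = nodes[:, :2].copy()
        quads = np.asarray(self.quads, dtype=int)
        if quads.ndim != 2 or quads.shape[1] != 4:
            raise MembraneError(f"quads must be (m, 4), got {quads.shape}")
        rewound = 0
        quads = quads.copy()
        for f, q in enumerate(quads):
            a1 = projected_area(nodes[[q[0], q[1], q[2]]])
            a2 = projected_area(nodes[[q[0], q[2], q[3]]])
            if a1 < 0 and a2 < 0:
                quads[f] = q[::-1]
                rewound += 1
            elif a1 * a2 < 0:
                logger.warning("membrane quad %d is self-intersecting", f)
        if rewound:
            logger.info("re-wound %d clockwise membrane quads to canonical CCW", rewound)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "quads", quads)

    @property
    def triangles(self) -> np.ndarray:
        if self.alt_diagonal:
            q = self.quads
            tris = np.empty((2 * len(q), 3), dtype=int)
            tris[0::2] = q[:, [0, 1, 3]]
            tris[1::2] = q[:, [1, 2, 3]]
            return tris
        return split_quads(self.quads)

    @property
    def areas(self) -> np.ndarray:
        """Signed projected areas of the derived triangles, mm²."""
        return _tri_areas(self.nodes, self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass(frozen=True)
class VolumeDisplacement:
    """Complex fluid volume displacement with amplitude (mm³) and phase
    (degrees, (−180, 180])."""

    V: complex

    @property
    def amplitude(self) -> float:
        return abs(self.V)

    @property
    def phase_deg(self) -> float:
        return amplitude_phase(self.V)[1]


def amplitude_phase(z: complex) -> tuple[float, float]:
    """(|z|, phase in degrees), phase in (−180, 180], phase of 0 is 0."""
    amp = abs(z)
    if amp == 0.0:
        return 0.0, 0.0
    ph = math.degrees(math.atan2(z.imag, z.real))
    if ph <= -180.0:
        ph += 360.0
    return amp, ph


def relative_displacement(
    vertex: Sequence[float], wz: complex, ring: RingMotion
) -> complex:
    """Δw = w_z − (w̄ + γ̄·y − φ̄·x) at one vertex."""
    x, y = float(vertex[0]), float(vertex[1])
    return wz - (ring.w_bar + ring.gamma_bar * y - ring.phi_bar * x)


def total_vd(
    mesh: MembraneMesh, field: Sequence[complex], ring: RingMotion
) -> VolumeDisplacement:
    """Membrane volume displacement relative to the rim's rigid motion.

    V = Σ_t (A_t/3)(Δw_A + Δw_B + Δw_C), summed over the derived triangles.
    """
    w = np.asarray(field, dtype=complex)
    if w.shape != (len(mesh.nodes),):
        raise MembraneError(
            f"field covers {w.shape} nodes, mesh has {len(mesh.nodes)}"
        )
    dw = w - ring.rigid_field(mesh.nodes[:, 0], mesh.nodes[:, 1])
    tris = mesh.triangles
    areas = _tri_areas(mesh.nodes, tris)
    V = complex(np.sum(areas / 3.0 * dw[tris].sum(axis=1)))
    return VolumeDisplacement(V=V)
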