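"""Rigid-body motion of the round-window bony edge.

The bony rim of the round window is sampled at nodes lying on the border
between compact bone and the membrane.  Under the small-rotation assumption
the out-of-plane displacement of a point (x, y) of a rigidly moving edge is

    w_z(x, y) = w + γ·y − φ·x

with translation w along the window normal and rotations γ, φ about the
in-plane x- and y-axes.  Each disjoint triple of ring nodes (a triangle)
determines (w, γ, φ) exactly by inverting the 3×3 system; the ring motion is
the arithmetic mean over all triangles.  Displacements are complex (one
harmonic response), so real and imaginary parts are fitted jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: a triangle whose doubled signed area falls below this (mm²) is degenerate
DEGENERATE_AREA_TOL = 1e-12


class RingError(ValueError):
    """Ring geometry or fit contract violation."""


@dataclass(frozen=True)
class TriangleMotion:
    """Rigid z-motion of one edge triangle: translation w (mm, complex) and
    small rotations gamma (about x) and phi (about y), rad, complex."""

    w: complex
    gamma: complex
    phi: complex

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.gamma, self.phi], dtype=complex)


@dataclass(frozen=True)
class RingMotion:
    """Triangle-averaged rigid motion of the full edge ring."""

    w_bar: complex
    gamma_bar: complex
    phi_bar: complex

    def rigid_field(self, x, y) -> np.ndarray:
        """Evaluate the rigid z-displacement w̄ + γ̄·y − φ̄·x at points."""
        return self.w_bar + self.gamma_bar * np.asarray(y) - self.phi_bar * np.asarray(x)


@dataclass(frozen=True)
class RingTriangulation:
    """Edge ring: node ids in angular order, planar coordinates (mm, window
    frame), and disjoint index triples grouping the nodes into triangles."""

    node_ids: tuple
    xy: np.ndarray          # (n, 2)
    triangles: tuple        # of (i, j, k) index triples

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        object.__setattr__(self, "triangles", tuple(tuple(t) for t in self.triangles))
        n = len(self.node_ids)
        if xy.shape != (n, 2):
            raise RingError(f"xy shape {xy.shape} does not match {n} node ids")
        if n % 3 != 0:
            raise RingError(f"ring has {n} nodes, not divisible by 3")
        used = sorted(i for t in self.triangles for i in t)
        if used != list(range(n)):
            raise RingError("triangles must partition the ring nodes")
        for t in self.triangles:
            if abs(_denominator(xy[list(t)])) <= DEGENERATE_AREA_TOL:
                raise RingError(f"degenerate (collinear) triangle {t}")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


def _denominator(coords: np.ndarray) -> float:
    """(y_k − y_i)·x_j + (y_j − y_k)·x_i + (y_i − y_j)·x_k — twice the signed
    triangle area, the determinant of the rigid-fit system."""
    (xi, yi), (xj, yj), (xk, yk) = coords
    return (yk - yi) * xj + (yj - yk) * xi + (yi - yj) * xk


def fit_triangle_motion(
    coords: Sequence[Sequence[float]], wz: Sequence[complex]
) -> TriangleMotion:
    """Exactly invert w_s = w + γ·y_s − φ·x_s for one node triple.

    Uses the explicit adjugate of the 3×3 coefficient matrix so the forward
    model reproduces the inputs to machine precision.
    """
    c = np.asarray(coords, dtype=float)
    if c.shape != (3, 2):
        raise RingError(f"need three (x, y) pairs, got shape {c.shape}")
    w = np.asarray(wz, dtype=complex)
    if w.shape != (3,):
        raise RingError(f"need three nodal displacements, got shape {w.shape}")
    den = _denominator(c)
    if abs(den) <= DEGENERATE_AREA_TOL:
        raise RingError(
            f"singular triangle: vertices {c.tolist()} are collinear "
            f"(denominator {den!r})"
        )
    (xi, yi), (xj, yj), (xk, yk) = c
    adj = np.array(
        [
            [xj * yk - yj * xk, yi * xk - xi * yk, xi * yj - yi * xj],
            [xk - xj, xi - xk, xj - xi],
            [yk - yj, yi - yk, yj - yi],
        ]
    )
    out = (adj @ w) / den
    return TriangleMotion(w=out[0], gamma=out[1], phi=out[2])


def average_ring_motion(motions: Sequence[TriangleMotion]) -> RingMotion:
    """Complex arithmetic mean of triangle motions (Re and Im averaged
    independently, equivalently one complex mean)."""
    if len(motions) == 0:
        raise RingError("cannot average an empty set of triangle motions")
    stack = np.array([m.as_array() for m in motions])
    mean = stack.mean(axis=0)
    return RingMotion(w_bar=mean[0], gamma_bar=mean[1], phi_bar=mean[2])


def fit_ring_motion(ring: RingTriangulation, wz: Sequence[complex]) -> RingMotion:
    """Fit every ring triangle and average: the edge's rigid motion."""
    w = np.asarray(wz, dtype=complex)
    if w.shape != (len(ring.node_ids),):
        raise RingError(
            f"field has {w.shape} entries for {len(ring.node_ids)} ring nodes"
        )
    motions = [
        fit_triangle_motion(ring.xy[list(t)], w[list(t)]) for t in ring.triangles
    ]
    return average_ring_motion(motions)


def build_ring(
    node_ids: Sequence, xy: Sequence[Sequence[float]], angle_tol: float = 1e-9
) -> RingTriangulation:
    """Order ring nodes by polar angle and group consecutive disjoint triples.

    The grouping (0,1,2), (3,4,5), … of angularly sorted nodes yields
    n/3 disjoint triangles (16 for the canonical 48-node rim).  Node count
    must be divisible by 3; duplicate polar angles (within ``angle_tol``
    radians) are rejected because the ordering would be ambiguous.
    """
    pts = np.asarray(xy, dtype=float)
    ids = list(node_ids)
    if pts.shape != (len(ids), 2):
        raise RingError(f"xy shape {pts.shape} does not match {len(ids)} ids")
    if len(ids) % 3 != 0:
        raise RingError(f"{len(ids)} ring nodes not divisible by 3")
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.argsort(ang, kind="stable")
    sorted_ang = ang[order]
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 2 * math.pi]]))
    if np.any(gaps < angle_tol):
        raise RingError("duplicate polar angles in ring; ordering ambiguous")
    ids_sorted = [ids[i] for i in order]
    pts_sorted = pts[order]
    tris = [(3 * m, 3 * m + 1, 3 * m + 2) for m in range(len(ids) // 3)]
    return RingTriangulation(node_ids=tuple(ids_sorted), xy=pts_sorted, triangles=tuple(tris))
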