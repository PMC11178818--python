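"""Sub-grid refinement of criterion extremes.

The coarse angle grid (15° steps) locates an extremum only to grid
resolution.  A biquadratic interpolant over the 3×3 stencil of neighboring
criterion values — the tensor-product shape functions of a 9-node Lagrangian
surface element on the biunit square — refines it: the interpolant is
maximized (or minimized) over [−1, 1]² by dense sampling followed by one
Newton polish, clamped to the square, and the local coordinates are mapped
back to degrees via center + local·spacing.

Dense sampling before Newton avoids converging to the biquadratic's saddle;
an extremum landing on the stencil boundary is flagged, since it suggests
the coarse extremum was misidentified (the true extremum lies in a
neighboring cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import DirectionAngles


class RefineError(ValueError):
    pass


@dataclass(frozen=True)
class Stencil3x3:
    """3×3 grid patch around a coarse extremum.

    ``values[i, j]`` holds the criterion at (alpha + (i−1)·spacing,
    beta + (j−1)·spacing); local coordinates (ξ, η) ∈ [−1, 1]² map to
    (alpha, beta) offsets ξ·spacing, η·spacing.
    """

    center: DirectionAngles
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise RefineError(f"stencil values must be 3×3, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise RefineError("stencil values must be finite")
        object.__setattr__(self, "values", v)


def _basis(t: np.ndarray) -> np.ndarray:
    """1-D quadratic Lagrange basis on nodes {−1, 0, +1}; shape (..., 3)."""
    t = np.asarray(t, dtype=float)
    return np.stack([0.5 * t * (t - 1.0), 1.0 - t * t, 0.5 * t * (t + 1.0)], axis=-1)


def _dbasis(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.stack([t - 0.5, -2.0 * t, t + 0.5], axis=-1)


def lagrange9_interpolate(stencil: Stencil3x3, xi, eta) -> np.ndarray:
    """Evaluate the biquadratic interpolant at local (ξ, η) ∈ [−1, 1]²."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(np.abs(xi) > 1 + 1e-12) or np.any(np.abs(eta) > 1 + 1e-12):
        raise RefineError("local coordinates outside the biunit square")
    Nx = _basis(xi)
    Ny = _basis(eta)
    return np.einsum("...i,ij,...j->...", Nx, stencil.values, Ny)


def _grad_hess(stencil: Stencil3x3, xi: float, eta: float):
    V = stencil.values
    nx, ny = _basis(xi), _basis(eta)
    dx, dy = _dbasis(xi), _dbasis(eta)
    d2x = np.array([1.0, -2.0, 1.0])
    g = np.array([dx @ V @ ny, nx @ V @ dy])
    H = np.array(
        [[d2x @ V @ ny, dx @ V @ dy], [dx @ V @ dy, nx @ V @ d2x]]
    )
    return g, H


@dataclass(frozen=True)
class RefinedExtremum:
    angles: DirectionAngles
    value: float
    local: tuple[float, float]
    boundary: bool


def refine_extremum(
    stencil: Stencil3x3, kind: str = "max", sample_step: float = 0.005
) -> RefinedExtremum:
    """Locate the interpolant's extremum over the biunit square.

    Dense lattice scan (step ≤ ``sample_step``) picks the basin; one Newton
    step from the scan argmax polishes it (accepted only if it stays in the
    square and improves the objective).  The refined value never falls below
    (for ``max``) the best stencil nodal value.
    """
    if kind not in ("max", "min"):
        raise RefineError(f"kind must be 'max' or 'min', got {kind!r}")
    sgn = 1.0 if kind == "max" else -1.0
    n = int(np.ceil(2.0 / sample_step)) + 1
    t = np.linspace(-1.0, 1.0, n)
    X, Y = np.meshgrid(t, t, indexing="ij")
    Z = lagrange9_interpolate(stencil, X, Y)
    flat = int(np.argmax(sgn * Z))
    i, j = np.unravel_index(flat, Z.shape)
    xi, eta, val = float(t[i]), float(t[j]), float(Z[i, j])
    # one Newton polish on the stationary equations of the biquadratic
    g, H = _grad_hess(stencil, xi, eta)
    det = np.linalg.det(H)
    if abs(det) > 1e-14:
        step = np.linalg.solve(H, -g)
        cand = (xi + float(step[0]), eta + float(step[1]))
        if max(abs(cand[0]), abs(cand[1])) <= 1.0:
            cval = float(lagrange9_interpolate(stencil, *cand))
            if sgn * cval >= sgn * val:
                xi, eta, val = cand[0], cand[1], cval
    boundary = max(abs(xi), abs(eta)) >= 1.0 - 1e-9
    a = stencil.center.alpha + xi * stencil.spacing
    b = stencil.center.beta + eta * stencil.spacing
    return RefinedExtremum(
        angles=DirectionAngles(alpha=a, beta=b),
        value=val,
        local=(xi, eta),
        boundary=boundary,
    )
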