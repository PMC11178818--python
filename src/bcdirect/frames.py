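"""Coordinate frames and the two-angle force-direction parametrization.

A bone-conduction stimulation direction is described by two angles
``(alpha, beta)`` measured in a local right-handed frame anchored at the
stimulation site.  The primary direction (0, 0) points along the frame's
z-versor; ``alpha`` rotates the force about the frame's x-axis (Rodrigues
rotation), after which ``beta`` rotates it about the rotated y-axis.  All
angles in the public interface are degrees; radians appear only inside
trigonometric calls.

The module also ships the stimulation frame of the reference temporal-bone
model (origin and versors printed to three decimals, re-orthonormalized on
load) as :data:`STIMULATION_FRAME`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("bcdirect")

#: tolerance for unit-norm / orthogonality contracts on constructed frames
FRAME_TOL = 1e-9
#: printed 3-decimal versors may be off by this much before re-orthonormalization
RAW_VERSOR_TOL = 2e-3


class FrameError(ValueError):
    """A frame or direction violated its geometric contract."""


def _as_vec3(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise FrameError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal coordinate frame in global skull coordinates.

    Attributes
    ----------
    origin : (3,) ndarray
        Frame origin, mm, global coordinates.
    x_hat, y_hat, z_hat : (3,) ndarray
        Unit versors of the frame axes expressed in global coordinates.
    """

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    z_hat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_hat", "y_hat", "z_hat"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name)))
        for name in ("x_hat", "y_hat", "z_hat"):
            n = np.linalg.norm(getattr(self, name))
            if abs(n - 1.0) > FRAME_TOL:
                raise FrameError(f"{name} is not unit length (|{name}| = {n!r})")
        for a, b in (("x_hat", "y_hat"), ("y_hat", "z_hat"), ("x_hat", "z_hat")):
            d = float(np.dot(getattr(self, a), getattr(self, b)))
            if abs(d) > FRAME_TOL:
                raise FrameError(f"{a}·{b} = {d!r}, frame not orthogonal")
        if np.linalg.norm(np.cross(self.x_hat, self.y_hat) - self.z_hat) > FRAME_TOL:
            raise FrameError("frame is not right-handed (x̂ × ŷ ≠ ẑ)")

    @classmethod
    def from_raw(
        cls,
        origin: Sequence[float],
        x_hat: Sequence[float],
        y_hat: Sequence[float],
        z_hat: Sequence[float],
    ) -> "Frame":
        """Build a frame from versors printed at limited precision.

        Rounded versors (three decimals) violate orthonormality at the 1e-3
        level; a single Gram–Schmidt pass anchored on ``x_hat`` restores an
        exact right-handed orthonormal triple.  Each versor may move by at
        most ``RAW_VERSOR_TOL`` (2e-3); larger corrections indicate a wrong
        input and raise.
        """
        x0, y0, z0 = _as_vec3(x_hat), _as_vec3(y_hat), _as_vec3(z_hat)
        x = x0 / np.linalg.norm(x0)
        y = y0 - np.dot(y0, x) * x
        y = y / np.linalg.norm(y)
        z = z0 - np.dot(z0, x) * x - np.dot(z0, y) * y
        z = z / np.linalg.norm(z)
        for raw, fixed, name in ((x0, x, "x_hat"), (y0, y, "y_hat"), (z0, z, "z_hat")):
            shift = float(np.linalg.norm(fixed - raw))
            if shift > RAW_VERSOR_TOL:
                raise FrameError(
                    f"re-orthonormalization moved {name} by {shift:.2e} "
                    f"(> {RAW_VERSOR_TOL}); input versors are inconsistent"
                )
        return cls(origin=_as_vec3(origin), x_hat=x, y_hat=y, z_hat=z)

    def to_config(self) -> dict:
        """Serializable config block (lists, mm)."""
        return {
            "origin_mm": self.origin.tolist(),
            "x_hat": self.x_hat.tolist(),
            "y_hat": self.y_hat.tolist(),
            "z_hat": self.z_hat.tolist(),
        }

    @classmethod
    def from_config(cls, block: dict) -> "Frame":
        return cls.from_raw(
            block["origin_mm"], block["x_hat"], block["y_hat"], block["z_hat"]
        )


#: Stimulation frame of the reference temporal-bone model: origin at the
#: implant site on the otic capsule above the lateral semicircular canal,
#: z-versor along the primary stimulation direction (toward the cochlea).
STIMULATION_FRAME = Frame.from_raw(
    origin=(-45.92, 6.24, -25.28),
    x_hat=(0.004, -0.918, 0.397),
    y_hat=(-0.270, -0.383, -0.884),
    z_hat=(0.963, -0.104, -0.249),
)

#: Global skull frame: identity axes, origin at (0, 0, 0).
GLOBAL_FRAME = Frame(
    origin=np.zeros(3),
    x_hat=np.array([1.0, 0.0, 0.0]),
    y_hat=np.array([0.0, 1.0, 0.0]),
    z_hat=np.array([0.0, 0.0, 1.0]),
)


@dataclass(frozen=True)
class DirectionAngles:
    """Force-direction angles, degrees, canonical range [-90, 90].

    ``degenerate`` flags gimbal lock (|beta| = 90, where alpha is undefined
    and reported as 0).
    """

    alpha: float
    beta: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise FrameError("direction angles must be finite")

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis.

    R = k kᵀ (1 − cos θ) + I cos θ + [k]× sin θ, with [k]× the cross-product
    (skew) matrix of the axis.  Returns an orthogonal matrix with det = +1.
    """
    k = _as_vec3(axis)
    n = float(np.linalg.norm(k))
    if abs(n - 1.0) > FRAME_TOL:
        raise FrameError(f"rotation axis must be unit length, |axis| = {n!r}")
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    skew = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.outer(k, k) * (1.0 - c) + np.eye(3) * c + skew * s


def direction_vector(
    frame: Frame, angles: DirectionAngles | tuple[float, float]
) -> np.ndarray:
    """Unit force-direction vector ẑ_αβ in global coordinates.

    Applies the two sequential Rodrigues rotations: A(α about x̂00) takes the
    frame's z-versor to ẑ_α0 and its y-versor to ŷ_α0; B(β about ŷ_α0)
    then takes ẑ_α0 to ẑ_αβ.  (0, 0) returns the frame's z-versor.
    """
    a, b = angles.as_tuple() if isinstance(angles, DirectionAngles) else angles
    A = rotation_about_axis(frame.x_hat, a)
    y_a0 = A @ frame.y_hat
    z_a0 = A @ frame.z_hat
    B = rotation_about_axis(y_a0, b)
    return B @ z_a0


def angles_from_direction(frame: Frame, v: Sequence[float]) -> DirectionAngles:
    """Recover (alpha, beta) from a unit direction vector.

    beta = arcsin(v·x̂), alpha = atan2(−v·ŷ, v·ẑ) in the frame basis; the
    inverse of :func:`direction_vector` (closed form of the two rotations:
    ẑ_αβ = sin β x̂ − cos β sin α ŷ + cos β cos α ẑ).  Directions with
    alpha outside [−90°, 90°] have an in-range representative at −v; use
    :func:`canonical_angles` to resolve the sign automatically.  At gimbal
    lock (|beta| = 90°) alpha is undefined and reported as 0 with the
    ``degenerate`` flag set.
    """
    u = _as_vec3(v)
    n = float(np.linalg.norm(u))
    if abs(n - 1.0) > FRAME_TOL:
        raise FrameError(f"direction must be a unit vector, |v| = {n!r}")
    sx = float(np.clip(np.dot(u, frame.x_hat), -1.0, 1.0))
    beta = math.degrees(math.asin(sx))
    cy = float(np.dot(u, frame.y_hat))
    cz = float(np.dot(u, frame.z_hat))
    if math.hypot(cy, cz) < 1e-12:
        return DirectionAngles(alpha=0.0, beta=beta, degenerate=True)
    alpha = math.degrees(math.atan2(-cy, cz))
    return DirectionAngles(alpha=alpha, beta=beta)


def canonical_angles(frame: Frame, v: Sequence[float]) -> DirectionAngles:
    """Angles of the representative of ±v with alpha in [−90°, 90°].

    Prefers the sign giving alpha in range; when both qualify (alpha = ±90°
    boundary) the representative with cos β cos α ≥ 0 is kept.
    """
    u = _as_vec3(v)
    cand = [angles_from_direction(frame, u), angles_from_direction(frame, -u)]
    ok = [c for c in cand if abs(c.alpha) <= 90.0 + 1e-12]
    if len(ok) == 1:
        return ok[0]
    pool = ok if ok else cand
    key = lambda c: math.cos(math.radians(c.beta)) * math.cos(math.radians(c.alpha))
    return max(pool, key=key)


def angle_between(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between two vectors, degrees in [0, 180]."""
    a, b = _as_vec3(u), _as_vec3(v)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise FrameError("angle_between requires nonzero vectors")
    c = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(c))


def angle_grid(
    step: float = 15.0, lo: float = -90.0, hi: float = 90.0
) -> list[DirectionAngles]:
    """Cartesian (alpha, beta) grid, beta-major order (beta varies slowest).

    The default 15° step over [−90°, 90°] yields 13 × 13 = 169 pairs,
    including (0°, 0°).
    """
    span = hi - lo
    n = span / step
    if abs(n - round(n)) > 1e-9:
        raise FrameError(f"step {step} does not divide the span [{lo}, {hi}]")
    vals = [lo + step * i for i in range(int(round(n)) + 1)]
    return [DirectionAngles(alpha=a, beta=b) for b in vals for a in vals]


def _wrap180(a: float) -> float:
    """Wrap an angle into (−180, 180]."""
    w = math.fmod(a + 180.0, 360.0)
    if w <= 0.0:
        w += 360.0
    return w - 180.0


def symmetry_image(
    angles: DirectionAngles | tuple[float, float],
) -> tuple[DirectionAngles, int]:
    """In-range equivalent of an out-of-range angle pair, with a phase sign.

    The rotation algebra satisfies two exact identities (asserted in tests):
    ẑ(α+180°, β+180°) = +ẑ(α, −β) and ẑ(α+180°, β) = −ẑ(α, −β).  Given a
    pair outside [−90°, 90°]², this reduces it to an in-range representative
    and reports the sign relating the two direction vectors: +1 means the
    vectors coincide (identical response phase), −1 means they are
    antiparallel (reversed phase under a linear model).  In-range input is
    returned unchanged with sign +1.
    """
    a, b = angles.as_tuple() if isinstance(angles, DirectionAngles) else angles
    a, b = _wrap180(a), _wrap180(b)
    sign = 1
    # beta period: z(α, β+180) = −z(α, β)
    if b > 90.0:
        b -= 180.0
        sign = -sign
    elif b < -90.0:
        b += 180.0
        sign = -sign
    # alpha shift: z(α+180, β) = −z(α, −β)
    if a > 90.0:
        a -= 180.0
        b = -b
        sign = -sign
    elif a < -90.0:
        a += 180.0
        b = -b
        sign = -sign
    # verify against the actual rotation algebra (cheap, frame-independent)
    v_in = direction_vector(GLOBAL_FRAME, angles)
    v_out = direction_vector(GLOBAL_FRAME, (a, b))
    got = 1 if float(np.dot(v_in, v_out)) > 0 else -1
    if got != sign or np.linalg.norm(v_in - got * v_out) > 1e-9:
        raise FrameError(
            f"symmetry reduction failed for input {angles}: expected sign "
            f"{sign}, vectors disagree"
        )
    return DirectionAngles(alpha=a, beta=b), sign


def grid_to_frame(grid: Iterable[DirectionAngles], frame: Frame) -> "np.ndarray":
    """Stack global-coordinate ẑ_αβ direction vectors for a grid, (n, 3)."""
    return np.array([direction_vector(frame, g) for g in grid])


def export_grid_csv(path, grid: Sequence[DirectionAngles], frame: Frame) -> None:
    """Write a direction grid as CSV: alpha_deg, beta_deg, zx, zy, zz."""
    import pandas as pd

    vecs = grid_to_frame(grid, frame)
    df = pd.DataFrame(
        {
            "alpha_deg": [g.alpha for g in grid],
            "beta_deg": [g.beta for g in grid],
            "zx": vecs[:, 0],
            "zy": vecs[:, 1],
            "zz": vecs[:, 2],
        }
    )
    df.to_csv(path, index=False)
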