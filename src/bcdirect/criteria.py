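"""Direction-dependence criteria over the stimulation-angle grid.

For each stimulation direction (α, β) and frequency f the pipeline produces
two scalar amplitudes: |V_αβ(f)| (membrane volume displacement, mm³) and
|w̄_αβ(f)| (averaged rim displacement along the window normal, mm — the
modulus of the complex triangle-averaged translation).  Per frequency, the
amplitudes are normalized by their grid maximum, a weight

    μ^f = 1 − min/max

measures how much the direction matters at that frequency (μ → 1: strongly
directional; μ → 0: direction-independent), and the single-figure criteria
are weighted sums over the frequency set:

    crit_αβ = Σ_f n_αβ(f) μ^f / Σ_f μ^f ∈ [0, 1].

The grid extremes of both criteria give the four characteristic stimulation
directions; a separate module refines them below the grid resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import DirectionAngles

logger = logging.getLogger("bcdirect")

#: one-third-octave frequency ladder covering the hearing range, Hz
THIRD_OCTAVE_17 = (
    200.0, 300.0, 400.0, 500.0, 630.0, 800.0, 1000.0, 1250.0, 1600.0,
    2000.0, 2500.0, 3150.0, 4000.0, 5000.0, 6300.0, 8000.0, 10000.0,
)


class CriteriaError(ValueError):
    pass


def validate_frequency_set(freqs: Sequence[float]) -> tuple[float, ...]:
    f = tuple(float(x) for x in freqs)
    if len(f) == 0:
        raise CriteriaError("frequency set is empty")
    if any(x <= 0 for x in f):
        raise CriteriaError("frequencies must be positive")
    if any(b <= a for a, b in zip(f, f[1:])):
        raise CriteriaError("frequency set must be strictly increasing")
    return f


@dataclass(frozen=True)
class ResponseSurface:
    """Per-direction, per-frequency response amplitudes.

    ``v_amp`` and ``w_amp`` are (n_directions, n_frequencies) arrays of
    non-negative amplitudes (|V| in mm³, |w̄| in mm) aligned with ``angles``.
    """

    angles: tuple                 # of DirectionAngles
    frequencies: tuple            # Hz, strictly increasing
    v_amp: np.ndarray
    w_amp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", tuple(self.angles))
        object.__setattr__(
            self, "frequencies", validate_frequency_set(self.frequencies)
        )
        shape = (len(self.angles), len(self.frequencies))
        for name in ("v_amp", "w_amp"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != shape:
                raise CriteriaError(f"{name} shape {a.shape}, expected {shape}")
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise CriteriaError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, a)


@dataclass(frozen=True)
class CriterionMap:
    """Weighted-sum criteria per direction plus the per-frequency weights."""

    angles: tuple
    v_crit: np.ndarray
    w_crit: np.ndarray
    mu_v: np.ndarray
    mu_w: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", tuple(self.angles))
        for name in ("v_crit", "w_crit", "mu_v", "mu_w"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


def normalize(amp: np.ndarray, frequencies: Sequence[float]) -> np.ndarray:
    """Divide each frequency column by its grid maximum (per-frequency max 1)."""
    a = np.asarray(amp, dtype=float)
    mx = a.max(axis=0)
    bad = np.nonzero(mx <= 0.0)[0]
    if bad.size:
        fs = ", ".join(str(frequencies[i]) for i in bad)
        raise CriteriaError(f"zero maximum amplitude at frequency {fs} Hz")
    return a / mx


def weight_coefficients(amp: np.ndarray, frequencies: Sequence[float]) -> np.ndarray:
    """μ^f = 1 − min/max of the amplitudes over the grid, per frequency."""
    a = np.asarray(amp, dtype=float)
    mx = a.max(axis=0)
    bad = np.nonzero(mx <= 0.0)[0]
    if bad.size:
        fs = ", ".join(str(frequencies[i]) for i in bad)
        raise CriteriaError(f"zero maximum amplitude at frequency {fs} Hz")
    return 1.0 - a.min(axis=0) / mx


def weighted_criterion(normalized: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """crit_αβ = Σ_f n_αβ(f)·μ^f / Σ_f μ^f."""
    n = np.asarray(normalized, dtype=float)
    m = np.asarray(mu, dtype=float)
    s = m.sum()
    if s <= 0.0:
        raise CriteriaError(
            "all weight coefficients are zero: the response is direction-"
            "independent at every frequency, the weighted criterion is undefined"
        )
    return n @ m / s


def criterion_map(surface: ResponseSurface) -> CriterionMap:
    """Full criterion chain: normalize, weight, and combine both criteria."""
    mu_v = weight_coefficients(surface.v_amp, surface.frequencies)
    mu_w = weight_coefficients(surface.w_amp, surface.frequencies)
    v_crit = weighted_criterion(normalize(surface.v_amp, surface.frequencies), mu_v)
    w_crit = weighted_criterion(normalize(surface.w_amp, surface.frequencies), mu_w)
    return CriterionMap(
        angles=surface.angles, v_crit=v_crit, w_crit=w_crit, mu_v=mu_v, mu_w=mu_w
    )


@dataclass(frozen=True)
class ExtremeRecord:
    criterion: str          # "V" or "w"
    kind: str               # "max" or "min"
    angles: DirectionAngles
    value: float
    tie: bool = False


def _argext(angles, values, kind: str) -> tuple[int, bool]:
    v = np.asarray(values, dtype=float)
    target = v.max() if kind == "max" else v.min()
    idx = np.nonzero(v == target)[0]
    tie = len(idx) > 1
    if tie:
        # deterministic: smallest (|alpha|, |beta|, alpha, beta)
        best = min(
            idx,
            key=lambda i: (
                abs(angles[i].alpha), abs(angles[i].beta),
                angles[i].alpha, angles[i].beta,
            ),
        )
        logger.warning(
            "tie among %d grid points for %s; breaking to (%.0f, %.0f)",
            len(idx), kind, angles[best].alpha, angles[best].beta,
        )
        return int(best), True
    return int(idx[0]), False


def coarse_extremes(cmap: CriterionMap) -> list[ExtremeRecord]:
    """Grid argmax/argmin of both criteria (four records, ties logged)."""
    out = []
    for name, vals in (("V", cmap.v_crit), ("w", cmap.w_crit)):
        for kind in ("max", "min"):
            i, tie = _argext(cmap.angles, vals, kind)
            out.append(
                ExtremeRecord(
                    criterion=name, kind=kind, angles=cmap.angles[i],
                    value=float(vals[i]), tie=tie,
                )
            )
    return out


def b81_force(ofl_db_re_1uN: Sequence[float] | float) -> np.ndarray:
    """Stimulating-force amplitude of a B81 transducer from its output force
    level, F = (2.5/2.83)·10⁻⁶·10^(OFL/20) newtons (OFL in dB re 1 μN)."""
    ofl = np.asarray(ofl_db_re_1uN, dtype=float)
    if not np.all(np.isfinite(ofl)):
        raise CriteriaError("OFL values must be finite")
    return (2.5 / 2.83) * 1e-6 * 10.0 ** (ofl / 20.0)
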