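"""Tuning-curve summary statistics and distributional goodness of fit.

Hand-position curves are scored by mean rate, coding level, the coefficient
of determination of the best linear fit, and a nearest-neighbor complexity
score; size-tuning curves by preferred size, peak rate, suppression index
and normalized participation ratio.  Two fitted distributions are compared
per statistic with the two-sample Kolmogorov-Smirnov distance.

Note the linear-fit R^2 uses the *uncentered* sum of squares in its
denominator (sum of squared responses, not squared deviations from the
mean), so a constant positive curve scores exactly 1.  The conventional
centered version is available via ``centered=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model_feedforward import HandGrid

__all__ = [
    "M1Stats",
    "SizeTuningStats",
    "coding_level",
    "r_squared",
    "complexity_score",
    "m1_stats",
    "size_tuning_stats",
    "ks_distance",
    "RATE_THRESHOLD",
]

RATE_THRESHOLD = 5.0  # Hz; "significantly greater than zero"


@dataclass
class M1Stats:
    mean_rate: float
    coding_level: float
    r_squared: float
    complexity_score: float


@dataclass
class SizeTuningStats:
    preferred_size: float
    max_rate: float
    suppression_index: float
    norm_participation_ratio: float
    degenerate: bool = False


def _check_m1_curve(tc) -> np.ndarray:
    tc = np.asarray(tc, dtype=float)
    if tc.shape != (27,):
        raise ValueError("hand-position tuning curves have 27 conditions")
    return tc


def coding_level(tc) -> float:
    """Fraction of the 27 conditions with rate above 5 Hz."""
    tc = _check_m1_curve(tc)
    return float(np.mean(tc > RATE_THRESHOLD))


def r_squared(tc, grid: HandGrid, centered: bool = False) -> float:
    """1 - SS_res / sum(r^2) for the least-squares linear fit r ~ r0 + m.x.

    Returns NaN for the all-zero curve (0/0).
    """
    tc = _check_m1_curve(tc)
    X = np.column_stack([np.ones(27), grid.stimulus_positions])
    coef, *_ = np.linalg.lstsq(X, tc, rcond=None)
    resid = tc - X @ coef
    denom = np.sum((tc - tc.mean()) ** 2) if centered else np.sum(tc**2)
    if denom == 0.0:
        return float("nan")
    return float(1.0 - np.sum(resid**2) / denom)


def _neighbor_pairs(grid: HandGrid) -> np.ndarray:
    pos = grid.stimulus_positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    i, j = np.nonzero(np.isclose(d2, 1.0))
    keep = i < j
    return np.column_stack([i[keep], j[keep]])


def complexity_score(tc, grid: HandGrid) -> float:
    """SD of |neighbor response differences| after rescaling the curve to [-1, 1].

    Returns NaN for a constant curve (the rescaling is undefined).
    """
    tc = _check_m1_curve(tc)
    lo, hi = tc.min(), tc.max()
    if hi == lo:
        return float("nan")
    scaled = 2.0 * (tc - lo) / (hi - lo) - 1.0
    pairs = _neighbor_pairs(grid)
    diffs = np.abs(scaled[pairs[:, 0]] - scaled[pairs[:, 1]])
    return float(np.std(diffs))


def m1_stats(tc, grid: HandGrid) -> M1Stats:
    tc = _check_m1_curve(tc)
    return M1Stats(
        mean_rate=float(tc.mean()),
        coding_level=coding_level(tc),
        r_squared=r_squared(tc, grid),
        complexity_score=complexity_score(tc, grid),
    )


def size_tuning_stats(tc, sizes) -> SizeTuningStats:
    """Preferred size, peak rate, suppression index, participation ratio."""
    tc = np.asarray(tc, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if tc.shape != sizes.shape:
        raise ValueError("one response per tested size is required")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be sorted strictly ascending")
    if np.any(tc < 0):
        raise ValueError("responses must be non-negative")
    if np.all(tc == 0):
        return SizeTuningStats(float("nan"), 0.0, float("nan"), float("nan"),
                               degenerate=True)
    peak = int(np.argmax(tc))  # ties resolve toward the smaller size
    max_rate = float(tc[peak])
    si = 1.0 - tc[-1] / max_rate
    npr = (tc.sum() ** 2) / (tc.size * np.sum(tc**2))
    return SizeTuningStats(
        preferred_size=float(sizes[peak]),
        max_rate=max_rate,
        suppression_index=float(si),
        norm_participation_ratio=float(npr),
    )


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup-norm CDF distance)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(sps.ks_2samp(a, b, method="asymp").statistic)
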