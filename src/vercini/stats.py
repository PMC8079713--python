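"""Estimation statistics: bootstrap medians, median differences and
violin-plot summaries.

Effect sizes are reported as the difference (or ratio) of medians between two
conditions with a 95% percentile-bootstrap confidence interval, rather than
as a null-hypothesis p value; this keeps the magnitude of an effect in view
alongside its reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class BootstrapEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None


@dataclass(frozen=True)
class ViolinSummary:
    median: float
    q1: float
    q3: float
    adjacent_low: float
    adjacent_high: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _check(sample, min_size, name="sample"):
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size < min_size:
        raise ParameterError(f"{name} needs at least {min_size} values")
    return arr


def _boot_medians(arr, n_boot, rng):
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    return np.median(arr[idx], axis=1)


def bootstrap_median_ci(sample, n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> BootstrapEstimate:
    """Percentile-bootstrap 95% CI of the sample median."""
    arr = _check(sample, 2)
    rng = np.random.default_rng(seed) if rng is None else rng
    meds = _boot_medians(arr, n_boot, rng)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return BootstrapEstimate(float(np.median(arr)), float(lo), float(hi),
                             n_boot, seed)


def median_difference(a, b, n_boot: int = DEFAULT_N_BOOT,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None
                      ) -> BootstrapEstimate:
    """median(b) - median(a) with bootstrap CI (independent resampling)."""
    a = _check(a, 2, "a")
    b = _check(b, 2, "b")
    rng = np.random.default_rng(seed) if rng is None else rng
    diffs = _boot_medians(b, n_boot, rng) - _boot_medians(a, n_boot, rng)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapEstimate(float(np.median(b) - np.median(a)), float(lo),
                             float(hi), n_boot, seed)


def fold_change(a, b, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                rng: np.random.Generator | None = None) -> BootstrapEstimate:
    """median(b) / median(a) with bootstrap CI (independent resampling)."""
    a = _check(a, 2, "a")
    b = _check(b, 2, "b")
    if np.median(a) == 0:
        raise ParameterError("median of the reference sample is zero")
    rng = np.random.default_rng(seed) if rng is None else rng
    denom = _boot_medians(a, n_boot, rng)
    numer = _boot_medians(b, n_boot, rng)
    ratios = numer[denom != 0] / denom[denom != 0]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return BootstrapEstimate(float(np.median(b) / np.median(a)), float(lo),
                             float(hi), n_boot, seed)


def violin_summary(sample) -> ViolinSummary:
    """Median, quartiles (linear interpolation) and adjacent values.

    Adjacent values are the extreme *sample* values still within 1.5 IQR of
    the quartiles — the whisker ends of a violin/box plot.
    """
    arr = _check(sample, 4)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    inside = arr[(arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)]
    return ViolinSummary(float(med), float(q1), float(q3),
                         float(inside.min()), float(inside.max()), arr.size)
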