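"""Division-state classification and condensation-step detection.

A ring progresses through three stages: *nascent* (diffuse, axially thick),
*mature* (condensed but unconstricted) and *constricting*.  Stage is
classified from axial thickness and relative diameter; the condensation
event itself is detected as a variance change point in the axial-thickness
time series, accepted only when the two states differ by at least 50 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

THICKNESS_THRESHOLD_NM = 400.0
REL_DIAMETER_THRESHOLD = 0.9
MIN_STEP_NM = 50.0
PBP2B_THRESHOLD = 0.5
D213A_THICKNESS_THRESHOLD_NM = 356.0  # 1 sd above mean condensed thickness


def classify_state(thickness_nm: float, rel_diameter: float) -> str:
    """Label one frame as nascent, mature or constricting.

    Nascent: thickness > 400 nm.  Mature: thickness <= 400 nm and relative
    diameter >= 0.9.  Constricting: thickness <= 400 nm and relative
    diameter < 0.9.  Equality at either threshold takes the non-nascent /
    mature branch.
    """
    if thickness_nm <= 0 or rel_diameter <= 0:
        raise ParameterError("thickness and rel_diameter must be positive")
    if thickness_nm > THICKNESS_THRESHOLD_NM:
        return "nascent"
    if rel_diameter >= REL_DIAMETER_THRESHOLD:
        return "mature"
    return "constricting"


def classify_states(thickness_nm, rel_diameter) -> list:
    """Vectorised :func:`classify_state` over parallel arrays."""
    return [classify_state(th, rd)
            for th, rd in zip(np.atleast_1d(thickness_nm),
                              np.atleast_1d(rel_diameter))]


def classify_pbp2b_level(normalised_intensity: float) -> str:
    """Septal synthase level: 'low' below 0.5, 'high' at or above."""
    if normalised_intensity < 0:
        raise ParameterError("intensity must be non-negative")
    return "high" if normalised_intensity >= PBP2B_THRESHOLD else "low"


# ---------------------------------------------------------------------------
# Condensation step detection


@dataclass(frozen=True)
class StateSegmentation:
    """Result of one/two-state segmentation of a thickness series."""

    n_states: int
    change_index: int | None  # first index of the second segment
    means: tuple
    sds: tuple


def _segment_cost(n, sd, floor):
    return n * np.log(np.maximum(sd, floor))


def _sd_floor(series) -> float:
    # relative floor keeps log-costs finite on (near-)constant segments
    total_sd = float(np.std(series))
    return max(1e-12, 1e-3 * total_sd, 1e-9 * max(abs(float(np.mean(series))), 1.0))


def split_costs(series, min_seg: int = 3):
    """Two-segment variance-change cost for every admissible split.

    Cost of a segmentation is ``sum_seg n_seg * log(sd_seg)`` (Gaussian
    variance-change likelihood); returned as (split_indices, costs) where a
    split index is the first index of the second segment.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    floor = _sd_floor(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    splits = np.arange(min_seg, n - min_seg + 1)
    n1 = splits.astype(float)
    n2 = n - n1
    m1 = csum[splits] / n1
    m2 = (csum[n] - csum[splits]) / n2
    v1 = np.maximum(csum2[splits] / n1 - m1**2, 0.0)
    v2 = np.maximum((csum2[n] - csum2[splits]) / n2 - m2**2, 0.0)
    costs = _segment_cost(n1, np.sqrt(v1), floor) \
        + _segment_cost(n2, np.sqrt(v2), floor)
    return splits, costs


def detect_condensation_step(thickness_series, min_step_nm: float = MIN_STEP_NM,
                             min_seg: int = 3) -> StateSegmentation:
    """Detect one or two states in an axial-thickness time series.

    The single best change point minimises the variance-change cost over all
    splits; the two-state result is accepted only if the segment means differ
    by at least ``min_step_nm`` (default 50 nm), otherwise one state is
    reported.
    """
    x = np.asarray(thickness_series, dtype=float)
    if x.size < 10:
        raise ParameterError("need at least 10 points for state detection")
    splits, costs = split_costs(x, min_seg=min_seg)
    j = int(splits[np.argmin(costs)])
    m1, m2 = float(np.mean(x[:j])), float(np.mean(x[j:]))
    if abs(m1 - m2) >= min_step_nm:
        return StateSegmentation(2, j, (m1, m2),
                                 (float(np.std(x[:j])), float(np.std(x[j:]))))
    return StateSegmentation(1, None, (float(np.mean(x)),),
                             (float(np.std(x)),))


# ---------------------------------------------------------------------------
# Partially condensed (GTPase-mutant) rule and trajectory alignment


def d213a_low_thickness(thickness_series, t_constriction_start,
                        times=None,
                        threshold_nm: float = D213A_THICKNESS_THRESHOLD_NM
                        ) -> bool:
    """Low-thickness rule for rings without a clean condensation step.

    True iff the thickness drops below ``threshold_nm`` (default 356 nm) for
    at least one sample before the start of constriction.  ``times`` defaults
    to the sample index.
    """
    x = np.asarray(thickness_series, dtype=float)
    t = np.arange(x.size) if times is None else np.asarray(times, dtype=float)
    if not (t[0] <= t_constriction_start <= t[-1]):
        raise ParameterError("constriction start must lie within the series")
    pre = x[t < t_constriction_start]
    return bool(np.any(pre < threshold_nm))


def align_to_constriction(trajectories, t0s) -> list:
    """Shift each trajectory's time axis so constriction starts at t = 0.

    ``t0s`` holds one start time per trajectory; trajectories with a missing
    (None/NaN) start are skipped with a warning.  Sample spacing is preserved
    exactly (no resampling).
    """
    if len(trajectories) != len(t0s):
        raise ParameterError("need one t0 per trajectory")
    aligned = []
    for i, (traj, t0) in enumerate(zip(trajectories, t0s)):
        if t0 is None or (isinstance(t0, float) and np.isnan(t0)):
            warnings.warn(f"trajectory {i} has no constriction start; skipped")
            continue
        aligned.append(traj.shifted(-float(t0)))
    return aligned
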