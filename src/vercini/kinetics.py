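"""Constant-synthesis septal constriction kinetics.

For a Gram-positive septum built as a flat plate from the outside in, at
constant total synthesis rate around the leading edge, the leading-edge
diameter follows

    d(t) = d0                                   for t <  t0
    d(t) = sqrt(d0^2 - (4 k / pi) (t - t0))     for t >= t0

where ``d0`` is the unconstricted diameter (nm), ``t0`` the constriction
start time (s) and ``k`` the rate of area addition to the septal plate
(nm^2/s).  The septal plate area pi/4 (d0^2 - d^2) then grows linearly in
time with slope ``k``.

Two summary times are exposed: the conventional effective constriction time
``t_eff = 2 pi d0^2 / k`` used for cross-condition comparisons, and the
geometric completion time ``pi d0^2 / (4 k)`` at which the model diameter
reaches zero (they differ by a fixed factor of 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import FitError, ParameterError
from .trajectory import RingTrajectory


def eval_constriction_model(t, d0: float, t0: float, k: float):
    """Piecewise constriction law, clamped at zero after completion."""
    if d0 <= 0 or k <= 0:
        raise ParameterError("d0 and k must be positive")
    t = np.asarray(t, dtype=float)
    inner = d0 * d0 - (4.0 * k / math.pi) * (t - t0)
    d = np.sqrt(np.clip(inner, 0.0, None))
    return np.where(t < t0, d0, d)


def effective_constriction_time(d0: float, k: float) -> float:
    """Conventional effective constriction time ``2 pi d0^2 / k`` (seconds)."""
    if d0 <= 0 or k <= 0:
        raise ParameterError("d0 and k must be positive")
    return 2.0 * math.pi * d0 * d0 / k


def geometric_completion_time(d0: float, k: float) -> float:
    """Time after t0 at which the model diameter reaches zero: pi d0^2/(4k)."""
    if d0 <= 0 or k <= 0:
        raise ParameterError("d0 and k must be positive")
    return math.pi * d0 * d0 / (4.0 * k)


@dataclass
class ConstrictionFit:
    d0_nm: float
    t0_s: float
    k_nm2_s: float
    rss: float
    converged: bool
    mode: str  # "full" or "post_treatment"

    @property
    def t_eff_s(self) -> float:
        return effective_constriction_time(self.d0_nm, self.k_nm2_s)

    @property
    def t_eff_min(self) -> float:
        return self.t_eff_s / 60.0

    @property
    def completion_time_s(self) -> float:
        return self.t0_s + geometric_completion_time(self.d0_nm, self.k_nm2_s)


def _initial_guess(t, d):
    d0 = float(np.max(d))
    smooth = ndimage.median_filter(d, size=min(5, d.size), mode="nearest")
    below = np.nonzero(smooth < 0.95 * d0)[0]
    t0 = float(t[below[0]]) if below.size else float(t[0])
    # slope of d^2 over the declining portion gives -4k/pi
    dd = d * d
    i0 = below[0] if below.size else 0
    if t[-1] > t[i0]:
        slope = (dd[-1] - dd[i0]) / (t[-1] - t[i0])
    else:
        slope = -1.0
    k = max(-math.pi * slope / 4.0, 1e-6 * d0 * d0)
    return d0, t0, k


def fit_constriction(trajectory, mode: str = "full",
                     t_treat: float | None = None,
                     exclude_after_index: int | None = None
                     ) -> ConstrictionFit:
    """Least-squares fit of the constriction law to a diameter trajectory.

    Parameters
    ----------
    trajectory
        A :class:`RingTrajectory` with diameter data, or a ``(t, d)`` pair.
    mode
        "full" fits the whole trace; "post_treatment" restricts the fit to
        samples at ``t >= t_treat`` (for rapid-perturbation experiments where
        only post-arrival kinetics are of interest).
    exclude_after_index
        Drop samples after this index, e.g. where residual marker signal
        lingers after constriction has completed.
    """
    if isinstance(trajectory, RingTrajectory):
        if trajectory.diameter is None:
            raise FitError("trajectory has no diameter data")
        t, d = trajectory.t, trajectory.diameter
    else:
        t, d = (np.asarray(a, dtype=float) for a in trajectory)
    if exclude_after_index is not None:
        t, d = t[: exclude_after_index + 1], d[: exclude_after_index + 1]
    if mode == "post_treatment":
        if t_treat is None:
            raise ParameterError("post_treatment mode requires t_treat")
        keep = t >= t_treat
        t, d = t[keep], d[keep]
    elif mode != "full":
        raise ParameterError("mode must be 'full' or 'post_treatment'")
    if t.size < 6:
        raise FitError("need at least 6 usable diameter samples")
    if float(np.ptp(d)) <= 1e-12 * max(abs(float(d[0])), 1.0):
        return ConstrictionFit(float(d[0]) if d[0] > 0 else 1e-9, float(t[0]),
                               1e-9, 0.0, converged=False, mode=mode)

    d0g, t0g, kg = _initial_guess(t, d)
    span = float(t[-1] - t[0])

    def residual(p):
        return eval_constriction_model(t, p[0], p[1], p[2]) - d

    lower = [1e-6, t[0] - 2 * span, 1e-12]
    upper = [np.inf, t[-1] + span, np.inf]
    p0 = np.clip([d0g, t0g, kg], lower, upper)
    sol = optimize.least_squares(residual, p0, bounds=(lower, upper),
                                 method="trf", xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15, x_scale=[d0g, max(span, 1.0), kg],
                                 max_nfev=2000)
    return ConstrictionFit(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]),
                           float(np.sum(sol.fun**2)), bool(sol.status > 0),
                           mode=mode)
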