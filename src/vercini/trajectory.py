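"""Per-ring time-series container shared by the kinetics and state modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

#: Unconstricted septum diameter (nm); fallback reference for relative diameter.
DEFAULT_D0_NM = 1100.0


@dataclass
class RingTrajectory:
    """Time series of ring geometry and intensity for one dividing cell.

    ``t`` in seconds unless stated otherwise by the producer; ``diameter`` and
    ``thickness`` in nm; ``septal_density`` in ADU/nm.  Optional fields stay
    ``None`` when a measurement stage does not produce them.  ``ground_truth``
    carries generator parameters for synthetic trajectories.
    """

    t: np.ndarray
    diameter: np.ndarray | None = None
    thickness: np.ndarray | None = None
    septal_density: np.ndarray | None = None
    total_intensity: np.ndarray | None = None
    state: list | None = None
    ground_truth: dict | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ParameterError("times must be strictly increasing")
        for name in ("diameter", "thickness", "septal_density",
                     "total_intensity"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.t.shape:
                    raise ParameterError(f"{name} must match t in length")
                setattr(self, name, val)

    def __len__(self):
        return self.t.size

    def rel_diameter(self, reference_nm: float | None = None,
                     t_constriction_start: float | None = None) -> np.ndarray:
        """Diameter relative to the unconstricted reference.

        The reference defaults to the median diameter over the
        pre-constriction portion of this trajectory (if a start time is
        given), falling back to the population value of 1100 nm.
        """
        if self.diameter is None:
            raise ParameterError("trajectory has no diameter data")
        if reference_nm is None:
            if t_constriction_start is not None:
                pre = self.diameter[self.t < t_constriction_start]
                reference_nm = (float(np.median(pre)) if pre.size
                                else DEFAULT_D0_NM)
            else:
                reference_nm = DEFAULT_D0_NM
        if reference_nm <= 0:
            raise ParameterError("reference diameter must be positive")
        return self.diameter / reference_nm

    def shifted(self, dt: float) -> "RingTrajectory":
        """Copy with the time axis shifted by ``dt`` (no resampling)."""
        return replace(self, t=self.t + dt)
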