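"""Detect the ring-condensation step in an axial-thickness time series.

A diffuse nascent ring (~600 nm thick, noisy) collapses into a condensed
ring (~330 nm, quieter).  The detector finds the single best variance
change point and accepts it only if the two states differ by >= 50 nm.
"""

import numpy as np

from vercini import detect_condensation_step, simulate_thickness_trace

rng = np.random.default_rng(3)
x = simulate_thickness_trace(mean_pre=600, sd_pre=80, mean_post=330,
                             sd_post=30, step_index=60, n=120, rng=rng)
seg = detect_condensation_step(x)
print(f"{seg.n_states} states detected")
print(f"condensation at frame {seg.change_index} (truth: 60)")
print(f"thickness {seg.means[0]:.0f} -> {seg.means[1]:.0f} nm "
      f"(sd {seg.sds[0]:.0f} -> {seg.sds[1]:.0f})")

# a 30 nm drop fails the 50 nm acceptance rule: one state is reported
y = simulate_thickness_trace(600, 80, 570, 30, step_index=60, n=120, rng=rng)
print(f"30 nm step: {detect_condensation_step(y).n_states} state(s)")
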