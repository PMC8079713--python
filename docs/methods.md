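# Methods

This note documents the models implemented in `vercini`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real microscopy data.

## Ring image model and fitting

An end-on image of a division ring is modelled as a 12-sectored annulus
plus a diffuse cytoplasmic background. In polar coordinates about the ring
centre (x₀, y₀):

- signal: `A_i(θ) · exp(−(r − R₀)²/2σ²)`, with sector *i* covering
  [30i°, 30(i+1)°) and one non-negative amplitude per sector;
- background: isotropic Gaussian (amplitude a, width σ_bg1) + Cauchy
  (amplitude b, scale σ_bg2) + constant c, sharing the ring centre.

Coordinate convention: pixel centres at integer coordinates, origin top
left, x rightward, y downward; θ counterclockwise from +x (so
`y = y₀ − r sinθ` in array coordinates).

**Separable fitting.** All 15 amplitudes (12 sectors, a, b, c) enter the
model linearly. The fit therefore optimises only the six nonlinear
geometry parameters (x₀, y₀, R₀, σ, σ_bg1, σ_bg2) with a bounded
trust-region least-squares method, solving for the amplitudes by
non-negative least squares at every step (variable projection). This is
markedly more robust than a joint 21-parameter fit: the amplitude/geometry
trade-offs that trap a joint fit in local minima are eliminated by
re-solving the linear subproblem exactly. Background widths are bounded
below at 1 px; widths below that are unphysical and open a degenerate
trade-off between the annulus and the central background bump.

**Initialisation** (per-frame warm start from the previous frame when
fitting stacks): centre from the intensity centroid; R₀ from the argmax of
the high-pass-filtered radial average profile; σ = 2 px; the constant
offset from the border median. σ may be held fixed instead of fitted
(`fit_sigma=False`); fitted is the default.

**"No ring detected"** is decided by a nested-model comparison rather than
a bare amplitude threshold: the frame is refitted with the annulus removed
(background only, widths seeded by a coarse grid search because the
Gaussian/Cauchy width pair is itself weakly identified), and the ring is
rejected when adding the annulus improves the residual sum of squares by
less than `5 × 14 × rss/N` — roughly five times what its 14 extra degrees
of freedom would absorb from pure noise. This is the operational meaning
of "total annulus amplitude below the noise floor".

**Known bias.** Hard 30° sector edges make the objective discontinuous
when a boundary pixel changes sector as the centre moves; amplitudes of
sectors adjacent to a strong contrast carry a few-ADU uncertainty on that
account, while the geometry remains accurate to < 0.05 px. Separately, a
point source on a circle, azimuthally averaged, peaks slightly inside the
true radius (≈ σ_psf²/2R), so ring radii fitted to time-averaged sparse
filament movies underestimate the true filament orbit by a few percent.
Angular positions and hence angular speeds are unaffected; the nm/s
conversion inherits the small radius bias, well inside the 10% recovery
tolerance.

## Kymographs

For each frame the fitted background is subtracted and the image sampled by
bilinear interpolation on the fitted circle at 1°/column (360 columns),
rows ordered by time. A single-radius line profile is used (no radial band
averaging). Frames without a usable fit yield NaN rows; they are never
interpolated. For display, the kymograph may be doubled to 0–720° (two
revolutions side by side) so trajectories crossing the 0°/360° seam remain
readable. The per-ring intensity summary is the median over all kymograph
pixels of the first 60 frames.

## Ridge filter and trace metrics

The ridge filter is a Gaussian blur at the feature scale (default 2 px =
130 nm) followed by the major (largest-absolute-value) eigenvalue of the
Hessian per pixel, second derivatives by central finite differences;
boundaries are periodic in angle and replicated in time. Bright ridges give
strongly negative centreline values; a display option negates the output.
The signed output is kept because sign carries the bright/dark distinction.

Automated filament tracking is deliberately not implemented — at cellular
filament densities trackers fragment trajectories and miss immobile
filaments — so traces enter as annotations (CSV line ROIs) or simulator
ground truth. A trace's speed is |total unwrapped angular displacement| ×
radius / total time (not per-segment averages), matching how a single line
ROI is measured; angles are unwrapped by the minimal consistent step.
Filaments below 10 nm/s are classed immobile (strict inequality at 10).

**Guided re-measurement.** To score the pipeline against ground truth, each
simulated filament's track seeds a trace that is snapped per frame to the
nearest intensity peak of the kymograph row (blurred along the angle axis
only) within ±8°, refined by parabolic interpolation, and summarised by a
Theil–Sen regression slope. Row-wise (angle-only) blurring matters: with a
2-D blur, a filament's birth or death displaces the ridge-filtered maxima
outward along the trace at its ends, stretching short traces and inflating
speeds by ~8%; per-row peaks have no such end effect. Traces shorter than
10 frames are not measured — an annotator would not trace them either, and
their slope noise dominates the immobile/mobile classification.

## Horizontal-cell line profiles

Profiles are taken after rotating the image about the ring centroid
(bilinear interpolation) so the septal axis is horizontal, averaging ±2 px
(5 rows) about the centroid on each axis.

**Diameter (tilted-circle model).** A uniform-intensity circle of diameter
d viewed edge-on projects to line density ∝ 1/√((d/2)² − u²), |u| < d/2,
with integrable rim singularities. The projection is integrated exactly
per fine-grid bin via the arcsine antiderivative (so total intensity is
conserved to better than 0.1% for any d), convolved with a Gaussian PSF,
resampled to the profile grid and fitted by least squares for (d, centre,
total intensity, baseline, PSF width). The PSF width may be fixed or
fitted; fitted is the default. This functional form is the unique
line-of-sight projection of a uniform circle seen edge-on.

**Axial thickness.** The axial profile is fitted to a super-Gaussian
`A·exp(−((x−x₀)²/2σ²)^P) + baseline` with P ≥ 1 (initialised at 1, fitted
freely); thickness is the FWHM `2√2·σ·(ln 2)^(1/2P)`. With P fixed at 1
this reduces exactly to a Gaussian fit (FWHM = 2.3548σ).

**Septal density** is the baseline-subtracted sum of the lateral profile
divided by the ring circumference πd, in ADU/nm.

## Division states and condensation

Per-frame labels: nascent (thickness > 400 nm), mature (≤ 400 nm, relative
diameter ≥ 0.9), constricting (≤ 400 nm, < 0.9). The thresholds quoted are
open intervals in their source; equality is assigned to the non-nascent /
mature branch and documented here. Relative diameter is taken against the
median pre-constriction diameter of the same trajectory, falling back to
1100 nm (the population mean unconstricted diameter) when no
pre-constriction samples exist. Labels are per-frame; no smoothing or
hysteresis is applied.

**Condensation step.** The thickness series is segmented by a single change
point minimising the variance-change cost Σ n_seg·log(SD_seg) over all
splits (minimum segment 3 points; SDs floored at 10⁻³ of the series SD to
keep logs finite on near-constant segments). The two-state result is
accepted only if the segment means differ by ≥ 50 nm, otherwise one state
is reported. The implementation uses cumulative sums; an independent
exhaustive search with the identical cost is the test oracle, and the two
agree on every random series tried (500 series up to 200 points).

**Partially condensed rings** that never show a clean step are flagged
"low thickness" if any pre-constriction sample drops below 356 nm (one SD
above the mean condensed wild-type thickness) for at least one frame.

Per-synthase level, normalised septal intensity ≥ 0.5 is "high", below is
"low"; trajectories are aligned by shifting each time axis so constriction
starts at t = 0, without resampling.

## Constriction kinetics

`d(t) = d₀` for t < t₀ and `√(d₀² − (4k/π)(t−t₀))` after, clamped at zero:
under outside-in synthesis of a flat plate, the septal plate area
π/4·(d₀² − d²) grows linearly at rate k. Fits use bounded least squares
over (d₀, t₀, k); t₀ is initialised at the first time the median-filtered
trajectory drops below 0.95 of its maximum and k from the two-point slope
of d². Measured diameters below the resolution floor are retained — the
model, not the data, is clamped. Post-treatment mode fits only samples at
t ≥ t_treat (for rapid-perturbation experiments); an exclusion index cuts
trailing samples where residual marker signal lingers after completion. A
constant trajectory leaves t₀ unidentifiable and is returned flagged, not
raised.

Two summary times are computed and labelled: the conventional effective
constriction time t_eff = 2π·d₀²/k used for cross-condition comparisons,
and the model's geometric completion time π·d₀²/(4k); the first exceeds the
second by exactly 8 for any parameters. Both are exposed; comparisons
default to t_eff. Times are reported in minutes at the interface, seconds
internally.

## Estimation statistics

Percentile bootstrap (2.5/97.5) of the median or of a difference/ratio of
medians, default 10 000 resamples, deterministic under a fixed seed.
Quartiles use the linear-interpolation convention; violin summaries report
median, quartiles and adjacent values (extreme sample values within
1.5×IQR of the quartiles). Coverage of the median CI measured on Gaussian
samples of n = 50 is 94–95%, inside the 95 ± 2% band the package asserts.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions:

| parameter | default | meaning |
|---|---|---|
| ring_diameter_nm | 1100 | unconstricted septum diameter |
| pixel_size_nm | 65 | effective pixel of the custom microscope |
| frame_interval_s | 1 | treadmilling imaging rate |
| filament_density | 1.3 | mean filaments/ring/frame (nascent); presets 3.3, 6.5, 37.5 |
| mean_lifetime_s | 30 | exponential filament lifetime |
| immobile_fraction | 0.35 | nascent-ring immobile fraction |
| speed sampler | lognormal, median 30 nm/s, IQR 22–41 | mobile treadmilling speeds |
| filament_photons | 2000 | photons/filament/frame |
| psf_sigma_nm | 130 | PSF width (2 px), matching the ridge-filter scale |
| camera_gain / read noise / offset | 2 ADU/photon, 3 ADU, 100 ADU | camera model |

Mobile speeds default to a lognormal parameterised by target median and
IQR (values chosen to represent a treadmilling population with ~30 nm/s
median); an empirical table sampler supports bootstrap resampling of
measured speeds. Filament counts per frame are Poisson; the continuous-time
process is birth–death with births at rate density/lifetime and exponential
lifetimes, whose stationary population is drawn directly at t = 0
(memoryless residual lifetimes), so the time-averaged count equals the
configured density without burn-in. Immobile filaments get a uniform speed
in [0, 10) nm/s rather than exactly zero, matching the operational
definition of immobility; treadmilling direction is ±1 with equal
probability. Filaments render as isotropic 2-D Gaussians of integral
`filament_photons` on the Eq-style background; camera noise is
Poisson × gain + Gaussian read noise + offset, quantized and floored at
0 ADU. Identical config + seed reproduces stacks bit-for-bit.

The published simulated densities label 6.5 as twice and 37.5 as twelve
times the mature density 3.3 although 2×3.3 = 6.6 and 12×3.3 = 39.6; the
printed values are used verbatim as presets.

**What the synthetic tests do not show.** The generator draws point-like
filaments of fixed brightness on an ideal circle with a Gaussian PSF and a
perfectly matching background model; real data add finite filament length,
photobleaching, focus drift, cell tilt, background mismatch and
registration error. Passing recovery tests therefore validate the
estimators against their own forward models (correctness, calibration,
convergence), not robustness to every real-world artefact. Filament
collision/aggregation dynamics are observed phenomena but are not
simulated.

## Problem sizes and numerics

Default test/validation scales, chosen to give tight statistics at
interactive runtimes: 40 simulated movies × 120 frames for end-to-end
speed recovery (≈ 180 traces), 100 seeded replicates for noisy
constriction recovery, 500 random series for change-point/oracle
agreement, 1000 replicates × 1000 resamples for bootstrap coverage.
Optimisers run with tolerances 10⁻¹²–10⁻¹⁵ and explicit parameter scales;
any least-squares scheme achieving the documented recovery tolerances is
conforming. Ties in the change-point search resolve to the earliest split;
boundary conventions at 400 nm, 0.9, 0.5 and 10 nm/s are stated above.

## Scope limits

No cell segmentation, registration or denoising (inputs are registered,
cropped ROIs); no multi-ring fields; no automated filament tracking; no
Gram-negative (hemispherical-cap) constriction models; no simulation of
side-on cell images (horizontal-cell analysis is validated on 1-D profile
synthetics).
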