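# vercini

Quantitative analysis of bacterial division-ring dynamics from fluorescence
microscopy: sub-pixel septal ring fitting and circumferential kymograph
extraction for end-on imaged cells, filament treadmilling speed
quantification, division-state classification, septal constriction kinetics,
and bootstrap estimation statistics — together with a synthetic-data
generator that emulates the imaging and kinetic models, so the whole
pipeline can be exercised and validated end to end without microscope data.

## Who it is for

Cell biologists and biophysicists measuring FtsZ (or other septal protein)
dynamics in rod-shaped bacteria imaged end-on (the division septum rotated
into the imaging plane) or side-on (time-lapse of constriction), who need a
tested, scriptable replacement for ad-hoc image analysis.

## The models at its core

**Ring image model.** Each frame of a vertically trapped cell is fitted to
`F(x, y) = Signal(x, y) + Bg(x, y)` where the signal is a 12-sectored
annulus in polar coordinates about the sub-pixel ring centre (x₀, y₀),

    Signal(r, θ) = A_i(θ) · exp(−(r − R₀)² / 2σ²),

with one free amplitude per 30° sector, and the cytoplasmic background is a
Gaussian plus a Cauchy plus a constant,

    Bg = a·exp(−r²/2σ²_bg1) + b·σ²_bg2/(r² + σ²_bg2) + c.

Sampling the background-subtracted image along the fitted circle per frame
gives a kymograph (angle × time) in which a treadmilling filament is a
sloped ridge; ridge slope × ring radius is its speed in nm/s. Filaments
slower than 10 nm/s count as immobile. A Hessian ridge filter (Gaussian
blur at the feature scale, then the major eigenvalue of the Hessian per
pixel) makes dim ridges annotatable.

**Constriction kinetics.** Assuming outside-in synthesis of a flat septal
plate at constant total rate *k* (nm²/s), the leading-edge diameter follows

    d(t) = d₀                         for t < t₀
    d(t) = √(d₀² − (4k/π)(t − t₀))    for t ≥ t₀.

Fits report d₀, t₀, k and the effective constriction time
t_eff = 2π·d₀²/k used to compare conditions.

**State classification.** Nascent: axial thickness > 400 nm; mature:
thickness ≤ 400 nm and relative diameter ≥ 0.9; constricting: thickness
≤ 400 nm and relative diameter < 0.9. Ring condensation is detected as a
variance change point in the thickness series, accepted only when the two
states differ by ≥ 50 nm.

**Statistics.** Effect sizes are medians and median differences with 95%
percentile-bootstrap confidence intervals (estimation statistics), not
p values.

## Worked example

`examples/simulate_and_measure_speeds.py` simulates a 120-frame movie of a
1100 nm ring at nascent density (1.3 filaments/ring/frame, 35% immobile),
fits the ring model, extracts the kymograph and re-measures each filament:

```
simulated 120 frames, 12 filaments
fitted ring diameter: 1062 nm (truth 1100 nm)

measured 9 traces (>= 10 frames):
...
median speed 32.1 nm/s (ground truth 32.3); immobile fraction 22% (configured 35%)
```

The fitted diameter sits a few percent under the truth because the
azimuthally averaged point-spread function of filaments on a circle peaks
slightly inside the true radius; speeds, being angular slopes, are
unaffected. On a single movie the immobile fraction carries large binomial
error (here 2 of 9 traces); across 30+ movies it converges to the
configured value (see the reproduction script below). The other examples
cover constriction fitting, condensation-step detection, line-profile
measurements and estimation statistics, each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library for shell use:

```sh
vercini simulate --out-dir out --seed 1
vercini fit-rings out/movie.tif --out out/ring
vercini speeds traces.csv --radius 550 --out metrics.csv
vercini constrict traj.csv --out fits.csv
```

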