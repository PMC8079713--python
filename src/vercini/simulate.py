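"""Synthetic data generator for every pipeline stage.

Emulates end-on movies of a bacterial division ring: sub-diffraction
treadmilling filaments move around a circle of configurable diameter, sitting
on a diffuse Gaussian + Cauchy cytoplasmic background, imaged through a
Gaussian PSF with shot noise, camera gain and read noise.  Also generates
constriction trajectories (constant-synthesis kinetics plus Gaussian noise)
and two-state axial-thickness series for the condensation-step detector.

Every generator is deterministic given its seed; ground truth is returned
alongside each synthetic dataset so downstream estimators can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ParameterError
from .ringfit import BackgroundParams, eval_background
from .trajectory import RingTrajectory

IMMOBILE_SPEED_NM_S = 10.0  # operational definition: immobile if speed < 10 nm/s

#: Ring-averaged filament densities (filaments/ring/frame) measured for
#: nascent, mature, 2x mature and 12x mature rings.
DENSITY_PRESETS = {"nascent": 1.3, "mature": 3.3, "mature_2x": 6.5,
                   "mature_12x": 37.5}


# ---------------------------------------------------------------------------
# Speed samplers


class SpeedSampler:
    """Draws treadmilling speeds (nm/s) for mobile filaments."""

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class LognormalSpeedSampler(SpeedSampler):
    """Lognormal speeds parameterised by target median and interquartile range."""

    median: float = 30.0
    iqr: tuple = (22.0, 41.0)

    def __post_init__(self):
        q1, q3 = self.iqr
        if self.median <= 0 or q1 <= 0 or q3 <= q1:
            raise ParameterError("need median > 0 and 0 < q1 < q3")

    def sample(self, n, rng):
        q1, q3 = self.iqr
        mu = math.log(self.median)
        # q3/q1 = exp(sigma * (z75 - z25)), z75 - z25 = 1.34898
        sigma = math.log(q3 / q1) / 1.3489795003921634
        return rng.lognormal(mu, sigma, size=n)


@dataclass(frozen=True)
class EmpiricalSpeedSampler(SpeedSampler):
    """Bootstrap resampling from a measured speed table."""

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in np.atleast_1d(self.values))
        if len(vals) == 0:
            raise ConfigError("empirical speed table is empty")
        object.__setattr__(self, "values", vals)

    def sample(self, n, rng):
        arr = np.asarray(self.values)
        return arr[rng.integers(0, arr.size, size=n)]


def constant_speed(value: float) -> EmpiricalSpeedSampler:
    """A degenerate sampler returning ``value`` always."""
    return EmpiricalSpeedSampler((float(value),))


# ---------------------------------------------------------------------------
# Configuration and ground truth


def default_background() -> BackgroundParams:
    """Cytoplasmic background in photon units for a typical nascent ring."""
    return BackgroundParams(a=30.0, sigma1_px=6.0, b=20.0, sigma2_px=10.0,
                            c=2.0)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a synthetic ring movie.

    Defaults describe a nascent ring on the custom microscope: 1100 nm ring,
    65 nm pixels, 1 frame/s, 1.3 filaments/ring/frame of which 35% are
    immobile, with mobile speeds drawn from a lognormal (median 30 nm/s).
    """

    ring_diameter_nm: float = 1100.0
    pixel_size_nm: float = 65.0
    frame_interval_s: float = 1.0
    n_frames: int = 120
    filament_density: float = 1.3
    mean_lifetime_s: float = 30.0
    immobile_fraction: float = 0.35
    speed_sampler: SpeedSampler = field(default_factory=LognormalSpeedSampler)
    filament_photons: float = 2000.0
    psf_sigma_nm: float = 130.0
    background: BackgroundParams = field(default_factory=default_background)
    camera_gain: float = 2.0
    read_noise_adu: float = 3.0
    offset_adu: float = 100.0
    field_size_px: int | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("ring_diameter_nm", "pixel_size_nm", "frame_interval_s",
                     "mean_lifetime_s", "filament_photons", "psf_sigma_nm",
                     "camera_gain"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_frames <= 0:
            raise ParameterError("n_frames must be positive")
        if self.filament_density < 0:
            raise ParameterError("filament_density must be non-negative")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ParameterError("immobile_fraction must lie in [0, 1]")
        if self.read_noise_adu < 0 or self.offset_adu < 0:
            raise ParameterError("read noise and offset must be non-negative")

    @property
    def ring_radius_nm(self) -> float:
        return self.ring_diameter_nm / 2.0

    @property
    def ring_radius_px(self) -> float:
        return self.ring_radius_nm / self.pixel_size_nm

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def field_px(self) -> int:
        if self.field_size_px is not None:
            return self.field_size_px
        return int(math.ceil(4.8 * self.ring_radius_px)) | 1  # odd


@dataclass(frozen=True)
class GroundTruthFilament:
    """True trajectory of one simulated filament on the ring."""

    birth_time: float
    death_time: float
    initial_angle_deg: float
    speed: float
    direction: int
    immobile: bool

    def __post_init__(self):
        if self.death_time <= self.birth_time:
            raise ParameterError("death_time must exceed birth_time")
        if self.speed < 0:
            raise ParameterError("speed must be non-negative")
        if self.immobile and self.speed >= IMMOBILE_SPEED_NM_S:
            raise ParameterError("immobile filaments must have speed < 10 nm/s")

    def angle_at(self, t, radius_nm: float):
        """Angle (degrees, mod 360) at time ``t`` seconds."""
        t = np.asarray(t, dtype=float)
        omega_deg = math.degrees(self.speed / radius_nm) * self.direction
        return (self.initial_angle_deg
                + omega_deg * (t - self.birth_time)) % 360.0

    def alive_at(self, t):
        t = np.asarray(t, dtype=float)
        return (t >= self.birth_time) & (t < self.death_time)


@dataclass
class MovieStack:
    """Multi-frame image stack with physical metadata."""

    frames: np.ndarray  # (n_frames, h, w), ADU
    pixel_size_nm: float
    frame_interval_s: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (t, y, x) array")

    def __len__(self):
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Filament birth-death process


def sample_filament_count(density: float, rng: np.random.Generator) -> int:
    """Poisson filament count with the given ring-average density."""
    if density < 0:
        raise ParameterError("density must be non-negative")
    return int(rng.poisson(density))


def _draw_speed(config: SimConfig, rng) -> tuple[float, bool]:
    if rng.random() < config.immobile_fraction:
        return float(rng.uniform(0.0, IMMOBILE_SPEED_NM_S)), True
    return float(config.speed_sampler.sample(1, rng)[0]), False


def simulate_filaments(config: SimConfig,
                       rng: np.random.Generator | None = None,
                       duration_s: float | None = None) -> list:
    """Stationary birth-death filament population over the movie duration.

    Births arrive at constant rate ``density / mean_lifetime`` and lifetimes
    are exponential, so the steady-state expected count equals the configured
    density.  The population present at t = 0 is drawn directly from the
    stationary law (Poisson count, memoryless residual lifetimes).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if duration_s is None:
        duration_s = config.n_frames * config.frame_interval_s
    tau = config.mean_lifetime_s
    beta = config.filament_density / tau
    filaments = []

    def make(birth, death):
        speed, immobile = _draw_speed(config, rng)
        direction = 1 if rng.random() < 0.5 else -1
        angle0 = float(rng.uniform(0.0, 360.0))
        return GroundTruthFilament(birth, death, angle0, speed, direction,
                                   immobile)

    # stationary population at t = 0
    for _ in range(sample_filament_count(config.filament_density, rng)):
        death = float(rng.exponential(tau))
        if death > 0:
            filaments.append(make(0.0, death))
    # subsequent births
    t = 0.0
    while True:
        t += float(rng.exponential(1.0 / beta)) if beta > 0 else np.inf
        if t >= duration_s:
            break
        death = t + float(rng.exponential(tau))
        if death > t:
            filaments.append(make(t, death))
    return filaments


# ---------------------------------------------------------------------------
# Rendering and camera noise


def render_frame(shape, centre_xy, radius_px, angles_deg, filament_photons,
                 psf_sigma_px, background: BackgroundParams | None = None):
    """Noiseless photon-expectation image of point filaments on a ring.

    Each filament is an isotropic 2-D Gaussian of integral ``filament_photons``
    centred at its position on the circle; the cytoplasmic background is added
    per pixel.  Filaments off the pixel grid are silently clipped by the
    field of view.
    """
    if psf_sigma_px <= 0:
        raise ParameterError("psf_sigma_px must be positive")
    h, w = shape
    x0, y0 = centre_xy
    if background is not None:
        img = eval_background(background, shape, x0, y0)
    else:
        img = np.zeros(shape, dtype=float)
    if len(angles_deg) == 0:
        return img
    y, x = np.mgrid[0:h, 0:w]
    norm = filament_photons / (2.0 * math.pi * psf_sigma_px**2)
    for ang in np.atleast_1d(angles_deg):
        fx = x0 + radius_px * math.cos(math.radians(ang))
        fy = y0 - radius_px * math.sin(math.radians(ang))
        img += norm * np.exp(-((x - fx) ** 2 + (y - fy) ** 2)
                             / (2.0 * psf_sigma_px**2))
    return img


def add_camera_noise(photon_image, gain: float, read_noise_adu: float,
                     offset_adu: float, rng: np.random.Generator):
    """Shot noise + gain + Gaussian read noise + offset, quantized >= 0 ADU."""
    if gain <= 0:
        raise ParameterError("gain must be positive")
    if read_noise_adu < 0:
        raise ParameterError("read noise must be non-negative")
    photon_image = np.asarray(photon_image, dtype=float)
    if np.any(photon_image < 0):
        raise ParameterError("photon expectation must be non-negative")
    adu = rng.poisson(photon_image).astype(float) * gain
    if read_noise_adu > 0:
        adu += rng.normal(0.0, read_noise_adu, size=photon_image.shape)
    adu += offset_adu
    return np.maximum(np.rint(adu), 0.0)


def simulate_ring_movie(config: SimConfig):
    """Full synthetic movie: (MovieStack, ground-truth filament list)."""
    rng = np.random.default_rng(config.seed)
    filaments = simulate_filaments(config, rng)
    n_px = config.field_px()
    centre = ((n_px - 1) / 2.0, (n_px - 1) / 2.0)
    frames = np.empty((config.n_frames, n_px, n_px))
    times = np.arange(config.n_frames) * config.frame_interval_s
    for i, t in enumerate(times):
        angles = [f.angle_at(t, config.ring_radius_nm)
                  for f in filaments if f.alive_at(t)]
        photons = render_frame((n_px, n_px), centre, config.ring_radius_px,
                               angles, config.filament_photons,
                               config.psf_sigma_px, config.background)
        frames[i] = add_camera_noise(photons, config.camera_gain,
                                     config.read_noise_adu, config.offset_adu,
                                     rng)
    stack = MovieStack(frames, config.pixel_size_nm, config.frame_interval_s)
    return stack, filaments


# ---------------------------------------------------------------------------
# Kinetic and thickness traces


def simulate_constriction_trace(d0: float, t0: float, k: float,
                                noise_sd: float, dt: float, n: int,
                                rng: np.random.Generator | None = None
                                ) -> RingTrajectory:
    """Constant-synthesis constriction trajectory plus Gaussian noise.

    The noiseless diameter follows the flat-then-square-root law (clamped at
    zero after completion); ground-truth parameters are recorded on the
    returned trajectory.
    """
    from .kinetics import eval_constriction_model

    if d0 <= 0 or k <= 0 or dt <= 0:
        raise ParameterError("d0, k and dt must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    t = np.arange(n) * dt
    d = eval_constriction_model(t, d0, t0, k)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=n)
    return RingTrajectory(t=t, diameter=d,
                          ground_truth={"d0": d0, "t0": t0, "k": k})


def simulate_thickness_trace(mean_pre: float, sd_pre: float, mean_post: float,
                             sd_post: float, step_index: int, n: int,
                             rng: np.random.Generator | None = None
                             ) -> np.ndarray:
    """Axial-thickness series with one condensation step (or none).

    ``step_index = n`` yields a single-state series entirely at the
    pre-condensation moments.
    """
    if sd_pre < 0 or sd_post < 0:
        raise ParameterError("standard deviations must be non-negative")
    if not 0 <= step_index <= n:
        raise ParameterError("step_index must lie in [0, n]")
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty(n)
    out[:step_index] = mean_pre + sd_pre * rng.standard_normal(step_index)
    out[step_index:] = mean_post + sd_post * rng.standard_normal(n - step_index)
    return out
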