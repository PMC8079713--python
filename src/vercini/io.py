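"""Readers and writers: TIFF movies with YAML sidecar metadata, CSV tables.

CSV is the universal table format (column names are the format contract),
TIFF the image format, YAML the configuration format.  All writes go through
a temp-then-rename step so partially written files never appear under the
target name.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError
from .kymo import FilamentTrace, trace_metrics
from .ringfit import Kymograph, RingFitResult
from .simulate import GroundTruthFilament, MovieStack


def _atomic_write(path, write_fn):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".yaml")


# ---------------------------------------------------------------------------
# Movies


def write_movie(stack: MovieStack, path) -> None:
    """Multi-frame TIFF plus a YAML sidecar with the physical metadata."""
    _atomic_write(path, lambda tmp: tifffile.imwrite(
        tmp, np.asarray(stack.frames, dtype=np.float32)))
    meta = {"pixel_size_nm": float(stack.pixel_size_nm),
            "frame_interval_s": float(stack.frame_interval_s)}
    _atomic_write(_sidecar(path),
                  lambda tmp: Path(tmp).write_text(yaml.safe_dump(meta)))


def read_movie(path, pixel_size_nm: float | None = None,
               frame_interval_s: float | None = None) -> MovieStack:
    """Read a multi-frame TIFF; metadata from args or the YAML sidecar.

    Raises :class:`ConfigError` naming the missing field when neither source
    provides ``pixel_size_nm`` or ``frame_interval_s``.
    """
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ConfigError(f"{path}: expected a 2-D or 3-D TIFF stack")
    sidecar = _sidecar(path)
    meta = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if pixel_size_nm is None:
        pixel_size_nm = meta.get("pixel_size_nm")
    if frame_interval_s is None:
        frame_interval_s = meta.get("frame_interval_s")
    if pixel_size_nm is None:
        raise ConfigError(f"{path}: missing metadata field 'pixel_size'"
                          " (provide pixel_size_nm or a YAML sidecar)")
    if frame_interval_s is None:
        raise ConfigError(f"{path}: missing metadata field 'frame_interval'"
                          " (provide frame_interval_s or a YAML sidecar)")
    return MovieStack(frames, float(pixel_size_nm), float(frame_interval_s))


# ---------------------------------------------------------------------------
# Kymographs


def write_kymograph(kymo: Kymograph, path_prefix) -> None:
    """Write a kymograph as float TIFF and CSV (rows = frames)."""
    prefix = Path(path_prefix)
    _atomic_write(prefix.with_suffix(".tif"), lambda tmp: tifffile.imwrite(
        tmp, kymo.values.astype(np.float32)))
    df = pd.DataFrame(kymo.values,
                      columns=[f"deg_{a:g}" for a in kymo.angles_deg])
    df.insert(0, "frame", np.arange(kymo.n_frames))
    _atomic_write(prefix.with_suffix(".csv"),
                  lambda tmp: df.to_csv(tmp, index=False))


# ---------------------------------------------------------------------------
# Tables

GROUND_TRUTH_COLUMNS = ["filament_id", "birth_s", "death_s", "angle0_deg",
                        "speed_nm_s", "direction", "immobile"]


def write_ground_truth(filaments, path) -> None:
    rows = [{"filament_id": i, "birth_s": f.birth_time,
             "death_s": f.death_time, "angle0_deg": f.initial_angle_deg,
             "speed_nm_s": f.speed, "direction": f.direction,
             "immobile": int(f.immobile)}
            for i, f in enumerate(filaments)]
    df = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))


def read_ground_truth(path) -> list:
    df = pd.read_csv(path)
    return [GroundTruthFilament(r.birth_s, r.death_s, r.angle0_deg,
                                r.speed_nm_s, int(r.direction),
                                bool(r.immobile))
            for r in df.itertuples()]


def write_fit_table(fits, path) -> None:
    """Per-frame ring-fit table (one row per frame; NaN where no ring)."""
    rows = []
    for i, fit in enumerate(fits):
        if fit is None:
            rows.append({"frame": i, "converged": False})
            continue
        p = fit.params if isinstance(fit, RingFitResult) else fit
        row = {"frame": i, "x0": p.x0, "y0": p.y0, "R0": p.R0,
               "sigma": p.sigma}
        row.update({f"A_{j}": p.amplitudes[j] for j in range(12)})
        b = p.background
        row.update({"a": b.a, "sigma_bg1": b.sigma1_px, "b": b.b,
                    "sigma_bg2": b.sigma2_px, "c": b.c})
        if isinstance(fit, RingFitResult):
            row.update({"rss": fit.rss, "converged": fit.converged})
        rows.append(row)
    _atomic_write(path, lambda tmp: pd.DataFrame(rows).to_csv(tmp,
                                                              index=False))


def read_traces(path, radius_nm: float | None = None) -> list:
    """Long-format trace CSV (trace_id, t_s, angle_deg[, radius_nm]) -> traces."""
    df = pd.read_csv(path)
    traces = []
    for _, grp in df.groupby("trace_id"):
        r = radius_nm
        if r is None:
            if "radius_nm" not in grp:
                raise ConfigError("trace CSV has no radius_nm column and no "
                                  "radius was given")
            r = float(grp["radius_nm"].iloc[0])
        traces.append(FilamentTrace(grp["t_s"].to_numpy(),
                                    grp["angle_deg"].to_numpy(), r))
    return traces


def write_trace_metrics(traces, path) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(traces):
        m = trace_metrics(tr)
        rows.append({"trace_id": i, "speed_nm_s": m.speed_nm_s,
                     "lifetime_s": m.lifetime_s,
                     "distance_nm": m.arc_distance_nm,
                     "immobile": int(m.immobile)})
    df = pd.DataFrame(rows)
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))
    return df


def write_trajectory(traj, path) -> None:
    data = {"t_s": traj.t}
    for name, col in (("diameter_nm", traj.diameter),
                      ("thickness_nm", traj.thickness),
                      ("septal_density", traj.septal_density),
                      ("total_intensity", traj.total_intensity)):
        if col is not None:
            data[name] = col
    if traj.state is not None:
        data["state"] = traj.state
    _atomic_write(path, lambda tmp: pd.DataFrame(data).to_csv(tmp,
                                                              index=False))


def read_trajectory(path):
    from .trajectory import RingTrajectory

    df = pd.read_csv(path)
    def col(name):
        return df[name].to_numpy() if name in df else None
    return RingTrajectory(t=df["t_s"].to_numpy(), diameter=col("diameter_nm"),
                          thickness=col("thickness_nm"),
                          septal_density=col("septal_density"),
                          total_intensity=col("total_intensity"),
                          state=list(df["state"]) if "state" in df else None)


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    _atomic_write(path, lambda tmp: Path(tmp).write_text(yaml.safe_dump(cfg)))
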