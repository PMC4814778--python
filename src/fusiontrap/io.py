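"""Plain-text trajectory files.

Format: ``#``-prefixed ``key=value`` header lines followed by a
tab-separated body with columns ``t_s  x_nm  y_nm  z_nm  [state]``.
Units are fixed to seconds and nanometres; the physics modules convert to
SI internally, which keeps unit handling in one place.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

#: tolerated deviation from uniform 1/sampling_rate spacing, seconds
TIME_TOLERANCE = 1e-9

REQUIRED_COLUMNS = ("t_s", "x_nm", "y_nm", "z_nm")

DEFAULT_TEMPERATURE_K = 295.0
DEFAULT_BEAD_RADIUS_UM = 0.485


def write_trajectory(traj: Trajectory, destination) -> Path:
    """Write a trajectory as a ``#``-headed TSV file.

    Positions are written with 1e-6 nm resolution and times with 1e-9 s
    resolution, so ``read_trajectory(write_trajectory(t))`` reproduces the
    positions to <= 1e-6 nm.
    """
    destination = Path(destination)
    header = {
        "sampling_rate_hz": repr(float(traj.sampling_rate)),
        "temperature_k": repr(float(traj.temperature)),
        "bead_radius_um": repr(traj.bead_radius * 1e6),
        "units": "t=s, positions=nm",
    }
    for key, value in traj.metadata.items():
        if key not in header:
            header[str(key)] = str(value)

    body = {
        "t_s": np.char.mod("%.9f", traj.times),
        "x_nm": traj.x,
        "y_nm": traj.y,
        "z_nm": traj.z,
    }
    df = pd.DataFrame(body)
    if traj.states is not None:
        df["state"] = traj.states
    with open(destination, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return destination


def _parse_header(source: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(source) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, _, value = text.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_trajectory(source) -> Trajectory:
    """Read a trajectory file written by :func:`write_trajectory`.

    Missing optional metadata is filled with documented defaults (295 K,
    0.485 um bead) and logged as a warning.  Missing required columns and
    non-uniform sampling (beyond 1 ns) are rejected.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    meta = _parse_header(source)
    df = pd.read_csv(source, sep="\t", comment="#")
    for column in REQUIRED_COLUMNS:
        if column not in df.columns:
            raise ValueError(f"missing column {column}")
    if len(df) == 0:
        raise ValueError("trajectory file has no samples")

    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        if len(df) < 2:
            raise ValueError(
                "cannot infer sampling rate from a single-sample file "
                "without a sampling_rate_hz header"
            )
        rate = 1.0 / float(df["t_s"].iloc[1] - df["t_s"].iloc[0])
        logger.warning(
            "header lacks sampling_rate_hz; inferred %.6g Hz from the "
            "first time step",
            rate,
        )
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1:
        deviation = np.abs(np.diff(t) - 1.0 / rate).max()
        if deviation > TIME_TOLERANCE:
            raise ValueError(
                "non-uniform sampling: time step deviates from "
                f"1/sampling_rate by up to {deviation:.3g} s "
                f"(tolerance {TIME_TOLERANCE:g} s)"
            )

    if "temperature_k" in meta:
        temperature = float(meta["temperature_k"])
    else:
        temperature = DEFAULT_TEMPERATURE_K
        logger.warning(
            "header lacks temperature_k; using default %.1f K", temperature
        )
    if "bead_radius_um" in meta:
        bead_radius = float(meta["bead_radius_um"]) * 1e-6
    else:
        bead_radius = DEFAULT_BEAD_RADIUS_UM * 1e-6
        logger.warning(
            "header lacks bead_radius_um; using default %.3f um",
            DEFAULT_BEAD_RADIUS_UM,
        )

    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("sampling_rate_hz", "temperature_k", "bead_radius_um", "units")
    }
    states = df["state"].to_numpy() if "state" in df.columns else None
    return Trajectory(
        sampling_rate=rate,
        x=df["x_nm"].to_numpy(dtype=float),
        y=df["y_nm"].to_numpy(dtype=float),
        z=df["z_nm"].to_numpy(dtype=float),
        temperature=temperature,
        bead_radius=bead_radius,
        states=states,
        metadata=extra,
    )
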