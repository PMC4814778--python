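"""MSD-based diffusion estimation and drag decomposition.

The lateral diffusion constant is the second, position-independent
signature of the fusion intermediates: D drops from its bulk value D_inf
to about a third (D_0) at the surface, then suddenly to D_hf when a
membrane connection forms, and to zero at full fusion.  D is extracted
from the short-lag slope of the time-averaged one-dimensional MSD (lags
far below both 20 ms and the trap relaxation time, so confinement does not
bias the slope), with localisation noise as an additive 2 sigma^2
intercept.  The drop decomposes via Stokes-Einstein and drag additivity:

    gamma_0 = k_B T / D_0,   gamma_hf = k_B T / D_hf,
    gamma_m = gamma_hf - gamma_0,   D_m = k_B T / gamma_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import KB, Trajectory


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement over overlapping pairs."""

    lags: np.ndarray  # s, starting at 0
    msd: np.ndarray  # nm^2
    counts: np.ndarray  # pairs per lag

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.msd[0] != 0.0 or self.lags[0] != 0.0:
            raise ValueError("MSD curve must start at (0, 0)")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "msd_nm2": self.msd, "count": self.counts}
        )


@dataclass
class DiffusionEstimate:
    """Short-time diffusion constant from a weighted linear MSD fit."""

    d: float  # um^2/s, floored at 0
    stderr: float  # um^2/s
    fit_max_lag: float  # s
    noise_floor: float  # nm^2, the 2 sigma^2 intercept used or fitted
    window_center: float | None = None  # s, set by sliding_diffusion


@dataclass
class DragDecomposition:
    """Surface/membrane drag decomposition of one fusion event."""

    temperature: float  # K
    d_0: float  # um^2/s
    d_hf: float  # um^2/s
    delta_d: float  # um^2/s
    gamma_0: float  # N s/m
    gamma_hf: float  # N s/m
    gamma_m: float  # N s/m
    d_m: float  # um^2/s
    d_inf: float | None = None  # um^2/s, if a free stretch was measured


def compute_msd(traj: Trajectory, axis: str, max_lag: float) -> MSDCurve:
    """Time-averaged 1-D MSD up to ``max_lag`` seconds.

    Uses all overlapping pairs at each lag (maximal data use); the pair
    counts are reported so standard errors can be computed conservatively
    downstream.
    """
    positions = traj.axis(axis)
    n = len(positions)
    max_k = int(round(max_lag * traj.sampling_rate))
    if max_k < 1:
        raise ValueError("max_lag shorter than one sampling interval")
    if n < 10 * max_k:
        raise ValueError(
            f"segment too short: {n} samples for max lag of {max_k} samples "
            "(need >= 10x)"
        )
    lags = np.arange(max_k + 1) / traj.sampling_rate
    msd = np.empty(max_k + 1)
    counts = np.empty(max_k + 1, dtype=int)
    msd[0] = 0.0
    counts[0] = n
    for k in range(1, max_k + 1):
        diff = positions[k:] - positions[:-k]
        msd[k] = np.mean(diff * diff)
        counts[k] = n - k
    return MSDCurve(lags=lags, msd=msd, counts=counts)


def fit_short_time_diffusion(
    msd: MSDCurve,
    fit_max_lag: float,
    localization_noise_sd: float | None = None,
) -> DiffusionEstimate:
    """Weighted least squares of msd = 2 D tau + 2 sigma_noise^2.

    ``localization_noise_sd`` (nm) fixes the intercept when the stage
    noise is known from metadata; otherwise the intercept is fitted.
    Weights are the pair counts.  D is floored at zero.
    """
    mask = (msd.lags > 0) & (msd.lags <= fit_max_lag)
    tau = msd.lags[mask]
    y = msd.msd[mask]
    w = msd.counts[mask].astype(float)
    if len(tau) < 3:
        raise ValueError("need at least 3 lags within the fit range")
    if np.allclose(tau, tau[0]):
        raise ValueError("degenerate fit: all lags equal")

    if localization_noise_sd is not None:
        intercept = 2.0 * localization_noise_sd**2
        yc = y - intercept
        denom = np.sum(w * tau * tau)
        slope = np.sum(w * tau * yc) / denom
        resid = yc - slope * tau
        dof = max(len(tau) - 1, 1)
        s2 = np.sum(w * resid**2) / (np.sum(w) * dof / len(tau))
        slope_var = s2 / denom
    else:
        W = np.diag(w)
        X = np.column_stack([tau, np.ones_like(tau)])
        xtw = X.T @ W
        cov = np.linalg.inv(xtw @ X)
        beta = cov @ (xtw @ y)
        slope, intercept = beta
        resid = y - X @ beta
        dof = max(len(tau) - 2, 1)
        s2 = (w * resid**2).sum() / dof
        slope_var = cov[0, 0] * s2 / np.mean(w)

    d = max(slope / 2.0, 0.0) * 1e-6  # nm^2/s -> um^2/s
    stderr = np.sqrt(max(slope_var, 0.0)) / 2.0 * 1e-6
    return DiffusionEstimate(
        d=d,
        stderr=stderr,
        fit_max_lag=fit_max_lag,
        noise_floor=float(intercept),
    )


def sliding_diffusion(
    traj: Trajectory,
    axis: str,
    window: float = 1.0,
    fit_max_lag: float | None = None,
    localization_noise_sd: float | None = None,
) -> list[DiffusionEstimate]:
    """Short-time D in consecutive (non-overlapping) windows.

    On a full fusion trace the window sequence shows the stepwise
    D_inf -> D_0 -> D_hf -> ~0 profile.  ``fit_max_lag`` defaults to 10
    sampling intervals (0.1 ms at 100 kHz), safely below both the 20 ms
    MSD linearity bound and the trap relaxation time.  If
    ``localization_noise_sd`` is None, the stage-noise SD recorded in the
    trajectory metadata (per-axis) is used when present.
    """
    if fit_max_lag is None:
        fit_max_lag = 10.0 / traj.sampling_rate
    w = int(round(window * traj.sampling_rate))
    if w < 100:
        raise ValueError("window must contain at least 100 samples")
    if w > traj.n_samples:
        raise ValueError("window longer than trace")
    if localization_noise_sd is None:
        key = (
            "stage_noise_sd_axial_nm"
            if axis == "z"
            else "stage_noise_sd_lateral_nm"
        )
        if key in traj.metadata:
            localization_noise_sd = float(traj.metadata[key])
    estimates = []
    n_windows = traj.n_samples // w
    for i in range(n_windows):
        sub = Trajectory(
            sampling_rate=traj.sampling_rate,
            x=traj.x[i * w : (i + 1) * w],
            y=traj.y[i * w : (i + 1) * w],
            z=traj.z[i * w : (i + 1) * w],
            temperature=traj.temperature,
            bead_radius=traj.bead_radius,
        )
        curve = compute_msd(sub, axis, max_lag=fit_max_lag)
        est = fit_short_time_diffusion(
            curve, fit_max_lag, localization_noise_sd=localization_noise_sd
        )
        est.window_center = (i + 0.5) * w / traj.sampling_rate
        estimates.append(est)
    return estimates


def decompose_drag(
    d_0: float,
    d_hf: float,
    temperature: float,
    d_inf: float | None = None,
) -> DragDecomposition:
    """Decompose the hemifusion diffusion drop into surface + membrane drag.

    Parameters are in um^2/s.  Requires ``0 < d_hf < d_0``: a fused state
    (``d_hf = 0``) has no finite decomposition, and ``d_hf >= d_0`` would
    imply a negative membrane drag.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if d_hf <= 0:
        raise ValueError(
            "D_hf must be positive: the fused state has no finite drag "
            "decomposition"
        )
    if d_hf >= d_0:
        raise ValueError(
            f"D_hf ({d_hf:g}) must be smaller than D_0 ({d_0:g}); "
            "otherwise the membrane drag would be negative"
        )
    kbt = KB * temperature
    gamma_0 = kbt / (d_0 * 1e-12)
    gamma_hf = kbt / (d_hf * 1e-12)
    gamma_m = gamma_hf - gamma_0
    d_m = kbt / gamma_m * 1e12
    return DragDecomposition(
        temperature=temperature,
        d_0=d_0,
        d_hf=d_hf,
        delta_d=d_0 - d_hf,
        gamma_0=gamma_0,
        gamma_hf=gamma_hf,
        gamma_m=gamma_m,
        d_m=d_m,
        d_inf=d_inf,
    )
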