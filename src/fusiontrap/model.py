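"""High-level Model/Results interface binding the analysis stages.

:class:`FusionTraceModel` is built from a :class:`~fusiontrap.Trajectory`
(or a trajectory file) and ``fit()`` runs the full pipeline: sliding
widths, state segmentation, windowed diffusion constants, the drag
decomposition of the hemifusion drop, Evans-Sackmann contact radii (both
prefactor variants) and the Boltzmann energy landscape of the arrested
state.  :class:`FusionTraceResults` carries the estimates, a ``summary()``
table and plain-text exporters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .io import read_trajectory
from .fluctuations import sliding_width
from .segmentation import (
    ClassifierConfig,
    StateSegment,
    classify_states,
    segments_table,
)
from .diffusion import DragDecomposition, decompose_drag, sliding_diffusion
from .landscape import EnergyLandscape, barrier_depth, landscape_from_samples
from .mechanics import ContactRadiusResult, MembraneParams, invert_contact_radius

logger = logging.getLogger(__name__)

FUSION_LABELS = ("transient_fusion", "hemifusion", "fused")


class FusionTraceModel:
    """Fusion-intermediate analysis of one trapped-bead trajectory.

    Parameters
    ----------
    trajectory : Trajectory
        The position trace to analyse.
    window_length, step : float
        Width-estimator window and advance, seconds.
    classifier : ClassifierConfig, optional
        State-classification thresholds.
    membrane : MembraneParams, optional
        Evans-Sackmann parameters for the contact-radius inversion
        (temperature is overridden by the trajectory's).
    diffusion_window : float
        Window for the sliding diffusion constant, seconds.
    fit_max_lag : float
        Maximum MSD lag of the short-time diffusion fit, seconds.
    landscape_axis : str
        Axis whose arrested-state histogram is Boltzmann-inverted.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        *,
        window_length: float = 0.5,
        step: float | None = None,
        classifier: ClassifierConfig | None = None,
        membrane: MembraneParams | None = None,
        diffusion_window: float = 1.0,
        fit_max_lag: float | None = None,
        landscape_axis: str = "z",
    ) -> None:
        self.trajectory = trajectory
        self.window_length = window_length
        self.step = step
        self.classifier = classifier or ClassifierConfig()
        membrane = membrane or MembraneParams()
        self.membrane = replace(membrane, temperature=trajectory.temperature)
        self.diffusion_window = diffusion_window
        self.fit_max_lag = fit_max_lag
        self.landscape_axis = landscape_axis

    @classmethod
    def from_file(cls, path, **kwargs) -> "FusionTraceModel":
        return cls(read_trajectory(path), **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "FusionTraceResults":
        traj = self.trajectory
        widths = {
            a: sliding_width(traj, a, self.window_length, self.step)
            for a in "xyz"
        }
        segments = classify_states(
            widths["x"], widths["y"], widths["z"], self.classifier
        )

        diffusion = sliding_diffusion(
            traj,
            "x",
            window=self.diffusion_window,
            fit_max_lag=self.fit_max_lag,
        )
        d_centers = np.array([e.window_center for e in diffusion])
        d_values = np.array([e.d for e in diffusion])

        def median_d(label: str) -> float | None:
            sel = np.zeros(len(d_centers), dtype=bool)
            margin = self.diffusion_window / 2.0
            for seg in segments:
                if seg.label == label:
                    sel |= (d_centers >= seg.start + margin) & (
                        d_centers <= seg.end - margin
                    )
            if not sel.any():
                return None
            return float(np.median(d_values[sel]))

        d_inf = median_d("free")
        d_0 = median_d("surface")
        d_hf = median_d("hemifusion")
        if d_hf is None:
            d_hf = median_d("transient_fusion")

        drag: DragDecomposition | None = None
        radii: dict[str, ContactRadiusResult] = {}
        if d_0 is not None and d_hf is not None and 0 < d_hf < d_0:
            drag = decompose_drag(d_0, d_hf, traj.temperature, d_inf=d_inf)
            for variant in ("four_pi", "eight_pi"):
                params = replace(self.membrane, prefactor_variant=variant)
                try:
                    radii[variant] = invert_contact_radius(drag.d_m, params)
                except ValueError as exc:
                    logger.warning(
                        "contact-radius inversion (%s) failed: %s", variant, exc
                    )
        elif d_0 is not None and d_hf is not None:
            logger.warning(
                "no drag decomposition: D_hf (%.3g) not below D_0 (%.3g)",
                d_hf,
                d_0,
            )

        landscape: EnergyLandscape | None = None
        barrier: float | None = None
        arrested = [
            s
            for s in segments
            if s.label in ("hemifusion", "transient_fusion")
        ]
        if arrested:
            longest = max(arrested, key=lambda s: s.duration)
            sub = traj.slice(longest.start, longest.end)
            samples = sub.axis(self.landscape_axis)
            if len(samples) >= 1000:
                landscape = landscape_from_samples(
                    samples, traj.temperature, axis=self.landscape_axis
                )
                barrier = barrier_depth(landscape)

        return FusionTraceResults(
            model=self,
            widths=widths,
            segments=segments,
            diffusion=diffusion,
            d_inf=d_inf,
            d_0=d_0,
            d_hf=d_hf,
            drag=drag,
            contact_radii=radii,
            landscape=landscape,
            barrier_depth_kbt=barrier,
        )

    # -- provenance -------------------------------------------------------

    def config_hash(self) -> str:
        payload = {
            "window_length": self.window_length,
            "step": self.step,
            "diffusion_window": self.diffusion_window,
            "fit_max_lag": self.fit_max_lag,
            "landscape_axis": self.landscape_axis,
            "classifier": vars(self.classifier),
            "membrane": {
                k: v for k, v in vars(self.membrane).items()
            },
        }
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class FusionTraceResults:
    """Estimates and diagnostics of a fitted :class:`FusionTraceModel`."""

    model: FusionTraceModel
    widths: dict
    segments: list[StateSegment]
    diffusion: list
    d_inf: float | None
    d_0: float | None
    d_hf: float | None
    drag: DragDecomposition | None
    contact_radii: dict[str, ContactRadiusResult]
    landscape: EnergyLandscape | None
    barrier_depth_kbt: float | None

    # -- derived tables ---------------------------------------------------

    @property
    def certified(self) -> bool:
        """Whether any fusion intermediate was certified on this trace."""
        return any(s.label in FUSION_LABELS for s in self.segments)

    @property
    def state_sequence(self) -> list[str]:
        return [s.label for s in self.segments]

    def widths_frame(self) -> pd.DataFrame:
        wx, wy, wz = (self.widths[a] for a in "xyz")
        return pd.DataFrame(
            {
                "center_s": wz.window_centers,
                "width_x_nm": wx.width,
                "width_y_nm": wy.width,
                "width_z_nm": wz.width,
            }
        )

    def segments_frame(self) -> pd.DataFrame:
        return segments_table(self.segments)

    def diffusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_s": [e.window_center for e in self.diffusion],
                "d_um2_per_s": [e.d for e in self.diffusion],
                "stderr": [e.stderr for e in self.diffusion],
                "noise_floor_nm2": [e.noise_floor for e in self.diffusion],
            }
        )

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config_hash": self.model.config_hash(),
            "seed": self.model.trajectory.metadata.get("seed"),
            "version": __version__,
        }

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = []
        traj = self.model.trajectory
        lines.append("Fusion-intermediate trajectory analysis")
        lines.append("=" * 55)
        lines.append(
            f"samples: {traj.n_samples}  rate: {traj.sampling_rate:g} Hz  "
            f"duration: {traj.duration:.3f} s  T: {traj.temperature:g} K"
        )
        prov = self.provenance()
        lines.append(
            f"config: {prov['config_hash']}  seed: {prov['seed']}  "
            f"version: {prov['version']}"
        )
        lines.append("")
        lines.append("State segments (width = 2 SD):")
        lines.append(
            f"{'start_s':>9} {'end_s':>9} {'label':<17}"
            f"{'w_x_nm':>8} {'w_y_nm':>8} {'w_z_nm':>8}"
        )
        for s in self.segments:
            lines.append(
                f"{s.start:9.3f} {s.end:9.3f} {s.label:<17}"
                f"{s.mean_widths[0]:8.1f} {s.mean_widths[1]:8.1f} "
                f"{s.mean_widths[2]:8.1f}"
            )
        lines.append("")
        lines.append("Lateral diffusion (um^2/s):")
        for name, value in (
            ("D_inf (free)", self.d_inf),
            ("D_0 (surface)", self.d_0),
            ("D_hf (membrane-connected)", self.d_hf),
        ):
            lines.append(
                f"  {name:<28} "
                + ("n/a" if value is None else f"{value:.4f}")
            )
        if self.drag is not None:
            d = self.drag
            lines.append(
                f"  gamma_0 = {d.gamma_0:.3e} N s/m   "
                f"gamma_hf = {d.gamma_hf:.3e} N s/m"
            )
            lines.append(
                f"  gamma_m = {d.gamma_m:.3e} N s/m   D_m = {d.d_m:.4f} um^2/s"
            )
        for variant, res in self.contact_radii.items():
            lines.append(
                f"  contact radius ({variant}): {res.radius:.1f} nm "
                f"(eps = {res.epsilon:.2f})"
            )
        lines.append("")
        if self.barrier_depth_kbt is not None:
            lines.append(
                "Sampled energy-landscape depth (lower bound on the barrier "
                f"out of the arrested state): {self.barrier_depth_kbt:.1f} kBT"
            )
        lines.append(
            "Fusion intermediate certified: "
            + ("yes" if self.certified else "no")
        )
        return "\n".join(lines)

    def to_directory(self, out_dir) -> Path:
        """Write the report tables as plain text under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.segments_frame().to_csv(out / "segments.tsv", sep="\t", index=False)
        self.widths_frame().to_csv(out / "widths.tsv", sep="\t", index=False)
        self.diffusion_frame().to_csv(out / "diffusion.tsv", sep="\t", index=False)
        if self.landscape is not None:
            self.landscape.as_table().to_csv(
                out / "landscape.tsv", sep="\t", index=False
            )
        (out / "report.txt").write_text(self.summary() + "\n")
        report = {
            "provenance": self.provenance(),
            "certified": self.certified,
            "state_sequence": self.state_sequence,
            "d_inf": self.d_inf,
            "d_0": self.d_0,
            "d_hf": self.d_hf,
            "barrier_depth_kbt": self.barrier_depth_kbt,
        }
        if self.drag is not None:
            report["gamma_m"] = self.drag.gamma_m
            report["d_m"] = self.drag.d_m
        for variant, res in self.contact_radii.items():
            report[f"contact_radius_nm_{variant}"] = res.radius
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        return out

    # -- plotting ---------------------------------------------------------

    def plot_widths(self, ax=None):
        """Plot the three width traces with segment boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for a in "xyz":
            w = self.widths[a]
            ax.plot(w.window_centers, w.width, label=f"width {a}")
        for s in self.segments[1:]:
            ax.axvline(s.start, color="k", lw=0.5, ls="--")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("width = 2 SD (nm)")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def plot_diffusion(self, ax=None):
        """Plot the windowed lateral diffusion constant over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.diffusion_frame()
        ax.plot(frame["center_s"], frame["d_um2_per_s"], "o-")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"D ($\mu m^2$/s)")
        return ax
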