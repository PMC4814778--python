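"""Threshold classification of fusion intermediates from width traces.

Each analysis window is labelled from the three per-axis widths relative
to the free-trap reference widths:

* ``fused`` — all three widths at the stage-noise floor (<= 8 nm);
* ``hemifusion`` — axial width below 25% of the free reference while the
  lateral widths are unchanged (in the crystalline-membrane mode a lateral
  reduction of 50-90% is also accepted);
* ``surface`` — axial width between 25% and 75% of the reference, lateral
  unchanged;
* ``free`` — every width at least 75% of its reference;
* ``unknown`` — anything else (typically transition windows).

Window labels are merged into contiguous segments; a segment shorter than
the certification time cannot be distinguished from a thermal excursion
and is merged into its neighbours, and hemifusion-like segments that
release back to a less confined state within a few seconds are relabelled
``transient_fusion``.

The certification time itself comes from first-passage reasoning: a
transition is only certain once the particle has had time to diffuse
beyond the peak-to-peak fluctuations (6 SD = 3x width) of the more
confined state, t = L^2 / (2 D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluctuations import WidthTrace
from .mechanics import stokes_einstein_diffusion

#: confinement rank used to decide whether a state is "less confined"
_RANK = {
    "unknown": 0,
    "free": 0,
    "surface": 1,
    "transient_fusion": 2,
    "hemifusion": 2,
    "fused": 3,
}


@dataclass
class ClassifierConfig:
    """Thresholds of the width-based state classifier.

    The fractional thresholds interpolate the canonical width progression
    162 -> 96 -> 12 -> 4 nm; ``crystalline_mode`` accepts the 50-90%
    lateral width reduction seen for membranes below their phase
    transition.  ``min_confirmation_time`` defaults to the first-passage
    detection latency (see :func:`detection_latency`); certification
    additionally always requires at least one full width-estimator window.
    """

    reference_widths: tuple[float, float, float] | None = None  # (x, y, z) nm
    surface_z_fraction: float = 0.75
    hemifusion_z_fraction: float = 0.25
    fused_all_axes_nm: float = 8.0
    lateral_unchanged_tolerance: float = 0.25
    transient_max_duration: float = 3.0
    min_confirmation_time: float | None = None
    crystalline_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.hemifusion_z_fraction < self.surface_z_fraction < 1.0:
            raise ValueError(
                "need 0 < hemifusion_z_fraction < surface_z_fraction < 1"
            )
        if self.fused_all_axes_nm <= 0:
            raise ValueError("fused_all_axes_nm must be positive")


@dataclass
class StateSegment:
    """A labelled, certified interval of the trajectory."""

    label: str
    start: float  # s
    end: float  # s
    mean_widths: tuple[float, float, float]  # (x, y, z) nm

    @property
    def duration(self) -> float:
        return self.end - self.start


def near_surface_diffusion(
    temperature: float = 298.0,
    viscosity: float = 0.89e-3,
    bead_radius: float = 0.485e-6,
    wall_factor: float = 3.0,
) -> float:
    """1-D diffusion constant of the bead at the surface, m^2/s.

    Bulk Stokes-Einstein divided by the lumped near-wall hindrance factor.
    """
    return stokes_einstein_diffusion(
        bead_radius, viscosity, temperature, hindrance_factor=wall_factor
    )


def detection_latency(confined_width: float, diffusion_near_surface: float) -> float:
    """Upper bound on the time needed to certify a confinement transition.

    ``confined_width`` is the width (2 SD, nm) of the *more confined*
    state; the peak-to-peak span is 3x the width (6 SD).  The latency is
    the time to diffuse that far, t = L^2 / (2 D), with
    ``diffusion_near_surface`` in m^2/s.  For the hemifused state
    (width 12 nm) this is ~3.8 ms; for the fused state (width 4 nm)
    ~0.4 ms.
    """
    if confined_width <= 0 or diffusion_near_surface <= 0:
        raise ValueError("width and diffusion constant must be positive")
    span = 3.0 * confined_width * 1e-9  # peak-to-peak, metres
    return span**2 / (2.0 * diffusion_near_surface)


def _axial_categories(
    wx: np.ndarray, wy: np.ndarray, wz: np.ndarray, cfg: ClassifierConfig,
    ref: tuple[float, float, float],
) -> np.ndarray:
    """Per-window confinement category from the (robust) axial width.

    The axial width relaxes quickly in every state, so it is reliable per
    window; the lateral widths are tested later on run averages, where the
    estimator has power even in the membrane-connected states (whose extra
    drag slows the lateral relaxation to tens of ms).  A window matching
    both the collapse and the fused rule is fused (tie-break).
    """
    rz = ref[2]
    fused = (
        (wx <= cfg.fused_all_axes_nm)
        & (wy <= cfg.fused_all_axes_nm)
        & (wz <= cfg.fused_all_axes_nm)
    )
    cats = np.full(len(wz), "z_free", dtype=object)
    cats[wz < cfg.surface_z_fraction * rz] = "z_partial"
    cats[wz < cfg.hemifusion_z_fraction * rz] = "z_collapse"
    cats[fused] = "fused"
    cats[~np.isfinite(wz)] = "unknown"
    return cats


def _pooled_width(
    widths: np.ndarray, means: np.ndarray | None, sl: slice
) -> float:
    """Width of all samples in a run of windows.

    Law of total variance: within-window variance (mean of the squared
    window SDs) plus the variance of the window means.  The second term
    matters whenever the position decorrelates slowly compared to the
    window — e.g. laterally in the membrane-connected states, where the
    extra drag stretches the relaxation time to tens of ms and a single
    window systematically under-measures the equilibrium amplitude.
    """
    s2 = np.nanmean((widths[sl] / 2.0) ** 2)
    if means is not None:
        s2 = s2 + np.nanvar(means[sl])
    return float(2.0 * np.sqrt(s2))


def _run_label(
    cat: str,
    mean_wx: float,
    mean_wy: float,
    cfg: ClassifierConfig,
    ref: tuple[float, float, float],
) -> str:
    """Final state label of a run, from its averaged lateral widths."""
    rx, ry, _ = ref
    tol = cfg.lateral_unchanged_tolerance
    unchanged = (
        abs(mean_wx - rx) <= tol * rx and abs(mean_wy - ry) <= tol * ry
    )
    if cat == "fused":
        return "fused"
    if cat == "z_collapse":
        if unchanged:
            return "hemifusion"
        if cfg.crystalline_mode and (
            0.1 * rx <= mean_wx <= 0.5 * rx and 0.1 * ry <= mean_wy <= 0.5 * ry
        ):
            # below the phase transition the surrounding crystalline
            # membrane also confines the lateral motion by 50-90%
            return "hemifusion"
        return "unknown"
    if cat == "z_partial":
        return "surface" if unchanged else "unknown"
    if cat == "z_free":
        if (
            mean_wx >= cfg.surface_z_fraction * rx
            and mean_wy >= cfg.surface_z_fraction * ry
        ):
            return "free"
        return "unknown"
    return "unknown"


def _estimate_reference(
    wx: np.ndarray, wy: np.ndarray, wz: np.ndarray
) -> tuple[float, float, float]:
    """Free-state reference widths from the least-confined stretch.

    The free trap maximises the axial width, so the reference is the
    per-axis median over the windows whose axial width is within 20% of
    the trace's 90th axial-width percentile — in effect the first
    certified free segment, while staying insensitive to the few inflated
    windows that straddle a transition (where a drifting mean masquerades
    as extra width).
    """
    finite = np.isfinite(wz)
    if not finite.any():
        raise ValueError("no finite windows to estimate reference widths from")
    anchor = np.nanpercentile(wz[finite], 90)
    sel = (wz >= 0.8 * anchor) & finite
    return (
        float(np.nanmedian(wx[sel])),
        float(np.nanmedian(wy[sel])),
        float(np.nanmedian(wz[sel])),
    )


def classify_states(
    width_x: WidthTrace,
    width_y: WidthTrace,
    width_z: WidthTrace,
    cfg: ClassifierConfig | None = None,
) -> list[StateSegment]:
    """Segment a trajectory into fusion intermediates from its width traces.

    The three traces must share window centers.  Returns an ordered,
    contiguous, non-overlapping cover of the analysed interval.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    centers = width_z.window_centers
    for other in (width_x, width_y):
        if len(other.window_centers) != len(centers) or not np.allclose(
            other.window_centers, centers
        ):
            raise ValueError("width traces must share window centers")
    if len(centers) == 0:
        raise ValueError("empty width traces")
    wx, wy, wz = width_x.width, width_y.width, width_z.width
    ref = cfg.reference_widths
    if ref is None:
        ref = _estimate_reference(wx, wy, wz)

    labels = _axial_categories(wx, wy, wz, cfg, ref)

    # run-length encode the window categories
    runs: list[list[int]] = []  # [i0, i1] inclusive window indices
    run_labels: list[str] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([start, i - 1])
            run_labels.append(labels[start])
            start = i

    step = width_z.step
    window = width_z.window_length

    def run_duration(run: list[int]) -> float:
        return (run[1] - run[0] + 1) * step

    # certification: a segment shorter than the first-passage latency can
    # never be certified, and one not spanning more than a full estimator
    # window (plus one advance) is indistinguishable from a width-estimator
    # excursion, since overlapping windows share most of their data
    latency = cfg.min_confirmation_time
    if latency is None:
        confined_width = cfg.hemifusion_z_fraction * ref[2]
        latency = detection_latency(confined_width, near_surface_diffusion())
    min_certified = max(latency, window + step)

    changed = True
    while changed and len(runs) > 1:
        changed = False
        durations = [run_duration(r) for r in runs]
        order = int(np.argmin(durations))
        if durations[order] < min_certified:
            i = order
            left = i - 1 if i > 0 else None
            right = i + 1 if i < len(runs) - 1 else None
            if left is not None and (
                right is None
                or run_duration(runs[left]) >= run_duration(runs[right])
            ):
                target = left
            else:
                target = right
            lo = min(runs[i][0], runs[target][0])
            hi = max(runs[i][1], runs[target][1])
            keep_label = run_labels[target]
            new_runs, new_labels = [], []
            for j, (r, lab) in enumerate(zip(runs, run_labels)):
                if j == i:
                    continue
                if j == target:
                    new_runs.append([lo, hi])
                    new_labels.append(keep_label)
                else:
                    new_runs.append(r)
                    new_labels.append(lab)
            runs, run_labels = new_runs, new_labels
            # merging can create adjacent equal labels; collapse them
            j = 1
            while j < len(runs):
                if run_labels[j] == run_labels[j - 1]:
                    runs[j - 1][1] = runs[j][1]
                    del runs[j], run_labels[j]
                else:
                    j += 1
            changed = True

    # resolve the axial categories into state labels using run-averaged
    # lateral widths, then collapse adjacent equal labels
    mx, my, mz = (
        width_x.window_mean,
        width_y.window_mean,
        width_z.window_mean,
    )
    for j, (run, cat) in enumerate(zip(runs, run_labels)):
        sl = slice(run[0], run[1] + 1)
        run_labels[j] = _run_label(
            cat,
            _pooled_width(wx, mx, sl),
            _pooled_width(wy, my, sl),
            cfg,
            ref,
        )
    j = 1
    while j < len(runs):
        if run_labels[j] == run_labels[j - 1]:
            runs[j - 1][1] = runs[j][1]
            del runs[j], run_labels[j]
        else:
            j += 1

    # hemifusion-like runs that release to a less confined state within
    # transient_max_duration are transient fusion
    for j, lab in enumerate(run_labels):
        if lab == "hemifusion" and run_duration(runs[j]) < cfg.transient_max_duration:
            if j + 1 < len(runs) and _RANK[run_labels[j + 1]] < _RANK["hemifusion"]:
                run_labels[j] = "transient_fusion"

    # convert window-index runs into time segments covering the interval
    segments: list[StateSegment] = []
    t0 = centers[0] - window / 2.0
    t_end = centers[-1] + window / 2.0
    for j, (run, lab) in enumerate(zip(runs, run_labels)):
        lo = t0 if j == 0 else 0.5 * (centers[runs[j - 1][1]] + centers[run[0]])
        hi = (
            t_end
            if j == len(runs) - 1
            else 0.5 * (centers[run[1]] + centers[runs[j + 1][0]])
        )
        sl = slice(run[0], run[1] + 1)
        segments.append(
            StateSegment(
                label=lab,
                start=float(lo),
                end=float(hi),
                mean_widths=(
                    _pooled_width(wx, mx, sl),
                    _pooled_width(wy, my, sl),
                    _pooled_width(wz, mz, sl),
                ),
            )
        )
    return segments


def segments_table(segments: list[StateSegment]) -> pd.DataFrame:
    """BED-like tabular export of a segmentation."""
    return pd.DataFrame(
        {
            "start_s": [s.start for s in segments],
            "end_s": [s.end for s in segments],
            "label": [s.label for s in segments],
            "width_x_nm": [s.mean_widths[0] for s in segments],
            "width_y_nm": [s.mean_widths[1] for s in segments],
            "width_z_nm": [s.mean_widths[2] for s in segments],
        }
    )
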