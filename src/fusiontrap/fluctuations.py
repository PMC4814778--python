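"""Fluctuation-width traces and 1/2/3-D position histograms.

The *width* — twice the sample standard deviation of the position within a
sliding window — is the state signature of the assay: the free trap shows
an axial width of ~162 nm, wall contact truncates it to ~96 nm, hemifusion
collapses it to ~12 nm with the lateral widths unchanged, and full fusion
takes all three axes down to the stage-noise floor of a few nm.  Position
histograms (and the volume of their occupied region) give the same
information without choosing an axis, and the 1-D histograms feed the
Boltzmann inversion in :mod:`fusiontrap.landscape`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

#: auto bin-width bounds, nm: fine enough for the confined states, coarse
#: enough for the free trap
AUTO_BIN_MIN_NM = 1.0
AUTO_BIN_MAX_NM = 5.0


@dataclass
class WidthTrace:
    """Sliding width (2 sample SD, ddof=1) of one axis over time."""

    axis: str
    window_centers: np.ndarray  # s
    width: np.ndarray  # nm
    window_length: float  # s
    step: float  # s
    window_mean: np.ndarray | None = None  # nm, mean position per window
    flagged: np.ndarray = field(default=None)  # windows with non-finite data

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.width)

    @property
    def n_windows(self) -> int:
        return len(self.width)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_s": self.window_centers,
                f"width_{self.axis}_nm": self.width,
                "flagged": self.flagged,
            }
        )


def sliding_width(
    traj: Trajectory,
    axis: str,
    window_length: float = 0.5,
    step: float | None = None,
) -> WidthTrace:
    """Sliding width (= 2 standard deviations) of one axis.

    Windows of ``window_length`` seconds advance by ``step`` (default
    window/4).  Windows containing non-finite samples are flagged and get
    NaN width.
    """
    if window_length < 10.0 / traj.sampling_rate:
        raise ValueError("window must contain at least 10 samples")
    positions = traj.axis(axis)
    w = int(round(window_length * traj.sampling_rate))
    if w > traj.n_samples:
        raise ValueError("window longer than trace")
    if step is None:
        step = window_length / 4.0
    s = max(1, int(round(step * traj.sampling_rate)))
    view = np.lib.stride_tricks.sliding_window_view(positions, w)[::s]
    width = 2.0 * view.std(axis=1, ddof=1)
    means = view.mean(axis=1)
    starts = np.arange(view.shape[0]) * s
    centers = (starts + (w - 1) / 2.0) / traj.sampling_rate
    return WidthTrace(
        axis=axis,
        window_centers=centers,
        width=width,
        window_length=window_length,
        step=s / traj.sampling_rate,
        window_mean=means,
    )


@dataclass
class PositionHistogram:
    """Dense 1-3-D position histogram over the occupied bounding box."""

    edges: list[np.ndarray]  # nm, per axis
    counts: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.ndim != len(self.edges):
            raise ValueError("edges/counts dimensionality mismatch")

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Normalised bin frequencies p(bin); sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def bin_widths(self) -> list[float]:
        return [float(e[1] - e[0]) for e in self.edges]

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @classmethod
    def from_samples(
        cls,
        samples: dict[str, np.ndarray],
        bin_width: float | None = None,
    ) -> "PositionHistogram":
        """Histogram raw per-axis samples (nm).

        ``bin_width`` defaults to the Freedman-Diaconis width (smallest
        over axes) clipped to [1, 5] nm, so confined states get ~1 nm bins
        and the free trap ~5 nm bins.
        """
        axes = tuple(samples)
        arrays = [np.asarray(samples[a], dtype=float) for a in axes]
        n = len(arrays[0])
        if n < 100:
            raise ValueError("need at least 100 samples for a histogram")
        if bin_width is None:
            bin_width = min(_freedman_diaconis(a) for a in arrays)
            bin_width = float(np.clip(bin_width, AUTO_BIN_MIN_NM, AUTO_BIN_MAX_NM))
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        edges = []
        for a in arrays:
            lo, hi = a.min(), a.max()
            nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
            # expand symmetrically so edges are an integer number of bins
            pad = (nbins * bin_width - (hi - lo)) / 2.0
            edges.append(lo - pad + bin_width * np.arange(nbins + 1))
            edges[-1][-1] = np.nextafter(edges[-1][-1], np.inf)
        counts, _ = np.histogramdd(np.column_stack(arrays), bins=edges)
        return cls(edges=edges, counts=counts.astype(int), axes=axes)

    def as_table(self) -> pd.DataFrame:
        """Tabular export: bin centers per axis, counts, frequency."""
        grids = np.meshgrid(*self.centers, indexing="ij")
        data = {f"{a}_nm": g.ravel() for a, g in zip(self.axes, grids)}
        data["count"] = self.counts.ravel()
        data["frequency"] = self.frequencies.ravel()
        return pd.DataFrame(data)


def _freedman_diaconis(a: np.ndarray) -> float:
    q75, q25 = np.percentile(a, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return AUTO_BIN_MIN_NM
    return 2.0 * iqr / len(a) ** (1.0 / 3.0)


def position_histogram(
    traj: Trajectory,
    axes: str = "xyz",
    bin_width: float | None = None,
) -> PositionHistogram:
    """Position histogram of a trajectory (segment) over selected axes.

    ``axes`` is a string like ``"z"``, ``"xy"`` or ``"xyz"``.
    """
    if traj.n_samples == 0:
        raise ValueError("empty segment")
    samples = {a: traj.axis(a) for a in axes}
    return PositionHistogram.from_samples(samples, bin_width=bin_width)


def occupancy_volume(hist: PositionHistogram, iso_fraction: float) -> float:
    """Volume of the occupied region above an iso-probability level.

    Counts the bins whose frequency is at least ``iso_fraction`` times the
    modal frequency and multiplies by the bin volume (nm^3 for a 3-D
    histogram, nm^2 / nm for 2-D / 1-D).  The collapse of this volume —
    orders of magnitude between the free trap and the fused state — tracks
    the progression of fusion without reference to a single axis.
    """
    if not 0.0 < iso_fraction < 1.0:
        raise ValueError("iso_fraction must be in (0, 1)")
    freq = hist.frequencies
    if hist.total == 0:
        raise ValueError("empty histogram")
    level = iso_fraction * freq.max()
    bin_volume = float(np.prod(hist.bin_widths))
    return float((freq >= level).sum()) * bin_volume
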