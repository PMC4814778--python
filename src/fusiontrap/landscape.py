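"""Boltzmann inversion of position histograms into energy landscapes.

In thermal equilibrium the probability of finding the particle in a bin is
p(x) dx ~ exp(-E(x)/k_B T) dx, so the occupancy histogram of an arrested
fusion intermediate inverts into the energy landscape the particle
explores, E(x) = -k_B T ln p(x) + k_B T ln C.  The depth of the *sampled*
landscape (max - min over visited bins) is a lower bound on the true
barrier out of the state: unvisited regions can only be higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluctuations import PositionHistogram

logger = logging.getLogger(__name__)

#: resolution rule: the modal bin may hold at most this fraction of samples
MODAL_FRACTION_LIMIT = 0.05
#: coverage rule: defined edge bins should hold at least this many counts
MIN_EDGE_COUNTS = 5


@dataclass
class EnergyLandscape:
    """1-D energy landscape in units of k_B T, minimum shifted to 0.

    Zero-count bins are masked ``undefined`` and never imputed.
    """

    bin_centers: np.ndarray  # nm
    energy: np.ndarray  # kBT; NaN on undefined bins
    counts: np.ndarray
    defined: np.ndarray  # bool mask
    temperature: float
    norm_constant: float  # C with E = -ln p + ln C, i.e. the modal frequency

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_nm": self.bin_centers,
                "energy_kbt": self.energy,
                "count": self.counts,
                "defined": self.defined,
            }
        )


def boltzmann_invert(
    hist: PositionHistogram, temperature: float
) -> EnergyLandscape:
    """Invert a 1-D position histogram into an energy landscape.

    E(bin) = -ln p(bin) in k_B T units, shifted so the minimum over
    defined (non-empty) bins is zero.  Multiplying all counts by a
    constant leaves the landscape unchanged (the normalisation constant
    absorbs it).
    """
    if hist.ndim != 1:
        raise ValueError("boltzmann_invert needs a 1-D histogram")
    counts = hist.counts.astype(float)
    if counts.sum() < 1000:
        raise ValueError("need a total count of at least 1000")
    defined = counts > 0
    if defined.sum() < 3:
        raise ValueError("need at least 3 non-empty bins")
    freq = counts / counts.sum()
    energy = np.full(len(counts), np.nan)
    with np.errstate(divide="ignore"):
        energy[defined] = -np.log(freq[defined])
    e_min = np.nanmin(energy)
    energy -= e_min
    return EnergyLandscape(
        bin_centers=hist.centers[0],
        energy=energy,
        counts=counts.astype(int),
        defined=defined,
        temperature=temperature,
        norm_constant=float(np.exp(-e_min)),  # = modal frequency
    )


def barrier_depth(landscape: EnergyLandscape) -> float:
    """Depth (max - min over defined bins) of the sampled landscape, kBT.

    A *lower* bound on the true barrier out of the state: regions the
    particle never visited during the observation are higher than any
    defined bin.
    """
    if landscape.n_defined < 3:
        raise ValueError("landscape has fewer than 3 defined bins")
    return float(np.nanmax(landscape.energy) - np.nanmin(landscape.energy))


def default_bin_width(samples: np.ndarray) -> float:
    """Default inversion bin width for a 1-D sample.

    The largest width for which the modal bin holds at most 5% of the
    samples — the resolution side of the trade-off.  If at that width the
    shallowest defined edge bin is expected to hold fewer than 5 counts, a
    warning is logged (the deep tail of the landscape will then be noisy)
    but resolution is kept.
    """
    samples = np.asarray(samples, dtype=float)
    span = samples.max() - samples.min()
    if span <= 0:
        raise ValueError("degenerate sample: zero range")
    # scan a geometric grid of candidate widths, coarse to fine
    candidates = span / np.unique(
        np.round(np.geomspace(3, max(len(samples) // 20, 4), 200)).astype(int)
    )
    chosen = candidates.min()
    for bw in np.sort(candidates)[::-1]:
        nbins = max(3, int(np.ceil(span / bw)))
        counts, _ = np.histogram(samples, bins=nbins)
        if counts.max() <= MODAL_FRACTION_LIMIT * len(samples):
            chosen = bw
            break
    nbins = max(3, int(np.ceil(span / chosen)))
    counts, _ = np.histogram(samples, bins=nbins)
    edge_counts = counts[counts > 0]
    if edge_counts.min() < MIN_EDGE_COUNTS:
        logger.warning(
            "shallowest defined bin holds only %d counts (< %d): the deep "
            "end of the landscape will be noisy at bin width %.3g nm",
            int(edge_counts.min()),
            MIN_EDGE_COUNTS,
            chosen,
        )
    return float(chosen)


def landscape_from_samples(
    samples: np.ndarray,
    temperature: float,
    bin_width: float | None = None,
    axis: str = "z",
) -> EnergyLandscape:
    """Histogram a 1-D position sample (nm) and Boltzmann-invert it.

    ``bin_width`` defaults to :func:`default_bin_width`'s resolution rule.
    """
    samples = np.asarray(samples, dtype=float)
    if bin_width is None:
        bin_width = default_bin_width(samples)
    hist = PositionHistogram.from_samples({axis: samples}, bin_width=bin_width)
    return boltzmann_invert(hist, temperature)
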