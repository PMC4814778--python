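"""The universal input of the pipeline: a uniformly sampled 3-D position trace."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, J/K (CODATA exact value).
KB = 1.380649e-23


@dataclass
class Trajectory:
    """Uniformly sampled 3-D position trace of one tracked particle.

    Positions are stored in nanometres; ``z`` is measured from the coverslip
    wall (wall at 0) whenever a wall was present during acquisition or
    simulation.  Times are implicit: sample ``i`` was recorded at
    ``i / sampling_rate`` seconds.

    Parameters
    ----------
    sampling_rate : float
        Acquisition rate in Hz (the instrument samples at 100 kHz).
    x, y, z : ndarray
        Per-axis positions in nm; equal lengths.
    temperature : float
        Sample temperature in kelvin.
    bead_radius : float
        Tracer bead radius in metres (0.485 um for the 0.97 um bead).
    states : ndarray of str, optional
        Ground-truth state label per sample (simulated traces only).
    metadata : dict
        Free-form acquisition/simulation metadata.
    """

    sampling_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    temperature: float = 295.0
    bead_radius: float = 0.485e-6
    states: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y and z must have equal lengths")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        if self.states is not None:
            self.states = np.asarray(self.states)
            if len(self.states) != len(self.x):
                raise ValueError("states must match position length")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def axis(self, name: str) -> np.ndarray:
        """Positions along one axis ('x', 'y' or 'z'), nm."""
        if name not in ("x", "y", "z"):
            raise ValueError(f"unknown axis {name!r}")
        return getattr(self, name)

    def slice(self, start: float, end: float) -> "Trajectory":
        """Sub-trace covering times ``[start, end)`` seconds."""
        i0 = max(0, int(np.ceil(start * self.sampling_rate)))
        i1 = min(self.n_samples, int(np.ceil(end * self.sampling_rate)))
        if i1 <= i0:
            raise ValueError("empty time slice")
        return Trajectory(
            sampling_rate=self.sampling_rate,
            x=self.x[i0:i1],
            y=self.y[i0:i1],
            z=self.z[i0:i1],
            temperature=self.temperature,
            bead_radius=self.bead_radius,
            states=None if self.states is None else self.states[i0:i1],
            metadata=dict(self.metadata),
        )
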