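"""Brownian-dynamics digital twin of the trapped-bead fusion assay.

A 0.97 um silica bead, coated with a lipid bilayer, sits in a weak 3-D
harmonic optical trap near a bilayer-coated coverslip.  Each fusion
intermediate changes the forces and the drag on the bead:

``free``
    bulk Stokes drag, trap stiffness only, far from the wall;
``surface``
    bead touching the coverslip: axial motion cut off by the wall
    (specular reflection at z = 0) and drag increased by the lumped
    near-wall hindrance factor (about 3);
``transient_fusion`` / ``hemifusion``
    a membrane connection adds a stiff axial tether and extra lateral
    drag ``gamma_m`` from the stalk moving through the supported membrane;
``fused``
    the bead is immobilised; residual recorded noise is dominated by the
    nanopositioning stage (SD 1 nm axial, 1.5 nm lateral).

Each axis follows an overdamped Langevin (Euler-Maruyama) update

    dx = -(k_total / gamma_total) * (x - x_c) * dt
         + sqrt(2 k_B T dt / gamma_total) * xi,

with ``gamma_total`` the (near-wall-scaled) Stokes drag plus any membrane
drag and ``k_total`` the trap plus tether stiffness.  Stage noise is added
as independent Gaussian noise on every recorded sample.  Traces are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .trajectory import KB, Trajectory

STATE_LABELS = ("free", "surface", "transient_fusion", "hemifusion", "fused")

#: Maximum allowed k * dt / gamma for a stable Euler-Maruyama step.
STABILITY_LIMIT = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical parameters of the trap simulation.

    All quantities are SI.  Defaults reproduce the photonic-force-microscope
    conditions: a 0.485 um-radius bead in water at 295 K, sampled at
    100 kHz, with near-wall drag three times the bulk Stokes drag and
    nanopositioning-stage noise of 1 nm (axial) / 1.5 nm (lateral) SD.
    """

    temperature: float = 295.0
    bead_radius: float = 0.485e-6
    bulk_viscosity: float = 0.89e-3
    near_wall_drag_factor: float = 3.0
    sampling_rate: float = 1e5
    integrator_substeps: int = 1
    stage_noise_sd_axial: float = 1e-9
    stage_noise_sd_lateral: float = 1.5e-9
    seed: int = 0
    thermal_force_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "temperature",
            "bead_radius",
            "bulk_viscosity",
            "sampling_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.near_wall_drag_factor < 1:
            raise ValueError("near_wall_drag_factor must be >= 1")
        if self.integrator_substeps < 1:
            raise ValueError("integrator_substeps must be >= 1")
        if self.stage_noise_sd_axial < 0 or self.stage_noise_sd_lateral < 0:
            raise ValueError("stage noise SDs must be non-negative")
        if not 0 <= self.thermal_force_scale <= 1:
            raise ValueError("thermal_force_scale must be in [0, 1]")

    @property
    def stokes_drag(self) -> float:
        """Bulk Stokes drag 6*pi*eta*r, N s/m."""
        return 6.0 * math.pi * self.bulk_viscosity * self.bead_radius

    def stabilized(self, schedule: "StateSchedule") -> "SimulationConfig":
        """Copy of the config with the minimum stable substep count.

        The integration step must satisfy ``k dt / gamma <= 0.1`` for every
        segment and axis, i.e. dt at most a tenth of the fastest relaxation
        time in the schedule; the stiff fused state would otherwise be
        unstable at the raw 10 us sampling step.
        """
        n = required_substeps(self, schedule)
        if n <= self.integrator_substeps:
            return self
        return replace(self, integrator_substeps=n)


@dataclass(frozen=True)
class ScheduleSegment:
    """One labelled interval of the simulated fusion progression.

    ``trap_stiffness`` is the optical-trap stiffness per axis in N/m;
    ``tether_stiffness_z`` adds the membrane tether (hemifusion/fused
    states) in the axial direction; ``extra_membrane_drag`` is the stalk's
    contribution ``gamma_m`` in N s/m; ``trap_center_z`` is the trap centre
    height above the wall in metres.
    """

    label: str
    duration: float
    trap_stiffness: tuple[float, float, float]
    tether_stiffness_z: float = 0.0
    extra_membrane_drag: float = 0.0
    wall_present: bool = False
    trap_center_z: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(
                f"unknown state label {self.label!r}; expected one of {STATE_LABELS}"
            )
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if any(k < 0 for k in self.trap_stiffness):
            raise ValueError("trap stiffness must be non-negative")
        if self.tether_stiffness_z < 0 or self.extra_membrane_drag < 0:
            raise ValueError("tether stiffness and membrane drag must be >= 0")

    def stiffness(self, axis: str) -> float:
        """Total restoring stiffness along one axis, N/m."""
        kx, ky, kz = self.trap_stiffness
        if axis == "x":
            return kx
        if axis == "y":
            return ky
        if axis == "z":
            return kz + self.tether_stiffness_z
        raise ValueError(f"unknown axis {axis!r}")

    def drag(self, config: SimulationConfig) -> float:
        """Total drag: (near-wall-scaled) Stokes drag plus membrane drag."""
        factor = config.near_wall_drag_factor if self.wall_present else 1.0
        return config.stokes_drag * factor + self.extra_membrane_drag


@dataclass
class StateSchedule:
    """Ordered sequence of :class:`ScheduleSegment` driving the simulator."""

    segments: list[ScheduleSegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def has_wall(self) -> bool:
        return any(s.wall_present for s in self.segments)

    def transition_times(self) -> list[tuple[float, str]]:
        """(start time, label) of each segment."""
        out, t = [], 0.0
        for seg in self.segments:
            out.append((t, seg.label))
            t += seg.duration
        return out


def required_substeps(config: SimulationConfig, schedule: StateSchedule) -> int:
    """Smallest substep count for which every segment integrates stably."""
    dt = 1.0 / config.sampling_rate
    worst = 0.0
    for seg in schedule.segments:
        gamma = seg.drag(config)
        for axis in "xyz":
            k = seg.stiffness(axis)
            if k > 0:
                worst = max(worst, k * dt / gamma)
    return max(1, math.ceil(worst / STABILITY_LIMIT))


@njit(cache=True)
def _euler_axis(x0, n_record, substeps, coef, noise_amp, center, wall, normals):
    """Euler-Maruyama recursion for one axis of one segment.

    ``coef = k dt / gamma``; ``noise_amp = sqrt(2 kB T dt / gamma)``.
    Positions are absolute (metres); reflection at 0 when ``wall``.
    """
    out = np.empty(n_record)
    x = x0
    idx = 0
    for i in range(n_record):
        for _ in range(substeps):
            x = x - coef * (x - center) + noise_amp * normals[idx]
            idx += 1
            if wall and x < 0.0:
                x = -x
        out[i] = x
    return out


def simulate_bead_trajectory(
    config: SimulationConfig, schedule: StateSchedule
) -> Trajectory:
    """Simulate the bead's 3-D thermal motion through a fusion schedule.

    Per axis and segment the position follows the overdamped Langevin
    update documented in the module docstring.  The coverslip is treated as
    present throughout any schedule that contains a wall segment (free
    segments simply sit far above it), implemented as specular reflection
    of ``z`` at 0.  Stage noise is added per recorded sample.

    Raises
    ------
    ValueError
        If any segment violates the stability condition
        ``k * dt / gamma <= 0.1`` at the configured substep count.
    """
    needed = required_substeps(config, schedule)
    if config.integrator_substeps < needed:
        dt = 1.0 / (config.sampling_rate * config.integrator_substeps)
        raise ValueError(
            "unstable integration step (k*dt/gamma > "
            f"{STABILITY_LIMIT}) at dt = {dt:.3g} s; "
            f"use integrator_substeps >= {needed} "
            "(see SimulationConfig.stabilized)"
        )
    rng = np.random.default_rng(config.seed)
    dt_sub = 1.0 / (config.sampling_rate * config.integrator_substeps)
    wall_everywhere = schedule.has_wall

    chunks: dict[str, list[np.ndarray]] = {"x": [], "y": [], "z": []}
    state_chunks: list[np.ndarray] = []
    # start at the first segment's trap centre
    last = {"x": 0.0, "y": 0.0, "z": schedule.segments[0].trap_center_z}

    for seg in schedule.segments:
        n_rec = int(round(seg.duration * config.sampling_rate))
        if n_rec < 1:
            raise ValueError(
                f"segment {seg.label!r} shorter than one sampling interval"
            )
        gamma = seg.drag(config)
        for axis in "xyz":
            k = seg.stiffness(axis)
            coef = k * dt_sub / gamma
            noise_amp = (
                math.sqrt(2.0 * KB * config.temperature * dt_sub / gamma)
                * config.thermal_force_scale
            )
            center = seg.trap_center_z if axis == "z" else 0.0
            wall = wall_everywhere and axis == "z"
            normals = rng.standard_normal(n_rec * config.integrator_substeps)
            trace = _euler_axis(
                last[axis],
                n_rec,
                config.integrator_substeps,
                coef,
                noise_amp,
                center,
                wall,
                normals,
            )
            chunks[axis].append(trace)
            last[axis] = trace[-1]
        state_chunks.append(np.full(n_rec, seg.label))

    x = np.concatenate(chunks["x"])
    y = np.concatenate(chunks["y"])
    z = np.concatenate(chunks["z"])
    n = len(x)
    x = x + rng.normal(0.0, config.stage_noise_sd_lateral, n)
    y = y + rng.normal(0.0, config.stage_noise_sd_lateral, n)
    z_noise = rng.normal(0.0, config.stage_noise_sd_axial, n)
    z = z + z_noise
    if wall_everywhere:
        # stage noise cannot push the recorded coordinate through the wall
        np.abs(z, out=z)

    metadata = {
        "seed": config.seed,
        "substeps": config.integrator_substeps,
        "near_wall_drag_factor": config.near_wall_drag_factor,
        "stage_noise_sd_axial_nm": config.stage_noise_sd_axial * 1e9,
        "stage_noise_sd_lateral_nm": config.stage_noise_sd_lateral * 1e9,
        "bulk_viscosity": config.bulk_viscosity,
        "schedule": ";".join(
            f"{s.label}:{s.duration:g}s" for s in schedule.segments
        ),
    }
    return Trajectory(
        sampling_rate=config.sampling_rate,
        x=x * 1e9,
        y=y * 1e9,
        z=z * 1e9,
        temperature=config.temperature,
        bead_radius=config.bead_radius,
        states=np.concatenate(state_chunks),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# equilibrium sampling from a 1-D potential


@dataclass
class PotentialSpec:
    """Piecewise 1-D potential E(x) in kBT units over a bounded support.

    ``energy`` maps position (nm) to energy in units of k_B T; it must be
    finite everywhere on ``support``.  By convention the minimum over the
    support is treated as 0 (an additive constant is irrelevant for the
    Boltzmann weight).
    """

    support: tuple[float, float]
    energy: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
            raise ValueError(
                "potential support must be a bounded interval (lo, hi); "
                "unbounded supports are rejected"
            )

    def grid(self, n: int = 32769) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate on a uniform grid; energies shifted so min = 0."""
        x = np.linspace(self.support[0], self.support[1], n)
        e = np.asarray(self.energy(x), dtype=float)
        if not np.all(np.isfinite(e)):
            raise ValueError("potential must be finite on its support")
        return x, e - e.min()

    @classmethod
    def harmonic(cls, sigma: float, n_sigma: float = 8.0) -> "PotentialSpec":
        """Quadratic well E(x) = x^2 / (2 sigma^2) kBT, truncated at n_sigma."""
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        lim = n_sigma * sigma
        return cls((-lim, lim), lambda x: x**2 / (2.0 * sigma**2))

    @classmethod
    def truncated_quadratic(
        cls, depth: float, half_width: float
    ) -> "PotentialSpec":
        """Quadratic well reaching ``depth`` kBT at ``|x| = half_width`` nm."""
        if depth <= 0 or half_width <= 0:
            raise ValueError("depth and half_width must be positive")
        return cls(
            (-half_width, half_width),
            lambda x: depth * (x / half_width) ** 2,
        )

    @classmethod
    def flat(cls, lo: float, hi: float) -> "PotentialSpec":
        return cls((lo, hi), lambda x: np.zeros_like(np.asarray(x, float)))


def sample_potential_positions(
    potential: PotentialSpec,
    n: int,
    temperature: float = 295.0,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. equilibrium positions from p(x) ~ exp(-E(x)).

    Inverse-CDF sampling on a dense grid (piecewise-linear CDF).  The
    potential is expressed in units of k_B T at ``temperature``, so the
    Boltzmann weight is exp(-E) directly; ``temperature`` is kept on the
    signature for interface symmetry with the trajectory simulator and is
    recorded by callers that build histograms.

    Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x, e = potential.grid()
    w = np.exp(-e)
    # probability mass per grid cell (trapezoid)
    cell = 0.5 * (w[1:] + w[:-1])
    total = cell.sum()
    if total <= 0:
        raise ValueError("potential has no integrable Boltzmann weight")
    cdf = np.concatenate(([0.0], np.cumsum(cell) / total))
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, x)


# ---------------------------------------------------------------------------
# schedule presets

PRESETS = (
    "dopc_intermediate_tension",
    "dopc_high_tension",
    "dopc_low_tension",
    "transient_only",
)

# target fluctuation widths (2 SD, nm) of the reference fusion progression;
# free 162 axially with 82/80 laterally, surface ~96 from wall truncation,
# hemifusion 12 axially with lateral widths unchanged, fused 2-4 on all axes
FREE_WIDTH_NM = {"x": 82.0, "y": 80.0, "z": 162.0}
HEMIFUSION_WIDTH_Z_NM = 12.0
FUSED_WIDTH_Z_NM = 4.0
FUSED_WIDTH_LATERAL_NM = 4.0
#: membrane (stalk) drag of the hemifused preset, N s/m; gives the
#: hemifused lateral diffusion constant ~0.034 um^2/s on top of the
#: near-wall drag
HEMIFUSION_MEMBRANE_DRAG = 9.25e-8
#: effectively rigid membrane drag of the fully fused preset, N s/m
FUSED_MEMBRANE_DRAG = 1e-6


def _k_from_width(width_nm: float, temperature: float, noise_sd_nm: float) -> float:
    """Stiffness whose equilibrium fluctuation (plus stage noise) has the
    requested total width = 2 SD."""
    var_total = (width_nm / 2.0 * 1e-9) ** 2
    var_thermal = var_total - (noise_sd_nm * 1e-9) ** 2
    if var_thermal <= 0:
        raise ValueError("target width smaller than stage noise")
    return KB * temperature / var_thermal


def _preset_segments(temperature: float) -> dict[str, ScheduleSegment]:
    kx = _k_from_width(FREE_WIDTH_NM["x"], temperature, 0.0)
    ky = _k_from_width(FREE_WIDTH_NM["y"], temperature, 0.0)
    kz = _k_from_width(FREE_WIDTH_NM["z"], temperature, 0.0)
    trap = (kx, ky, kz)
    k_hemi_z = _k_from_width(HEMIFUSION_WIDTH_Z_NM, temperature, 1.0)
    k_fused_z = _k_from_width(FUSED_WIDTH_Z_NM, temperature, 1.0)
    k_fused_lat = _k_from_width(FUSED_WIDTH_LATERAL_NM, temperature, 1.5)
    free = ScheduleSegment(
        "free", 10.0, trap, wall_present=False, trap_center_z=400e-9
    )
    surface = ScheduleSegment("surface", 2.0, trap, wall_present=True)
    # tethered states fluctuate about a small rest height above the wall
    # (z is the recorded coordinate, not the gap), so the tight axial
    # distribution is not folded by the reflecting boundary
    hemifusion = ScheduleSegment(
        "hemifusion",
        6.6,
        trap,
        tether_stiffness_z=max(k_hemi_z - kz, 0.0),
        extra_membrane_drag=HEMIFUSION_MEMBRANE_DRAG,
        wall_present=True,
        trap_center_z=30e-9,
    )
    transient = ScheduleSegment(
        "transient_fusion",
        0.5,
        trap,
        tether_stiffness_z=max(k_hemi_z - kz, 0.0),
        extra_membrane_drag=HEMIFUSION_MEMBRANE_DRAG,
        wall_present=True,
        trap_center_z=30e-9,
    )
    fused = ScheduleSegment(
        "fused",
        5.0,
        (k_fused_lat, k_fused_lat, kz),
        tether_stiffness_z=max(k_fused_z - kz, 0.0),
        extra_membrane_drag=FUSED_MEMBRANE_DRAG,
        wall_present=True,
        trap_center_z=30e-9,
    )
    return {
        "free": free,
        "surface": surface,
        "hemifusion": hemifusion,
        "transient_fusion": transient,
        "fused": fused,
    }


def make_fusion_schedule(
    preset: str,
    *,
    temperature: float = 295.0,
    duration_scale: float = 1.0,
    overrides: dict[str, dict] | None = None,
) -> StateSchedule:
    """Build a named fusion-progression schedule.

    Presets mirror the observed progressions: ``dopc_intermediate_tension``
    runs free -> surface -> hemifusion -> fused with durations
    (10, 2, 6.6, 5) s; ``dopc_high_tension`` fuses essentially on contact;
    ``dopc_low_tension`` never leaves the surface state;
    ``transient_only`` interrupts a surface stretch with a 0.5 s
    transient-fusion blip.

    ``overrides`` maps a state label to :class:`ScheduleSegment` field
    overrides (e.g. ``{"free": {"duration": 2.0}}``);
    ``duration_scale`` rescales every duration, for cheap test traces.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    base = _preset_segments(temperature)

    def seg(label: str, **extra) -> ScheduleSegment:
        s = base[label]
        fields = dict(
            label=s.label,
            duration=s.duration,
            trap_stiffness=s.trap_stiffness,
            tether_stiffness_z=s.tether_stiffness_z,
            extra_membrane_drag=s.extra_membrane_drag,
            wall_present=s.wall_present,
            trap_center_z=s.trap_center_z,
        )
        fields.update(extra)
        if overrides and label in overrides:
            fields.update(overrides[label])
        fields["duration"] *= duration_scale
        return ScheduleSegment(**fields)

    if preset == "dopc_intermediate_tension":
        segments = [seg("free"), seg("surface"), seg("hemifusion"), seg("fused")]
    elif preset == "dopc_high_tension":
        segments = [
            seg("free", duration=5.0),
            seg("surface", duration=0.5),
            seg("hemifusion", duration=3.0),
            seg("fused"),
        ]
    elif preset == "dopc_low_tension":
        segments = [seg("free"), seg("surface", duration=30.0)]
    else:  # transient_only
        segments = [
            seg("free", duration=2.0),
            seg("surface"),
            seg("transient_fusion"),
            seg("surface"),
        ]
    return StateSchedule(segments)
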