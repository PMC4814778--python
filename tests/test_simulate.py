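"""Simulator statistics: OU equilibrium, diffusion, wall, determinism."""

import numpy as np
import pytest

import fusiontrap as ft
from fusiontrap.simulate import (
    PRESETS,
    ScheduleSegment,
    SimulationConfig,
    StateSchedule,
    required_substeps,
)

from conftest import KB, KZ_FREE


def _single_segment_trace(segment, seed=0, rate=1e5, **config_kwargs):
    schedule = StateSchedule([segment])
    config = SimulationConfig(
        seed=seed, sampling_rate=rate, **config_kwargs
    ).stabilized(schedule)
    return ft.simulate_bead_trajectory(config, schedule)


class TestEquilibrium:
    def test_free_trap_equilibrium_width(self):
        """OU equilibrium SD is sqrt(kBT/k): 81 nm axially for the free trap.

        Tolerance is 3.5x the analytic standard error of the SD of a
        correlated OU trace, SE = sigma / sqrt(2 T / (2 tau_c))."""
        duration = 40.0
        seg = ScheduleSegment("free", duration, (KZ_FREE, KZ_FREE, KZ_FREE))
        traj = _single_segment_trace(seg, seed=0)
        sigma = np.sqrt(KB * 295.0 / KZ_FREE) * 1e9  # 81.07 nm
        tau = 6 * np.pi * 0.89e-3 * 0.485e-6 / KZ_FREE  # ~13 ms
        se = sigma / np.sqrt(duration / tau)
        for axis in "xyz":
            sd = traj.axis(axis).std(ddof=1)
            assert abs(sd - sigma) < 3.5 * se

    def test_equilibrium_recovery_across_seeds(self):
        """The mean equilibrium SD over 100 seeds is within 3% of analytic
        (the residual being the finite-trace variance deficit)."""
        sigma = np.sqrt(KB * 295.0 / KZ_FREE) * 1e9
        seg = ScheduleSegment("free", 2.0, (KZ_FREE, KZ_FREE, KZ_FREE))
        sds = []
        for seed in range(100):
            traj = _single_segment_trace(seg, seed=seed, rate=1e4)
            sds.append(traj.z.std(ddof=1))
        assert abs(np.mean(sds) - sigma) / sigma < 0.03

    def test_zero_thermal_force_relaxes_to_center(self):
        """With the thermal force scaled to zero the particle sits at the
        trap centre and the recorded width is set by the stage noise."""
        seg = ScheduleSegment("free", 1.0, (KZ_FREE, KZ_FREE, KZ_FREE))
        traj = _single_segment_trace(seg, seed=1, thermal_force_scale=0.0)
        tail = slice(1000, None)  # skip the deterministic relaxation
        assert abs(np.mean(traj.z[tail])) < 0.2
        assert 2 * traj.z[tail].std(ddof=1) == pytest.approx(2.0, rel=0.1)
        assert 2 * traj.x[tail].std(ddof=1) == pytest.approx(3.0, rel=0.1)

    def test_pure_diffusion_msd_slope(self):
        """A drag-only segment diffuses with D = kBT/gamma: short-lag MSD
        slope 2D within 5% (near-wall drag, D ~ 0.148 um^2/s)."""
        seg = ScheduleSegment(
            "surface", 5.0, (0.0, 0.0, 0.0), wall_present=True,
            trap_center_z=1e-6,
        )
        traj = _single_segment_trace(seg, seed=2, bulk_viscosity=1e-3)
        gamma = 3.0 * 6 * np.pi * 1e-3 * 0.485e-6
        d_expected = KB * 295.0 / gamma * 1e12  # um^2/s
        msd = ft.compute_msd(traj, "x", max_lag=2e-4)
        est = ft.fit_short_time_diffusion(msd, 1e-4, localization_noise_sd=1.5)
        assert est.d == pytest.approx(d_expected, rel=0.05)

    def test_hemifusion_membrane_drag_slows_lateral_diffusion(self):
        """Lateral MSD slope in a membrane-connected state matches
        Stokes-Einstein on the summed drag, D = kBT/(gamma_0 + gamma_m)."""
        seg = ScheduleSegment(
            "hemifusion",
            5.0,
            (2.42e-6, 2.42e-6, KZ_FREE),
            tether_stiffness_z=1.16e-4,
            extra_membrane_drag=9.25e-8,
            wall_present=True,
            trap_center_z=30e-9,
        )
        traj = _single_segment_trace(seg, seed=3, bulk_viscosity=1e-3)
        gamma_0 = 3.0 * 6 * np.pi * 1e-3 * 0.485e-6
        d_expected = KB * 295.0 / (gamma_0 + 9.25e-8) * 1e12  # ~0.034
        msd = ft.compute_msd(traj, "x", max_lag=2e-4)
        est = ft.fit_short_time_diffusion(msd, 1e-4, localization_noise_sd=1.5)
        assert est.d == pytest.approx(d_expected, rel=0.07)


class TestContracts:
    def test_wall_reflection_keeps_z_nonnegative(self, fusion_trace):
        assert fusion_trace.z.min() >= 0.0

    def test_deterministic_for_fixed_seed(self):
        seg = ScheduleSegment("free", 0.5, (KZ_FREE, KZ_FREE, KZ_FREE))
        a = _single_segment_trace(seg, seed=9, rate=1e4)
        b = _single_segment_trace(seg, seed=9, rate=1e4)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.z, b.z)

    def test_unstable_step_rejected_with_remedy(self):
        stiff = ScheduleSegment(
            "fused",
            0.2,
            (2.3e-3, 2.3e-3, KZ_FREE),
            tether_stiffness_z=1.4e-3,
            extra_membrane_drag=1e-6,
            wall_present=True,
        )
        schedule = StateSchedule([stiff])
        config = SimulationConfig(sampling_rate=1e3)
        with pytest.raises(ValueError, match="integrator_substeps"):
            ft.simulate_bead_trajectory(config, schedule)
        fixed = config.stabilized(schedule)
        assert fixed.integrator_substeps >= required_substeps(config, schedule)
        ft.simulate_bead_trajectory(fixed, schedule)  # now stable

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            ScheduleSegment("free", -1.0, (1e-6, 1e-6, 1e-6))
        with pytest.raises(ValueError):
            ScheduleSegment("floating", 1.0, (1e-6, 1e-6, 1e-6))


class TestPotentialSampling:
    def test_harmonic_well_sample_sd(self):
        pot = ft.PotentialSpec.harmonic(6.0)
        s = ft.sample_potential_positions(pot, 1_000_000, seed=0)
        assert abs(s.std(ddof=1) - 6.0) < 0.02

    def test_flat_potential_is_uniform(self):
        pot = ft.PotentialSpec.flat(0.0, 1.0)
        n = 100_000
        s = ft.sample_potential_positions(pot, n, seed=1)
        tol = 3.0 * (1.0 / np.sqrt(12.0)) / np.sqrt(n)
        assert abs(s.mean() - 0.5) < tol
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_same_seed_identical_samples(self):
        pot = ft.PotentialSpec.harmonic(6.0)
        a = ft.sample_potential_positions(pot, 1000, seed=7)
        b = ft.sample_potential_positions(pot, 1000, seed=7)
        assert np.array_equal(a, b)

    def test_unbounded_support_rejected(self):
        with pytest.raises(ValueError, match="bounded"):
            ft.PotentialSpec((0.0, np.inf), lambda x: x)


class TestPresets:
    def test_intermediate_tension_progression(self):
        sch = ft.make_fusion_schedule("dopc_intermediate_tension")
        assert [s.label for s in sch.segments] == [
            "free",
            "surface",
            "hemifusion",
            "fused",
        ]
        assert [s.duration for s in sch.segments] == [10.0, 2.0, 6.6, 5.0]

    def test_low_tension_never_fuses(self):
        sch = ft.make_fusion_schedule("dopc_low_tension")
        assert {s.label for s in sch.segments} == {"free", "surface"}

    def test_transient_only_has_blip(self):
        sch = ft.make_fusion_schedule("transient_only")
        labels = [s.label for s in sch.segments]
        assert "transient_fusion" in labels
        blip = sch.segments[labels.index("transient_fusion")]
        assert blip.duration == 0.5

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            ft.make_fusion_schedule("dppc")

    @pytest.mark.parametrize("preset", PRESETS)
    def test_presets_are_integrable(self, preset):
        sch = ft.make_fusion_schedule(preset)
        config = ft.SimulationConfig().stabilized(sch)
        assert required_substeps(config, sch) <= config.integrator_substeps
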