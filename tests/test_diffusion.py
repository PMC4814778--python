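"""MSD estimation, short-time diffusion fits and the drag decomposition."""

import numpy as np
import pytest

import fusiontrap as ft
from fusiontrap.simulate import ScheduleSegment, SimulationConfig, StateSchedule

from conftest import KB


def _brute_force_msd(x, rate, max_k):
    """Independent double-loop oracle for the time-averaged MSD."""
    n = len(x)
    msd = [0.0]
    counts = [n]
    for k in range(1, max_k + 1):
        acc = 0.0
        for i in range(n - k):
            acc += (x[i + k] - x[i]) ** 2
        msd.append(acc / (n - k))
        counts.append(n - k)
    return np.array(msd), np.array(counts)


def _trace_from_positions(x, rate=1e4):
    return ft.Trajectory(
        sampling_rate=rate, x=x, y=np.zeros_like(x), z=np.zeros_like(x)
    )


class TestComputeMSD:
    def test_matches_brute_force_oracle(self, rng):
        x = np.cumsum(rng.normal(0, 3.0, 2000)) + rng.normal(0, 1.5, 2000)
        traj = _trace_from_positions(x)
        curve = ft.compute_msd(traj, "x", max_lag=30 / 1e4)
        oracle, counts = _brute_force_msd(x, 1e4, 30)
        np.testing.assert_allclose(curve.msd, oracle, rtol=1e-10)
        np.testing.assert_array_equal(curve.counts, counts)

    def test_constant_trace_msd_zero(self):
        traj = _trace_from_positions(np.full(5000, 2.5))
        curve = ft.compute_msd(traj, "x", max_lag=1e-3)
        assert np.all(curve.msd == 0.0)

    def test_ou_plateau_at_twice_variance(self):
        """Trap-confined MSD plateaus at 2 sigma^2 at lags >> tau_c."""
        kz = 6.2e-7
        seg = ScheduleSegment("free", 200.0, (kz, kz, kz))
        schedule = StateSchedule([seg])
        config = SimulationConfig(
            seed=21, sampling_rate=1e3, stage_noise_sd_axial=0.0,
            stage_noise_sd_lateral=0.0,
        ).stabilized(schedule)
        traj = ft.simulate_bead_trajectory(config, schedule)
        sigma2 = KB * 295.0 / kz * 1e18  # nm^2
        curve = ft.compute_msd(traj, "z", max_lag=0.2)
        plateau = curve.msd[curve.lags > 0.15].mean()
        assert plateau == pytest.approx(2 * sigma2, rel=0.05)

    def test_too_short_segment_rejected(self):
        traj = _trace_from_positions(np.zeros(50))
        with pytest.raises(ValueError, match="too short"):
            ft.compute_msd(traj, "x", max_lag=10 / 1e4)


class TestShortTimeFit:
    def _free_bead_trace(self, seed=4, duration=5.0):
        seg = ScheduleSegment("free", duration, (0.0, 0.0, 0.0))
        schedule = StateSchedule([seg])
        config = SimulationConfig(
            seed=seed, sampling_rate=1e5, bulk_viscosity=1e-3
        ).stabilized(schedule)
        return ft.simulate_bead_trajectory(config, schedule)

    def test_free_diffusion_recovery(self):
        """D of a freely diffusing 0.485 um bead (0.445 um^2/s) within 5%."""
        traj = self._free_bead_trace()
        d_true = KB * 295.0 / (6 * np.pi * 1e-3 * 0.485e-6) * 1e12
        curve = ft.compute_msd(traj, "x", max_lag=2e-4)
        est = ft.fit_short_time_diffusion(curve, 1e-4, localization_noise_sd=1.5)
        assert est.d == pytest.approx(d_true, rel=0.05)

    def test_noise_only_trace_floors_near_zero(self, rng):
        traj = _trace_from_positions(rng.normal(0, 1.5, 100_000), rate=1e5)
        curve = ft.compute_msd(traj, "x", max_lag=2e-4)
        est = ft.fit_short_time_diffusion(curve, 1e-4)
        assert est.d <= 0.01
        assert est.noise_floor == pytest.approx(2 * 1.5**2, rel=0.1)

    def test_fit_range_insensitive_for_pure_diffusion(self):
        traj = self._free_bead_trace(seed=6, duration=10.0)
        curve = ft.compute_msd(traj, "x", max_lag=1.2e-3)
        d1 = ft.fit_short_time_diffusion(curve, 0.5e-3, localization_noise_sd=1.5).d
        d2 = ft.fit_short_time_diffusion(curve, 1.0e-3, localization_noise_sd=1.5).d
        assert abs(d1 - d2) / d1 < 0.05

    def test_degenerate_fit_rejected(self):
        curve = ft.MSDCurve(
            lags=np.array([0.0, 1e-5, 2e-5]),
            msd=np.array([0.0, 1.0, 2.0]),
            counts=np.array([100, 99, 98]),
        )
        with pytest.raises(ValueError, match="at least 3 lags"):
            ft.fit_short_time_diffusion(curve, 1.5e-5)


class TestSlidingDiffusion:
    def test_stepwise_plateaus_on_fusion_trace(self, fusion_results):
        """The windowed D profile steps D_inf -> D_0 -> D_hf -> ~0."""
        res = fusion_results
        assert res.d_inf is not None and res.d_0 is not None
        assert res.d_hf is not None
        assert res.d_inf > res.d_0 > res.d_hf
        fused = [s for s in res.segments if s.label == "fused"][0]
        final = [
            e.d
            for e in res.diffusion
            if fused.start + 0.5 <= e.window_center <= fused.end - 0.5
        ]
        assert np.median(final) < 0.01

    def test_near_wall_plateau_ratio_one_third(self, fusion_results):
        assert fusion_results.d_0 / fusion_results.d_inf == pytest.approx(
            1.0 / 3.0, rel=0.15
        )

    def test_homogeneous_trace_plateau_constant(self, free_trace):
        estimates = ft.sliding_diffusion(free_trace, "x", window=1.0)
        values = np.array([e.d for e in estimates])
        assert values.std() / values.mean() < 0.10

    def test_window_longer_than_trace_rejected(self, free_trace):
        with pytest.raises(ValueError, match="longer than trace"):
            ft.sliding_diffusion(free_trace, "x", window=60.0)


class TestDragDecomposition:
    def test_published_scale_example(self):
        """T = 295 K, D_0 = 0.148, D_hf = 0.034 um^2/s gives
        gamma_m ~ 9.2e-8 N s/m and D_m ~ 0.044 um^2/s."""
        dd = ft.decompose_drag(0.148, 0.0340, 295.0)
        assert dd.gamma_m == pytest.approx(9.227e-8, rel=1e-3)
        assert dd.d_m == pytest.approx(0.0441, rel=1e-2)
        assert dd.delta_d == pytest.approx(0.114)

    def test_halving_symmetry(self):
        """D_hf = D_0/2 implies gamma_m = gamma_0 and D_m = D_0 exactly."""
        dd = ft.decompose_drag(0.2, 0.1, 295.0)
        assert dd.gamma_m == pytest.approx(dd.gamma_0, rel=1e-12)
        assert dd.d_m == pytest.approx(0.2, rel=1e-12)

    def test_additivity_round_trip(self):
        dd = ft.decompose_drag(0.148, 0.034, 295.0)
        assert dd.gamma_hf == dd.gamma_0 + dd.gamma_m  # exact by construction
        d_hf_back = KB * 295.0 / (dd.gamma_0 + dd.gamma_m) * 1e12
        assert d_hf_back == pytest.approx(0.034, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="smaller than D_0"):
            ft.decompose_drag(0.1, 0.2, 295.0)
        with pytest.raises(ValueError, match="fused"):
            ft.decompose_drag(0.1, 0.0, 295.0)

    def test_membrane_drag_recovery_across_seeds(self):
        """Median relative error of D_m recovered from simulated
        surface+hemifusion traces with known gamma_m is < 10%."""
        gamma_m_true = 9.25e-8
        surface = ScheduleSegment(
            "surface", 3.0, (2.42e-6, 2.55e-6, 6.2e-7), wall_present=True
        )
        hemi = ScheduleSegment(
            "hemifusion",
            3.0,
            (2.42e-6, 2.55e-6, 6.2e-7),
            tether_stiffness_z=1.16e-4,
            extra_membrane_drag=gamma_m_true,
            wall_present=True,
            trap_center_z=30e-9,
        )
        schedule = StateSchedule([surface, hemi])
        d_m_true = KB * 295.0 / gamma_m_true * 1e12
        errors = []
        for seed in range(100):
            config = SimulationConfig(
                seed=seed, sampling_rate=1e4
            ).stabilized(schedule)
            traj = ft.simulate_bead_trajectory(config, schedule)
            d_vals = {}
            for label, (t0, t1) in {"s": (0.0, 3.0), "h": (3.0, 6.0)}.items():
                sub = traj.slice(t0 + 0.2, t1)
                curve = ft.compute_msd(sub, "x", max_lag=1e-3)
                d_vals[label] = ft.fit_short_time_diffusion(
                    curve, 1e-3, localization_noise_sd=1.5
                ).d
            dd = ft.decompose_drag(d_vals["s"], d_vals["h"], 295.0)
            errors.append(abs(dd.d_m - d_m_true) / d_m_true)
        assert np.median(errors) < 0.10
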