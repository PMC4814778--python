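import numpy as np
import pytest
from hypothesis import settings

import fusiontrap as ft

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None
)
settings.load_profile("default")

#: Boltzmann constant, J/K
KB = 1.380649e-23

#: trap stiffness whose axial equilibrium width is 162 nm at 295 K
KZ_FREE = 6.2e-7

#: sampling rate used for the cheap pipeline fixtures; the width and
#: diffusion statistics of interest live at >= 1 ms timescales, so 10 kHz
#: resolves them at a tenth of the simulation cost of the full 100 kHz
FAST_RATE = 1e4


def simulate_preset(preset, seed, rate=FAST_RATE, **kwargs):
    schedule = ft.make_fusion_schedule(preset, **kwargs)
    config = ft.SimulationConfig(seed=seed, sampling_rate=rate).stabilized(
        schedule
    )
    return ft.simulate_bead_trajectory(config, schedule), schedule


@pytest.fixture(scope="session")
def fusion_trace():
    """A full fusion progression: free -> surface -> hemifusion -> fused."""
    traj, schedule = simulate_preset("dopc_intermediate_tension", seed=3)
    return traj


@pytest.fixture(scope="session")
def fusion_results(fusion_trace):
    return ft.FusionTraceModel(fusion_trace).fit()


@pytest.fixture(scope="session")
def free_trace():
    """A free-trap trace (no wall), 10 s at 10 kHz."""
    seg = ft.ScheduleSegment("free", 10.0, (KZ_FREE, KZ_FREE, KZ_FREE))
    schedule = ft.StateSchedule([seg])
    config = ft.SimulationConfig(seed=5, sampling_rate=FAST_RATE).stabilized(
        schedule
    )
    return ft.simulate_bead_trajectory(config, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
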