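import numpy as np
import pytest

from gcampflux import simulate as sim


@pytest.fixture
def protocol20():
    """Standard trial: 20 Hz, 2-s train starting at 1 s, 8-s record."""
    return sim.StimulusProtocol(frequency=20.0)


@pytest.fixture
def linear_indicator():
    """Indicator operated far below Kd: dF/F is ~proportional to Ca."""
    return sim.IndicatorModel(kd=20000.0, hill_n=1.0, rmax=100.0, binding_tau=0.0)


@pytest.fixture
def gcamp1():
    return sim.INDICATOR_PRESETS["GCaMP1.3"]


@pytest.fixture
def small_imaging():
    """Three small boutons on a 80x64 frame, noiseless."""
    boutons = tuple(
        sim.BoutonSpec(center=(16.0 + 22 * i, 16.0), radius=5.0, f0=100.0 + 10 * i,
                       terminal_type="Ib", nmj_id=i // 2)
        for i in range(3))
    return sim.ImagingModel(frame_shape=(80, 64), boutons=boutons,
                            background_level=100.0, noise_sigma=0.0, rng_seed=0)


@pytest.fixture
def type2_calcium():
    return sim.CalciumModel(ca_rest=50.0, delta_ca_per_ap=4.0, k_leak=0.3,
                            pump_vmax=21.0, pump_km=30.0)


def frame_times(n, frame_rate=25.0):
    return (np.arange(n) + 0.5) / frame_rate
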