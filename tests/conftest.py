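import numpy as np
import pytest

from icpest import SynthConfig, WaveformSignal, synth_abp


@pytest.fixture
def clean_config():
    """Deterministic pulsatile ABP: no noise, no slow variability."""
    return SynthConfig(duration=60.0, fs=100.0, heart_rate=60.0,
                       mean_abp=90.0, pulse_pressure=40.0, hr_jitter=0.0,
                       noise_std=0.0, cbfv_noise_std=0.0, slow_abp_std=0.0,
                       slow_cbfv_std=0.0, resp_abp_amp=0.0,
                       vm_window=None, seed=1)


@pytest.fixture
def clean_abp(clean_config):
    return synth_abp(clean_config)


@pytest.fixture
def constant_signal():
    return WaveformSignal(np.full(6000, 100.0), fs=100.0, units="mmHg")
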