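"""Self-consistency of the two-element estimator.

Generates flow data directly from the two-element model -- a single
arterial resistance R_a = 6 mmHg·s/ml and compliance C_a = 0.15 ml/mmHg
between cerebral arterial pressure and a constant ICP of 10 mmHg -- and
checks that the estimator identifies all three quantities from the
waveforms alone.
"""

import numpy as np

from icpest import (KashifParams, SynthConfig, WaveformSignal,
                    kashif_estimate, synth_abp)

CA_TRUE, RA_TRUE, ICP_TRUE = 0.15, 6.0, 10.0

print(f"{'seed':>4} {'C_a':>7} {'R_a':>7} {'ICP':>7}")
for seed in (1, 2, 3, 4, 5):
    cfg = SynthConfig(duration=60.0, fs=100.0, heart_rate=70.0,
                      mean_abp=95.0, pulse_pressure=40.0, hr_jitter=0.02,
                      noise_std=0.0, cbfv_noise_std=0.0, slow_abp_std=0.0,
                      slow_cbfv_std=0.0, resp_abp_amp=0.0, vm_window=None,
                      seed=seed)
    pmca = synth_abp(cfg)
    dpdt = np.gradient(pmca.values) * cfg.fs
    q = (pmca.values - ICP_TRUE) / RA_TRUE + CA_TRUE * dpdt
    cbfv = WaveformSignal(q / 0.15, cfg.fs, units="cm/s")
    series, ca, ra, _ = kashif_estimate(pmca, cbfv,
                                        KashifParams(window_s=60.0),
                                        return_params=True, tau=0.0)
    print(f"{seed:4d} {np.median(ca):7.4f} {np.median(ra):7.3f} "
          f"{series.icp.mean():7.3f}")
print(f"true {CA_TRUE:7.4f} {RA_TRUE:7.3f} {ICP_TRUE:7.3f}")
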