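"""Explore the lumped-parameter intracranial circuit.

Prints the resistive (DC) operating point of the circuit over a range of
arterial pressures -- cerebral blood flow, capillary, venous-sinus and
intracranial pressure -- then drives the dynamic circuit with a pulsatile
synthetic ABP and shows that the time-averaged traces sit on the DC
solution while ICP carries a small cardiac pulsation.
"""

import numpy as np

from icpest import SynthConfig, simulate, steady_state, synth_abp

print("DC operating points (all pressures mmHg, flow ml/s):")
print(f"{'Pa':>5} {'Q_CBF':>7} {'P_c':>7} {'P_vs':>6} {'P_ic':>6}")
for pa in (60, 80, 100, 120):
    ss = steady_state(pa)
    print(f"{pa:5.0f} {ss['Q_CBF']:7.2f} {ss['P2']:7.2f} "
          f"{ss['Pvs']:6.2f} {ss['Pic']:6.2f}")

cfg = SynthConfig(duration=60.0, fs=100.0, heart_rate=72.0, mean_abp=100.0,
                  pulse_pressure=40.0, vm_window=None, seed=1)
abp = synth_abp(cfg)
sim = simulate(abp)
ss = steady_state(float(abp.values.mean()))
pulse_pp = float(np.percentile(sim.Pic, 98) - np.percentile(sim.Pic, 2))
print(f"\npulsatile run at mean ABP {abp.values.mean():.1f} mmHg:")
print(f"  mean simulated ICP {sim.Pic.mean():6.2f} mmHg "
      f"(DC solution {ss['Pic']:.2f})")
print(f"  mean simulated CBF {sim.Q_CBF.mean():6.2f} ml/s "
      f"(DC solution {ss['Q_CBF']:.2f})")
print(f"  ICP cardiac pulsation ~{pulse_pp:.1f} mmHg peak-to-peak")
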