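"""Rectification coefficient and sensor response from I-V sweeps.

Builds two synthetic cyclic-voltammetry sweeps — a baseline aptamer sensor
(r = -0.5) and the same sensor after a dopamine-like 11 % current decrease —
and extracts the figures of merit an experimenter quotes.
"""

import numpy as np

from aptapore.iv import IVCurve, rectification_coefficient, sensor_response
from aptapore.synth import gen_iv

baseline = gen_iv(r_true=-0.5, R_true=367e6, noise_sd=0.0, seed=0,
                  label="aptamer sensor in PBS")
target = IVCurve(baseline.voltage, baseline.current * 0.89,
                 label="after 1 nM dopamine")

r = rectification_coefficient(baseline, v_eval=0.5)
resp = sensor_response(baseline, target, v_eval=0.5)

print(f"rectification coefficient r = {r:+.3f}")
print(f"sensor response at +0.5 V  = {resp:+.1f} %")
print()
print("r is log10 |I(+0.5V)/I(-0.5V)|: -0.5 means transport is favoured at")
print("negative bias, the signature of the negatively charged DNA layer.")
print("The -11 % response is the dopamine direction (current decrease);")
print("serotonin sensors respond with a current increase instead.")
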