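"""The CH4 oxidation kinetics model: prediction, O2 optimum, refit.

ln MOX = 20.08 + 0.79 ln[CH4] - 5669.61/T + ln(e^(-0.01 O2) - e^(-0.19 O2))

The rate rises as a 0.79-power of CH4, follows an Arrhenius-type
temperature response, and is unimodal in O2: zero when anoxic, peaking
at micro-oxic concentrations.
"""

import numpy as np

from lakemox import calibrate_o2, fit_params, o2_optimum, predict_mox

print(f"O2 optimum of the rate bracket: {o2_optimum():.2f} uM (micro-oxic peak)")
for o2 in [0.0, 5.0, o2_optimum(), 100.0, 250.0]:
    rate = predict_mox(ch4=50.0, o2=o2, temp_k=288.15)
    print(f"  CH4 50 uM, 15 C, O2 {o2:6.2f} uM -> MOX {rate:6.2f} umol/L/d")

cal, anoxic = calibrate_o2(8.0)
print(f"\nSensor O2 8.0 uM -> calibrated {cal:.2f} uM, anoxic: {anoxic}")

# refit the model to its own noise-free output: coefficients come back exactly
ch4 = np.geomspace(0.1, 400, 10)
o2 = np.linspace(1, 250, 10)
temp = np.linspace(277, 298, 8)
c, o, t = (a.ravel() for a in np.meshgrid(ch4, o2, temp, indexing="ij"))
fit = fit_params(c, o, t, np.log(predict_mox(c, o, t)))
p = fit.params
print(
    f"refit on {fit.n_obs} noise-free points: ln[CH4] coefficient {p.ch4_exponent:.6f}, "
    f"1/T coefficient {p.temp_coefficient:.4f}"
)
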