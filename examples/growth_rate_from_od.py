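"""Fit a specific growth rate from an OD600 time course.

Builds a lag/exponential/stationary curve, lets the window detector
find the exponential phase, and compares treated growth to controls.
"""

import numpy as np

import solvtol as st

# a culture with 2 h lag, mu = 0.5 /h, stationary at OD 0.4
t = np.arange(0.0, 9.0)
od = np.where(t <= 2, 0.05,
              np.minimum(0.05 * np.exp(0.5 * (t - 2)), 0.4))
series = st.ODSeries("demo", "CF", 1.0, "r1", t, od)

fit = st.fit_growth_rate(series)
print(f"exponential window: {fit.window[0]:.1f}-{fit.window[1]:.1f} h "
      f"({fit.n_points} points, R2 = {fit.fit_r2:.4f})")
print(f"specific growth rate mu = {fit.mu:.4f} /h")

# percent-of-control: three treated replicates at half the control rate
control = [st.GrowthFit(0.50, (2.0, 7.0), 5, 1.0, False, 0.6)] * 3
treated = [st.GrowthFit(0.25, (2.0, 7.0), 5, 1.0, False, 0.4)] * 3
rel = st.relative_growth(treated, control, concentration=1.0)
print(f"treated growth = {rel.mean_percent:.1f}% of mu0 ({rel.mu0:.2f} /h) "
      f"-> this dose sits exactly at the EC50")
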