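"""Localize episodic perturbations with the drift-diffusion-jump analysis.

Simulates a cyclone-free series, injects three single-month crashes of
5x the increment SD (stand-ins for cyclone impacts), and shows that the
three largest jump-intensity peaks land on the injected months.
"""

import numpy as np

import roosttrend as rt
from roosttrend.early_warning import _prepare

ds = rt.simulate(rt.default_scenario(seed=50,
                                     schedule=rt.CycloneSchedule(())))
x, _ = _prepare(ds.counts, deseasonalize=True)
dx = np.diff(x)
sd = dx.std()
shock_months = (22, 81, 105)
for s in shock_months:
    x[s:] += -5.0 * sd - dx[s - 1]

res = rt.ddj(np.exp(x))
lam, time = res.jump_intensity, res.time
peaks = []
for i in np.argsort(-lam):
    if 0 < i < len(lam) - 1 and lam[i] >= lam[i - 1] and lam[i] >= lam[i + 1]:
        if all(abs(time[i] - time[j]) >= 9.0 for j in peaks):
            peaks.append(i)
    if len(peaks) == 3:
        break

print(f"increment SD of the deseasonalized log series: {sd:.3f}")
print(f"injected single-month crashes at months: {list(shock_months)}")
print("three largest jump-intensity peaks (month, intensity):")
for i in sorted(peaks, key=lambda i: time[i]):
    print(f"  t = {time[i]:6.1f}   lambda = {lam[i]:.3f}")
print("\nEach peak should sit within ~2 months of an injected crash; the")
print("diffusion component stays near the background increment variance "
      f"({np.median(res.diffusion):.4f} vs {sd**2:.4f} log-units^2/month).")
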