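"""Project the population beyond the end of the series.

For each retained posterior draw the process and in-camp layers are
simulated forward from that draw's final state; quantile bands summarise
the predictive distribution, with and without a hypothetical cyclone at
the first projected month.
"""

import roosttrend as rt

ds = rt.simulate(rt.default_scenario(seed=3))
cfg = rt.McmcConfig(n_chains=3, n_iter=2000, n_burnin=1000, seed=4)
draws = rt.fit(ds.counts, ds.schedule, cfg)

T = ds.counts.n_months
calm = rt.project(draws, horizon_months=24, seed=9)
hit = rt.project(draws, horizon_months=24,
                 future_schedule=rt.CycloneSchedule((T,)), seed=9)

print("projected total population (posterior medians):")
print("months ahead   no cyclone     cyclone at month 1")
for h in (5, 11, 17, 23):
    print(f"{h + 1:12d}   {calm['total_q0.5'].iloc[h]:12,.0f}  "
          f"{hit['total_q0.5'].iloc[h]:12,.0f}")
drop = 1 - hit['total_q0.5'].iloc[23] / calm['total_q0.5'].iloc[23]
print(f"\nafter two years the cyclone path sits {100 * drop:.0f}% below the "
      "calm path,\nreflecting the pulse of excess mortality and the lost "
      "breeding season.")
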