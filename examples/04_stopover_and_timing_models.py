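"""Stopover-duration and departure-time regressions.

Simulates minimum stopover durations (negative binomial, short-distance
mean 10.7 days vs long-distance 3.3 days, the study's group estimates)
and within-night departure times (Student-t, onshore flights 4.6% of
night length later than offshore), fits both Bayesian regressions, and
prints the group means and contrasts with 90% HPD intervals.
"""

import numpy as np

from migroute.glms import (DepartureTimeObservation, StopoverObservation,
                           fit_departure_time_model, fit_stopover_model)

rng = np.random.default_rng(3)

stop_obs = []
for species, group, mean in (("Blackcap", "short", 10.7),
                             ("Garden Warbler", "long", 3.3)):
    phi = 5.0
    y = rng.negative_binomial(phi, phi / (phi + mean), 80)
    routes = rng.permutation(["offshore", "onshore"] * 40)
    stop_obs += [StopoverObservation(int(d), species, r, group)
                 for d, r in zip(y, routes)]
fit = fit_stopover_model(stop_obs, seed=1, n_chains=2, n_iter=8000,
                         n_warmup=2000)
print("minimum stopover duration (days):")
print(fit.table.to_string(index=False))

time_obs = []
for species in ("Blackcap", "Garden Warbler"):
    for route, loc in (("offshore", 0.25), ("onshore", 0.296)):
        y = loc + 0.1 * rng.standard_t(5.0, 40)
        time_obs += [DepartureTimeObservation(float(v), species, route)
                     for v in y]
tfit = fit_departure_time_model(time_obs, seed=2, n_chains=2, n_iter=8000,
                                n_warmup=2000)
print("\ndeparture time relative to night length:")
print(tfit.table.to_string(index=False))
print("\nThe short - long stopover contrast recovers the ~7.4-day gap;"
      "\nthe onshore - offshore timing contrast recovers the ~0.046 offset"
      "\n(about half an hour for a 9.3-hour night).")
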