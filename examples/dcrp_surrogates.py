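"""Diagonal cross-recurrence profile with shuffle-surrogate significance band.

For the X-drives-Y oscillator scenario the recurrent mass sits off-centre
on the X-leading (negative-lag) side; 39 shuffles of Y give a pointwise
p < .05 envelope showing which lags carry real temporal structure.
"""

import numpy as np

from irnet import dcrp_with_surrogates, scenario_params, simulate

traj = simulate(scenario_params("x_drives_y"))
profile = dcrp_with_surrogates(
    traj.state_x(),
    traj.state_y(),
    rr_cross=0.03,
    n_surrogates=39,
    seed=1,
    max_lag=50,
)

peak = profile.peak_lag()
outside = (profile.rate < profile.surrogate_lo) | (
    profile.rate > profile.surrogate_hi
)
print(f"peak of the profile at lag {peak:+d} "
      f"({'X leads' if peak < 0 else 'Y leads' if peak > 0 else 'synchronous'})")
print(f"{outside.sum()} of {len(profile.lags)} lags fall outside the "
      f"39-surrogate envelope (pointwise p < .05)")
side = profile.rate[profile.lags < 0].sum() / profile.rate[profile.lags > 0].sum()
print(f"recurrent mass ratio, X-leading over Y-leading lags: {side:.2f}")
print("\nNegative lags collect recurrences in which X's state appears first"
      "\nand recurs later in Y; a peak there corroborates the IRN call that"
      "\nX drives Y in this scenario.")
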