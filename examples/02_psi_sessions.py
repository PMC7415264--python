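"""Bayesian adaptive (Psi) threshold estimation with the session protocol.

Runs the full measurement chain for one observer: a coarse one-down
one-up pre-staircase to centre the prior, then five 45-trial Psi sessions
(44 analysed each), aggregated into a single threshold backed by 220
analysed trials.
"""

import numpy as np

import crossmodal as cm
from crossmodal.psi import aggregate_sessions, default_psi_grid, run_psi_session
from crossmodal.staircase import run_prestaircase

pf = cm.PsychometricFunction(alpha=-18.0, beta=2.0, lapse=0.02)
grid = default_psi_grid()
rng = np.random.default_rng(1)

prior_center = run_prestaircase(pf, rng=rng)
print(f"pre-staircase prior centre: {prior_center:.2f} dB SNR")

session_thresholds = []
for day in range(1, 6):
    res = run_psi_session(pf, grid, prior_center, rng)
    session_thresholds.append(res.threshold_db)
    print(f"  session {day}: {res.threshold_db:.2f} dB SNR "
          f"({res.posterior_at_readout.trial_count} trials analysed)")

agg = aggregate_sessions(session_thresholds)
print(f"aggregated threshold: {agg.threshold_db:.2f} dB SNR "
      f"(true alpha {pf.alpha}, {agg.contributing_trials} contributing trials)")
# Each session's estimate is the posterior mean of the threshold marginal;
# the aggregate is the mean of the five session estimates.
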