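"""Simulate a 2IFC observer and estimate its threshold with a staircase.

Builds a logistic observer with a true threshold of -15 dB SNR, runs one
two-down one-up track (published step schedule, start at 0 dB SNR), and
compares the reversal-based estimate with the analytic 70.7%-correct
level the rule converges to.
"""

import numpy as np

import crossmodal as cm

pf = cm.PsychometricFunction(alpha=-15.0, beta=2.0, lapse=0.02)
rng = np.random.default_rng(0)

threshold, state = cm.run_staircase(pf, rng=rng)
analytic = cm.level_at_p(pf, np.sqrt(0.5))

print(f"true threshold (alpha):        {pf.alpha:.2f} dB SNR")
print(f"analytic 70.7%-correct level:  {analytic:.2f} dB SNR")
print(f"staircase estimate:            {threshold:.2f} dB SNR")
print(f"trials used:                   {len(state.trial_log)}")
print(f"reversals recorded:            {len(state.reversal_levels)}")
# The estimate is the mean of the final 10 reversal levels; it targets the
# 70.7%-correct point of the psychometric function, not alpha itself.
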