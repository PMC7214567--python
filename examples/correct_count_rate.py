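"""Correct a single observed count rate for paralyzable dead time.

A camera with a 1.3 us resolving time reports 87.81 kcps in the open
window; the Lambert-W inversion recovers the rate it would have recorded
with no dead time, and with the sensitivity C the activity in view.
"""

import deadtime as dt

TAU = 1.3e-6            # s
SENSITIVITY = 0.78e-3   # cps/Bq  (0.78 kcps/MBq)
OBSERVED = 87.81e3      # cps

true_rate = dt.correct_rate(OBSERVED, TAU)
factor = dt.correction_factor(OBSERVED, TAU)
activity = dt.estimate_activity(OBSERVED, TAU, SENSITIVITY)

print(f"observed rate : {OBSERVED / 1e3:8.2f} kcps")
print(f"corrected rate: {true_rate / 1e3:8.2f} kcps")
print(f"correction    : {100 * (factor - 1):8.1f} %  of the observed rate")
print(f"activity      : {activity / 1e6:8.1f} MBq  (= corrected rate / C)")
print(f"ceiling       : {dt.max_observed_rate(TAU) / 1e3:8.1f} kcps  -- rates above "
      "this cannot be corrected at all")

# The ~14% correction says one in seven true events was swallowed by dead
# time at this rate; the ceiling is the hard limit of the method.
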