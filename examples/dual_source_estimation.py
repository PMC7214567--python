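"""Dead time from source combinations (dual/triple-source method).

Simulates the combination schedule — sources 1, 2, 1+2, 3, 1+2+3 — and
turns each combined frame plus its two component frames into one dead-time
estimate via tau = 2*R12'/(R1'+R2')**2 * ln((R1'+R2')/R12').
"""

import deadtime as dt

series = dt.simulate_series(dt.make_intrinsic_preset(seed=3, poisson_noise=True))
results = dt.triple_source_schedule(series, "det1", "OW")

print("total activity (MBq)   tau (us)   valid")
for r in sorted(results, key=lambda r: r.total_activity):
    print(f"{r.total_activity / 1e6:12.1f}        {r.tau * 1e6:8.3f}   {r.valid}")

in_band = [r.tau for r in results
           if r.valid and 30e6 < r.total_activity < 350e6]
mean = sum(in_band) / len(in_band)
print(f"\nmean tau over 30-340 MBq: {mean * 1e6:.3f} us  (truth 1.300 us)")
print("low-activity estimates scatter (little dead time to measure);")
print("the highest-activity one is biased by the camera's model breakdown.")
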