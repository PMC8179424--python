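"""Photon distribution analysis: separate distance states from shot noise.

Simulates bursts at a planted closed-B/closed-A population ratio of 1.61
(the well-resolved nucleotide-analogue condition), fits a three-state PDA
model with constrained means, and prints the recovered weights and ratio
with a bootstrap confidence interval.
"""

from fretdyn.workflows import recover_state_ratio

res = recover_state_ratio(ratio=1.61, open_weight=0.20, seed=1,
                          duration=1500.0, n_boot=30)
print(f"{res['n_bursts']} bursts analysed, reduced chi^2 = {res['chi2_red']:.2f}")
print("fitted state weights (closed B, closed A, open):",
      [round(float(w), 3) for w in res["weights"]])
print(f"closed-B/closed-A ratio: {res['ratio']:.2f} "
      f"(95% CI {res['ci_low']:.2f}-{res['ci_high']:.2f}, planted 1.61)")
# A ratio near the planted value shows that burst-wise PDA weights estimate
# state populations once shot noise and background are modelled.
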