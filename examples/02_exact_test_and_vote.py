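"""The statistical core, step by step on hand-sized numbers.

Shows one per-sample Fisher exact table, the BH step-up correction, and how
the 3-of-4 consistency vote with its opposite-direction veto decides a call.
"""

from coldscreen import CallerConfig, bh_adjust, call_modified, fisher_gene_test

# A gene with 50 reads in a cold sample of 1e6 reads, against 120 reads in the
# pooled control condition of 4e6 reads: cold proportion is ~1.7x the control's.
p = fisher_gene_test(50, 1_000_000 - 50, 120, 4_000_000 - 120)
print(f"Fisher exact p for 50/1e6 cold vs 120/4e6 pooled control: {p:.4g}")
print("(two-sided, minimum-likelihood definition: sums all tables with the")
print(" observed margins whose probability does not exceed the observed one)\n")

# BH correction across a small family of raw p-values
raw = [0.001, 0.008, 0.039, 0.041, 0.20]
q = bh_adjust(raw)
print("BH step-up:  raw ", [f"{x:.3f}" for x in raw])
print("             adj ", [f"{x:.3f}" for x in q], "\n")

config = CallerConfig()  # alpha 0.05, at least 3 of 4 samples, veto on opposite
cases = [
    (("3 significant up, 1 not significant", [0.01, 0.02, 0.01, 0.20], ["up"] * 4)),
    (("4 significant but one down: vetoed", [0.01] * 4, ["up", "up", "up", "down"])),
    (("only 2 of 4 significant", [0.01, 0.01, 0.20, 0.20], ["up"] * 4)),
]
for label, qvals, dirs in cases:
    print(f"{label}: call = {call_modified(qvals, dirs, config)}")
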