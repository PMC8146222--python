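"""Relative qPCR quantification: 2^-ddCt, 2^-dCt and replicate tests.

A knockdown experiment read out by qPCR: target and reference (Gapdh)
Ct values in treated vs control samples, fold change by the comparative
Ct method, and a replicate summary with the two-tailed t-test and the
conventional star tiers.
"""

from lncscreen import ddct_fold_change, dct_expression, replicate_summary

# one replicate: target amplifies 2 cycles later in the knockdown while
# the reference is unchanged -> 4-fold down
fc = ddct_fold_change(ct_target_test=27.0, ct_ref_test=18.0,
                      ct_target_cal=25.0, ct_ref_cal=18.0)
print(f"2^-ddCt fold change (knockdown vs control): {fc:.3f}  "
      "(< 1 means reduced expression)")

rel = dct_expression(ct_target=28.4, ct_ref=18.4)
print(f"2^-dCt expression relative to the reference gene: {rel:.3e}")

control = [1.00, 1.08, 0.93]
knockdown = [0.21, 0.26, 0.24]
s = replicate_summary(control, knockdown)
print(f"\ncontrol   {s.mean_a:.3f} +/- {s.sem_a:.3f} (mean +/- SEM, n=3)")
print(f"knockdown {s.mean_b:.3f} +/- {s.sem_b:.3f}")
print(f"two-tailed Welch t-test p = {s.p:.2e} -> {s.tier}")
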