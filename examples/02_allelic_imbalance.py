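"""Ploidy-aware allelic-imbalance testing across donors.

Simulates read counts for 7 heterozygous donors with a true reference
allele fraction of 0.95, tests each donor and the pooled counts against
the balanced null, then re-tests the pooled counts under the two
triploid heterozygous nulls (1/3 and 2/3) to show the call is robust to
the local copy-number assumption.
"""

from allelescan import (
    SimulationConfig,
    gen_allelic_counts,
    null_sensitivity,
    ploidy_null,
    test_samples,
)

cfg = SimulationConfig(seed=1, true_ref_fraction=0.95)
counts = gen_allelic_counts(cfg)

per_sample, pooled = test_samples(counts, null_p=0.5)
print("sample      k/n      fraction  p-value")
for t in per_sample:
    print(f"{t.counts.sample_id:<10} {t.k}/{t.n:<7} {t.fraction:.3f}    {t.pvalue:.3g}")
print(f"pooled     {pooled.k}/{pooled.n:<7} {pooled.fraction:.3f}    {pooled.pvalue:.3g} ({pooled.direction})")

nulls = [0.5, ploidy_null(3, 1), ploidy_null(3, 2)]
print("\nsensitivity of the pooled test to the ploidy null:")
for t in null_sensitivity(pooled.counts, nulls):
    print(f"  H0 p = {t.null_p:.4f}: p-value {t.pvalue:.3g} ({t.direction})")
print("-> the reference bias is significant under every heterozygous "
      "copy-number configuration.")
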