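"""Allele-aware motif scoring of a disruptive SNV.

Builds a synthetic 11-bp motif whose informative position drops from
frequency 0.8 (reference allele) to 0.1 (alternate allele), plants its
consensus in a 51-bp window around the variant, and scores both alleles.
"""

from allelescan import (
    SimulationConfig,
    binding_report,
    gen_motif_and_variant,
    pfm_to_pwm,
    score_distribution,
)

cfg = SimulationConfig(seed=1, consensus_freq=0.8, disrupted_freq=0.1)
pfm, pair, expected_fold = gen_motif_and_variant(cfg)
pwm = pfm_to_pwm(pfm, pseudocount=0.0)
dist = score_distribution(pwm)
rep = binding_report(pwm, pair, dist=dist)

print(f"variant {pair.variant.id}: {pair.variant.ref}>{pair.variant.alt}")
print(f"best ref hit: score {rep.ref_hit.score:.3f} at offset {rep.ref_hit.offset} ({rep.ref_hit.strand})")
print(f"best alt hit: score {rep.alt_hit.score:.3f} at offset {rep.alt_hit.offset} ({rep.alt_hit.strand})")
fc = 1.0 / rep.efficiency_fold_change  # ref over alt
print(f"binding-efficiency fold change (ref/alt): {fc:.1f}  (planted: 2**{expected_fold:.1f} = {2**expected_fold:.1f})")
print(f"motif p-values: ref {rep.ref_hit.pvalue:.3g}, alt {rep.alt_hit.pvalue:.3g}; "
      f"p-value fold change {rep.pvalue_fold_change:.2f} favoring {rep.pvalue_favored_allele}")
print("-> the alternate allele weakens the predicted binding site by the "
      "planted factor; both statistics favor the reference allele.")
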