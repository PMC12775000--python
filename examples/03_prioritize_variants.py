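"""Reducing an LD block to candidates in accessible chromatin.

Generates a 17-variant high-LD block spanning ~14 kb with peaks covering
exactly 2 variants, filters by r2 to the lead SNP, and intersects with
the peaks (BED half-open convention: closed start, exclusive end).
"""

from allelescan import SimulationConfig, gen_variant_block
from allelescan.variant_prioritization import prioritize

cfg = SimulationConfig(seed=1)
variants, peaks, truth = gen_variant_block(cfg)

annotated = prioritize(variants, peaks, r2_min=0.8)
candidates = [v for v in annotated if v.in_peak]

print(f"LD block: {len(annotated)} variants, r2 to lead >= 0.8")
print(f"accessible-chromatin peaks: {len(peaks)}")
print(f"candidates in peaks: {len(candidates)}")
for v in candidates:
    print(f"  {v.id} at {v.chrom}:{v.pos} (r2 = {v.r2_to_lead:.3f})")
print(f"planted truth: {truth}")
print("-> prioritization recovers exactly the planted in-peak variants, "
      "shrinking the candidate set from 17 to 2.")
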