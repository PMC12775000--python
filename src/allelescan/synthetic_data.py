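"""Synthetic study generator with known ground truth.

Emulates the data shape of a regulatory fine-mapping study: a motif with
one strongly constrained position, a biallelic SNV whose alternate allele
destroys that position, an LD block of 17 high-r2 variants over ~14 kb
with accessible-chromatin peaks covering exactly 2 of them, and allelic
read counts for 7 heterozygous donors drawn from a binomial at a
configurable true reference-allele fraction.  Every generator is a pure
function of (config, seed): the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from allelescan.io_formats import (
    write_bed,
    write_counts,
    write_fasta,
    write_pfm,
    write_variants,
)
from allelescan.motif_analysis import DEFAULT_FLANK, VariantWindowPair
from allelescan.types import (
    AllelicCounts,
    GenomicInterval,
    PositionFrequencyMatrix,
    ValidationError,
    VariantRecord,
)

BASES = "ACGT"

#: chromosome names used by the generated fixture: the motif-bearing
#: contig holds the candidate SNV window, the block contig the LD block
MOTIF_CHROM = "chrS"
BLOCK_CHROM = "chrB"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated setting: an 11-bp GATA-like motif, a
    17-variant LD block spanning ~14 kb with 2 variants in peaks, and 7
    heterozygous donors.  ``consensus_freq``/``disrupted_freq`` set the
    motif frequency of the reference and alternate allele at the
    informative position, so the planted log2 binding-efficiency fold
    change is log2(consensus_freq / disrupted_freq).  Donor depths are
    negative-binomial with ``depth_mean``/``depth_dispersion``;
    ``true_ref_fraction`` is the simulated allele fraction and
    ``ploidy``/``ref_copies`` define the null used downstream.
    """

    seed: int = 0
    motif_length: int = 11
    informative_position: int = 5
    consensus_freq: float = 0.8
    disrupted_freq: float = 0.1
    flank: int = DEFAULT_FLANK
    n_variants_in_block: int = 17
    n_in_peak: int = 2
    block_span: int = 14000
    n_donors: int = 7
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0
    true_ref_fraction: float = 0.95
    ploidy: int = 2
    ref_copies: int = 1
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        # disrupted == consensus is allowed as a no-effect control
        if not 0.0 < self.disrupted_freq <= self.consensus_freq <= 1.0:
            raise ValidationError(
                "need 0 < disrupted_freq <= consensus_freq <= 1"
            )
        if self.consensus_freq + self.disrupted_freq >= 1.0 and self.motif_length > 0:
            # remaining bases would get non-positive frequency
            raise ValidationError("consensus_freq + disrupted_freq must be < 1")
        if not 0 <= self.informative_position < self.motif_length:
            raise ValidationError("informative_position outside motif")
        if self.motif_length > 2 * self.flank + 1:
            raise ValidationError("motif does not fit in the window")
        if self.n_in_peak > self.n_variants_in_block:
            raise ValidationError("n_in_peak > n_variants_in_block")
        if not 0.0 < self.true_ref_fraction < 1.0:
            raise ValidationError("true_ref_fraction must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) <= 0:
            raise ValidationError("background must be positive and sum to 1")

    @property
    def expected_log2_fold(self) -> float:
        """Planted log2 efficiency fold change (ref over alt) when both
        alleles' best placements coincide."""
        return math.log2(self.consensus_freq / self.disrupted_freq)

    @property
    def null_p(self) -> float:
        return self.ref_copies / self.ploidy


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so call order never matters
    return np.random.default_rng([int(config.seed), stream])


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(probs)))


def gen_motif_and_variant(
    config: SimulationConfig,
) -> tuple[PositionFrequencyMatrix, VariantWindowPair, float]:
    """Motif with one disruptable position plus the allele window pair.

    The PFM gives each position a random consensus base at
    ``consensus_freq`` (remainder spread evenly); at the informative
    position the alternate allele receives ``disrupted_freq`` instead.
    The motif consensus is planted in a random background window so the
    variant base sits exactly at the informative position, and the
    returned expected log2 fold equals log2(consensus/disrupted).
    """
    rng = _rng(config, 1)
    L = config.motif_length
    c, d = config.consensus_freq, config.disrupted_freq
    ip = config.informative_position

    consensus_idx = rng.integers(0, 4, size=L)
    counts = np.full((4, L), 0.0)
    for i in range(L):
        rest = (1.0 - c) / 3.0
        counts[:, i] = rest
        counts[consensus_idx[i], i] = c
    ref_base = BASES[consensus_idx[ip]]
    alt_choices = [b for b in range(4) if b != consensus_idx[ip]]
    alt_idx = int(rng.choice(alt_choices))
    alt_base = BASES[alt_idx]
    others = [b for b in range(4) if b not in (consensus_idx[ip], alt_idx)]
    counts[:, ip] = 0.0
    counts[consensus_idx[ip], ip] = c
    counts[alt_idx, ip] = d
    for b in others:
        counts[b, ip] = (1.0 - c - d) / 2.0
    pfm = PositionFrequencyMatrix(
        motif_id="SYN_MOTIF", counts=counts, is_frequency=True
    )

    flank = config.flank
    window = list(_random_seq(rng, 2 * flank + 1, config.background))
    consensus_seq = "".join(BASES[i] for i in consensus_idx)
    plant_offset = flank - ip  # variant base lands at window center
    if plant_offset < 0 or plant_offset + L > 2 * flank + 1:
        raise ValidationError("motif does not fit in window at the variant")
    window[plant_offset : plant_offset + L] = list(consensus_seq)
    ref_window = "".join(window)
    alt_window = ref_window[:flank] + alt_base + ref_window[flank + 1 :]

    variant = VariantRecord(
        chrom=MOTIF_CHROM,
        pos=flank + 1,
        id="rs_synthetic",
        ref=ref_base,
        alt=alt_base,
        r2_to_lead=1.0,
    )
    pair = VariantWindowPair(
        variant=variant, ref_window=ref_window, alt_window=alt_window, flank=flank
    )
    return pfm, pair, config.expected_log2_fold


def gen_variant_block(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], list[GenomicInterval], list[str]]:
    """LD block of variants with peaks covering exactly ``n_in_peak``.

    Variants are spread over ``block_span`` on a jittered lattice (so
    peaks around chosen variants never touch their neighbours), each with
    r2 to the lead drawn in [0.9, 1].  Returns (variants, peaks,
    ground-truth in-peak ids).
    """
    rng = _rng(config, 2)
    n = config.n_variants_in_block
    span = config.block_span
    slot = span / n
    if slot < 210:  # need room for a ~100 bp peak between neighbours
        raise ValidationError(
            f"block_span {span} too small for {n} distinct variants with peaks"
        )
    start = 1_000_001  # 1-based start of the block
    positions = []
    for i in range(n):
        center = start + (i + 0.5) * slot
        jitter = rng.uniform(-slot / 5, slot / 5)
        positions.append(int(round(center + jitter)))
    variants = []
    for i, pos in enumerate(positions):
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        r2 = 1.0 if i == 0 else float(rng.uniform(0.9, 0.999))
        variants.append(
            VariantRecord(
                chrom=BLOCK_CHROM, pos=pos, id=f"rs_blk{i:02d}",
                ref=str(ref), alt=str(alt), r2_to_lead=r2,
            )
        )
    chosen = sorted(rng.choice(n, size=config.n_in_peak, replace=False).tolist())
    peaks = []
    for i in chosen:
        p = positions[i]
        lo = int(rng.integers(20, 60))
        hi = int(rng.integers(20, 60))
        peaks.append(
            GenomicInterval(BLOCK_CHROM, p - 1 - lo, p + hi, name=f"peak_{i:02d}")
        )
    # decoy peak upstream of the block, covering no variant
    peaks.append(GenomicInterval(BLOCK_CHROM, start - 1001, start - 801, name="decoy"))
    truth_ids = [variants[i].id for i in chosen]
    return variants, peaks, truth_ids


def gen_allelic_counts(
    config: SimulationConfig,
) -> list[AllelicCounts]:
    """Per-donor allelic read counts at the candidate het site.

    Donor depth ~ negative binomial(mean, dispersion), redrawn if zero;
    reference count ~ Binomial(depth, true_ref_fraction).
    """
    rng = _rng(config, 3)
    m, r = config.depth_mean, config.depth_dispersion
    p_nb = r / (r + m)
    counts = []
    for i in range(config.n_donors):
        depth = 0
        while depth == 0:
            depth = int(rng.negative_binomial(r, p_nb))
        ref = int(rng.binomial(depth, config.true_ref_fraction))
        counts.append(
            AllelicCounts(sample_id=f"donor{i + 1}", ref_count=ref, alt_count=depth - ref)
        )
    return counts


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete fixture directory and return the ground truth.

    Files: motif.pfm, windows.fa (contig holding the reference window),
    variants.vcf (block variants + candidate SNV), variants.tsv (with r2),
    peaks.bed, counts.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfm, pair, expected_fold = gen_motif_and_variant(config)
    variants, peaks, truth_ids = gen_variant_block(config)
    counts = gen_allelic_counts(config)

    write_pfm(pfm, outdir / "motif.pfm")
    write_fasta({MOTIF_CHROM: pair.ref_window}, outdir / "windows.fa")
    all_variants = variants + [pair.variant]
    write_variants(all_variants, outdir / "variants.vcf")
    with (outdir / "variants.tsv").open("w") as fh:
        fh.write("chrom\tpos\tid\tref\talt\tr2_to_lead\n")
        for v in all_variants:
            r2 = "" if v.r2_to_lead is None else format(v.r2_to_lead, ".6g")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t{r2}\n")
    write_bed(peaks, outdir / "peaks.bed")
    write_counts(counts, outdir / "counts.tsv")
    truth = {
        "config": asdict(config),
        "in_peak_ids": truth_ids,
        "expected_log2_fold": expected_fold,
        "true_ref_fraction": config.true_ref_fraction,
        "null_p": config.null_p,
        "motif_variant_id": pair.variant.id,
    }
    with (outdir / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
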