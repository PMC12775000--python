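"""Allele-aware position weight matrix scoring.

The model: a motif of length L is a matrix of per-position nucleotide
frequencies M.  A sequence s of length L scores

    Score(s) = sum_i log2( M[s_i, i] / b[s_i] )

against a background composition b (uniform 0.25 by default), and its
predicted binding efficiency is 2**Score, so efficiency ratios between
alleles are 2**(score difference).  For a SNV we extract the two
2f+1-base windows centered on the variant (f = 25 giving 51 bp), score
every motif placement that covers the variant on both strands, and keep
the best placement per allele independently.  An exact null distribution
of scores over background sequences — computed by per-position
convolution on a fixed log2 grid — converts best scores into motif
p-values P(Score >= s), whose ratio between alleles is the p-value
fold-change statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from allelescan.types import (
    BASE_INDEX,
    PositionFrequencyMatrix,
    ValidationError,
    VariantRecord,
    reverse_complement,
)

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_FLANK = 25
DEFAULT_GRID_STEP = 0.001


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds form of a motif against a background composition."""

    motif_id: str
    log_odds: np.ndarray  # 4 x L, log2(M / b)
    background: np.ndarray  # length 4, sums to 1
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "background", bg)
        if lo.ndim != 2 or lo.shape[0] != 4:
            raise ValidationError(f"log_odds must be 4 x L, got {lo.shape}")
        if not np.all(np.isfinite(lo)):
            bad = np.argwhere(~np.isfinite(lo))[0]
            raise ValidationError(
                f"PWM {self.motif_id!r}: non-finite log-odds at base "
                f"{'ACGT'[bad[0]]}, position {bad[1]} (zero frequency needs a "
                "pseudocount > 0)"
            )
        if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValidationError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())


@dataclass(frozen=True)
class VariantWindowPair:
    """The two allele-specific sequence windows centered on a SNV."""

    variant: VariantRecord
    ref_window: str
    alt_window: str
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        f = self.flank
        for name, w in (("ref", self.ref_window), ("alt", self.alt_window)):
            if len(w) != 2 * f + 1:
                raise ValidationError(
                    f"{name}_window length {len(w)} != 2*flank+1 = {2 * f + 1}"
                )
            if any(b not in BASE_INDEX for b in w):
                raise ValidationError(f"{name}_window contains non-ACGT bases")
        if self.ref_window[f] != self.variant.ref:
            raise ValidationError(
                f"ref_window center {self.ref_window[f]!r} != variant.ref "
                f"{self.variant.ref!r}"
            )
        if self.alt_window[f] != self.variant.alt:
            raise ValidationError(
                f"alt_window center {self.alt_window[f]!r} != variant.alt "
                f"{self.variant.alt!r}"
            )
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_window, self.alt_window)) if a != b]
        if diffs != [f]:
            raise ValidationError(
                f"windows differ at positions {diffs}, expected exactly [{f}]"
            )

    @property
    def variant_offset(self) -> int:
        return self.flank

    def swapped(self) -> "VariantWindowPair":
        """The same pair with ref and alt alleles exchanged."""
        v = self.variant
        swapped_variant = VariantRecord(
            chrom=v.chrom, pos=v.pos, id=v.id, ref=v.alt, alt=v.ref,
            r2_to_lead=v.r2_to_lead, in_peak=v.in_peak,
        )
        return VariantWindowPair(
            variant=swapped_variant,
            ref_window=self.alt_window,
            alt_window=self.ref_window,
            flank=self.flank,
        )


@dataclass(frozen=True)
class MotifHit:
    """One scored placement of a motif within a window.

    ``offset`` is the 0-based start of the placement in forward-strand
    window coordinates; for a '-' strand hit the scored sequence is the
    reverse complement of the window slice.
    """

    strand: str
    offset: int
    score: float
    efficiency: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not math.isclose(self.efficiency, 2.0 ** self.score, rel_tol=1e-9):
            raise ValidationError("efficiency != 2**score")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"pvalue {self.pvalue} outside (0, 1]")


@dataclass(frozen=True)
class AlleleBindingReport:
    """Best hits for both alleles and the two fold-change statistics."""

    motif_id: str
    variant_id: str
    ref_hit: MotifHit
    alt_hit: MotifHit
    efficiency_fold_change: float  # alt efficiency / ref efficiency
    favored_allele: str  # allele ('ref'/'alt') with the higher best score
    pvalue_fold_change: float | None = None  # max(p)/min(p) >= 1
    pvalue_favored_allele: str | None = None  # allele with the smaller p-value

    @property
    def log2_fold_change(self) -> float:
        return self.alt_hit.score - self.ref_hit.score


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact PWM score distribution over background sequences on an ε grid.

    ``support`` holds ascending grid scores (integer multiples of
    ``grid_step``); ``mass`` the corresponding probabilities summing to 1.
    Scores are floored to the grid, which makes derived p-values
    conservative (never smaller than the exact tail probability).
    ``motif_length`` records how many floored terms a score sums, bounding
    the total rounding error at motif_length * grid_step.
    """

    grid_step: float
    support: np.ndarray
    mass: np.ndarray
    motif_length: int = 1

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be positive")
        s = np.asarray(self.support, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "mass", m)
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mass sums to {m.sum()!r}, expected 1")


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> PositionWeightMatrix:
    """Convert counts/frequencies to a log2-odds matrix.

    Per column: frequency = (count + pseudocount) / (total + 4*pseudocount),
    then log_odds = log2(frequency / background).  A zero count with a zero
    pseudocount is rejected because it would yield -inf.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    counts = pfm.counts
    if pseudocount == 0 and np.any(counts == 0):
        bad = np.argwhere(counts == 0)[0]
        raise ValidationError(
            f"PFM {pfm.motif_id!r}: zero count for base {'ACGT'[bad[0]]} at "
            f"position {bad[1]} requires pseudocount > 0"
        )
    col_tot = counts.sum(axis=0)
    freq = (counts + pseudocount) / (col_tot + 4.0 * pseudocount)
    bg = np.asarray(background, dtype=float)
    log_odds = np.log2(freq / bg[:, None])
    return PositionWeightMatrix(
        motif_id=pfm.motif_id,
        log_odds=log_odds,
        background=bg,
        pseudocount=pseudocount,
    )


def score_kmer(pwm: PositionWeightMatrix, kmer: str) -> float:
    """Sum of per-position log2-odds for one exact-length k-mer."""
    if len(kmer) != pwm.length:
        raise ValidationError(
            f"kmer length {len(kmer)} != motif length {pwm.length}"
        )
    total = 0.0
    for i, base in enumerate(kmer.upper()):
        j = BASE_INDEX.get(base)
        if j is None:
            raise ValidationError(f"ambiguous/invalid base {base!r} at position {i}")
        total += pwm.log_odds[j, i]
    return float(total)


def extract_windows(
    sequence_source, variant: VariantRecord, flank: int = DEFAULT_FLANK
) -> VariantWindowPair:
    """Cut the 2*flank+1 window around a SNV and build both allele windows.

    ``sequence_source`` is any mapping from chromosome name to a sliceable
    sequence (a dict of strings, a pyfaidx.Fasta, ...).  The genomic base
    at the variant position must match variant.ref.
    """
    contig = sequence_source[variant.chrom]
    contig_len = len(contig)
    start = variant.pos - 1 - flank  # 0-based window start
    end = variant.pos + flank  # 0-based exclusive
    if start < 0 or end > contig_len:
        raise ValidationError(
            f"{variant.id}: window [{start + 1}, {end}] exceeds contig "
            f"{variant.chrom} (length {contig_len})"
        )
    window = str(contig[start:end]).upper()
    found = window[flank]
    if found != variant.ref:
        raise ValidationError(
            f"{variant.id}: reference mismatch at {variant.chrom}:{variant.pos} — "
            f"found {found!r}, expected {variant.ref!r}"
        )
    alt_window = window[:flank] + variant.alt + window[flank + 1 :]
    return VariantWindowPair(
        variant=variant, ref_window=window, alt_window=alt_window, flank=flank
    )


def scan_allele(
    pwm: PositionWeightMatrix, window: str, variant_offset: int
) -> MotifHit:
    """Best-scoring placement covering the variant, over both strands.

    All length-L placements whose span includes ``variant_offset`` are
    scored on the forward window and on its reverse complement (reported
    back in forward coordinates).  Ties prefer the + strand, then the
    smaller offset.
    """
    window = window.upper()
    L = pwm.length
    W = len(window)
    if L > W:
        raise ValidationError(f"window length {W} shorter than motif length {L}")
    if not 0 <= variant_offset < W:
        raise ValidationError(f"variant_offset {variant_offset} outside window")
    lo = max(0, variant_offset - L + 1)
    hi = min(W - L, variant_offset)
    if lo > hi:
        raise ValidationError("no placement covers the variant")
    best: MotifHit | None = None
    for offset in range(lo, hi + 1):
        piece = window[offset : offset + L]
        for strand, seq in (("+", piece), ("-", reverse_complement(piece))):
            s = score_kmer(pwm, seq)
            if best is None or s > best.score:
                best = MotifHit(strand=strand, offset=offset, score=s, efficiency=2.0 ** s)
    assert best is not None
    return best


def count_placements(pwm_length: int, window_length: int, variant_offset: int) -> int:
    """Number of strand-placements scan_allele evaluates (both strands)."""
    lo = max(0, variant_offset - pwm_length + 1)
    hi = min(window_length - pwm_length, variant_offset)
    return 2 * max(0, hi - lo + 1)


def binding_report(
    pwm: PositionWeightMatrix,
    pair: VariantWindowPair,
    dist: ScoreDistribution | None = None,
) -> AlleleBindingReport:
    """Scan both allele windows independently and compare best hits.

    efficiency_fold_change = 2**(alt best score - ref best score); with a
    score distribution, best hits gain motif p-values and the report gains
    the p-value fold-change max(p)/min(p).
    """
    ref_hit = scan_allele(pwm, pair.ref_window, pair.variant_offset)
    alt_hit = scan_allele(pwm, pair.alt_window, pair.variant_offset)
    if dist is not None:
        ref_hit = MotifHit(
            strand=ref_hit.strand, offset=ref_hit.offset, score=ref_hit.score,
            efficiency=ref_hit.efficiency, pvalue=motif_pvalue(dist, ref_hit.score),
        )
        alt_hit = MotifHit(
            strand=alt_hit.strand, offset=alt_hit.offset, score=alt_hit.score,
            efficiency=alt_hit.efficiency, pvalue=motif_pvalue(dist, alt_hit.score),
        )
    fold = 2.0 ** (alt_hit.score - ref_hit.score)
    favored = "alt" if alt_hit.score > ref_hit.score else "ref"
    if alt_hit.score == ref_hit.score:
        favored = "none"
    pv_fold = pv_favored = None
    if dist is not None:
        p_ref, p_alt = ref_hit.pvalue, alt_hit.pvalue
        pv_fold = max(p_ref, p_alt) / min(p_ref, p_alt)
        pv_favored = "none" if p_ref == p_alt else ("ref" if p_ref < p_alt else "alt")
    return AlleleBindingReport(
        motif_id=pwm.motif_id,
        variant_id=pair.variant.id,
        ref_hit=ref_hit,
        alt_hit=alt_hit,
        efficiency_fold_change=fold,
        favored_allele=favored,
        pvalue_fold_change=pv_fold,
        pvalue_favored_allele=pv_favored,
    )


def score_distribution(
    pwm: PositionWeightMatrix, grid_step: float = DEFAULT_GRID_STEP
) -> ScoreDistribution:
    """Exact score distribution over i.i.d. background sequences.

    Per-position log-odds are floored to integer multiples of
    ``grid_step`` and convolved position by position (dynamic programming
    over the score grid), giving the distribution of Score(s) for random
    s ~ background.  Cost is O(L * span/ε), independent of 4**L.
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    idx = np.floor(pwm.log_odds / grid_step).astype(np.int64)  # 4 x L
    bg = pwm.background
    # mass over integer grid offsets, tracked with an explicit origin
    mass = np.array([1.0])
    origin = 0  # grid index of mass[0]
    for i in range(pwm.length):
        col = idx[:, i]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(mass) + (hi - lo), dtype=float)
        for b in range(4):
            shift = int(col[b]) - lo
            new[shift : shift + len(mass)] += bg[b] * mass
        mass = new
        origin += lo
    keep = mass > 0
    support_idx = origin + np.nonzero(keep)[0]
    mass = mass[keep]
    mass = mass / mass.sum()  # renormalize away accumulated rounding
    return ScoreDistribution(
        grid_step=grid_step,
        support=support_idx * grid_step,
        mass=mass,
        motif_length=pwm.length,
    )


def motif_pvalue(dist: ScoreDistribution, score: float) -> float:
    """P(Score >= score) under the background distribution.

    The query score is floored to the grid and discounted by the worst-case
    per-position rounding, (motif_length - 1) * grid_step, before the tail
    sum.  A distribution grid score undershoots its exact score by at most
    motif_length * grid_step, so the reported p-value is never smaller than
    the exact tail probability; the minimum-support score maps to 1.
    """
    eps = dist.grid_step
    threshold = math.floor(score / eps) * eps - (dist.motif_length - 1) * eps
    # half-step fuzz guard for float comparison on the grid
    tail = dist.mass[dist.support >= threshold - 0.5 * eps].sum()
    return float(min(max(tail, dist.mass.min()), 1.0))


def pvalue_fold_change(
    pwm: PositionWeightMatrix,
    pair: VariantWindowPair,
    grid_step: float = DEFAULT_GRID_STEP,
) -> tuple[float, str]:
    """Ratio of best-hit motif p-values between alleles (>= 1) and direction.

    Returns ``(max(p_ref, p_alt) / min(p_ref, p_alt), favored)`` where
    ``favored`` names the allele with the smaller p-value ('none' on a tie).
    """
    dist = score_distribution(pwm, grid_step=grid_step)
    report = binding_report(pwm, pair, dist=dist)
    return report.pvalue_fold_change, report.pvalue_favored_allele
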