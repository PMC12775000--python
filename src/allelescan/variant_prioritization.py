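"""LD-block reduction and coverage binning.

An associated locus is represented as a block of variants in high LD
with the lead SNP; functional fine-mapping keeps those inside accessible
chromatin (ATAC/DNase peaks).  Coverage tracks binned at a fixed window
size (500 bp for locus overviews, 50 bp for zoomed views) provide the
quantitative context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from allelescan.types import GenomicInterval, ValidationError, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageTrack:
    """Mean depth per fixed-size bin tiling a region."""

    chrom: str
    bin_size: int
    bins: list  # list of (GenomicInterval, float)
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        if self.normalization not in ("raw", "cpm"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        prev_end = None
        for iv, depth in self.bins:
            if depth < 0:
                raise ValidationError("negative bin depth")
            if prev_end is not None and iv.start != prev_end:
                raise ValidationError("bins must tile the region without gaps")
            prev_end = iv.end


def intersect_variants_peaks(
    variants: list[VariantRecord], peaks: list[GenomicInterval]
) -> list[VariantRecord]:
    """Annotate each variant with whether it falls inside any peak.

    A 1-based variant position p is inside a half-open peak [s, e) iff
    s <= p-1 < e (BED convention: the closed start is inside, the
    exclusive end is outside).  Input order is preserved; overlapping
    peaks count once.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    out = []
    n_in = 0
    for v in variants:
        hit = any(pk.contains_position(v.pos) for pk in by_chrom.get(v.chrom, []))
        n_in += hit
        out.append(replace(v, in_peak=hit))
    logger.info("peak intersection: %d/%d variants in peaks", n_in, len(variants))
    return out


def filter_by_ld(
    variants: list[VariantRecord], r2_min: float
) -> list[VariantRecord]:
    """Keep variants with r2 to the lead SNP >= r2_min (stable order)."""
    missing = [v.id for v in variants if v.r2_to_lead is None]
    if missing:
        raise ValidationError(
            f"r2_to_lead missing for: {', '.join(missing)}"
        )
    return [v for v in variants if v.r2_to_lead >= r2_min]


def bin_coverage(
    reads: list[GenomicInterval],
    region: GenomicInterval,
    bin_size: int,
    normalization: str = "raw",
    library_size: int | None = None,
) -> CoverageTrack:
    """Mean per-base depth in fixed-size bins over a region.

    Depth at a base is the number of read intervals overlapping it; each
    bin reports the mean over its bases.  cpm mode scales by
    1e6 / library_size (counts-per-million normalization).
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    scale = 1.0
    if normalization == "cpm":
        if not library_size:
            raise ValidationError("cpm normalization requires library_size > 0")
        scale = 1e6 / library_size
    elif normalization != "raw":
        raise ValidationError(f"unknown normalization {normalization!r}")

    span = len(region)
    depth = np.zeros(span, dtype=float)
    for rd in reads:
        if rd.chrom != region.chrom:
            continue
        lo = max(rd.start, region.start) - region.start
        hi = min(rd.end, region.end) - region.start
        if lo < hi:
            depth[lo:hi] += 1.0
    bins = []
    for s in range(region.start, region.end, bin_size):
        e = min(s + bin_size, region.end)
        mean = float(depth[s - region.start : e - region.start].mean()) * scale
        bins.append((GenomicInterval(region.chrom, s, e), mean))
    return CoverageTrack(
        chrom=region.chrom, bin_size=bin_size, bins=bins, normalization=normalization
    )


def prioritize(
    variants: list[VariantRecord],
    peaks: list[GenomicInterval],
    r2_min: float,
) -> list[VariantRecord]:
    """Full prioritization: LD filter then peak intersection; returns the
    annotated high-LD variants (candidates are those with in_peak set)."""
    block = filter_by_ld(variants, r2_min)
    return intersect_variants_peaks(block, peaks)
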