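"""Core domain types shared across the pipeline.

Coordinate conventions follow the two standards natively: variants are
1-based (VCF), intervals are 0-based half-open (BED).  Conversions happen
only inside intersection code, never in the containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """A binding motif as per-position nucleotide counts or frequencies.

    ``counts`` is a 4 x length array in A, C, G, T row order.  When
    ``is_frequency`` is set each column sums to 1 and the matrix is treated
    as frequencies rather than observation counts.
    """

    motif_id: str
    counts: np.ndarray
    is_frequency: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValidationError(
                f"PFM {self.motif_id!r}: counts must be 4 x L with L >= 1, "
                f"got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValidationError(f"PFM {self.motif_id!r}: negative entries")
        col_tot = counts.sum(axis=0)
        if np.any(col_tot <= 0):
            bad = int(np.argmax(col_tot <= 0))
            raise ValidationError(
                f"PFM {self.motif_id!r}: column {bad} has no positive entry"
            )
        if self.is_frequency and np.any(np.abs(col_tot - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(col_tot - 1.0) > 1e-6))
            raise ValidationError(
                f"PFM {self.motif_id!r}: frequency column {bad} sums to "
                f"{col_tot[bad]:.6g}, expected 1"
            )

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV, 1-based, optionally annotated with LD and peak overlap."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    r2_to_lead: float | None = None
    in_peak: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.id}: pos must be >= 1, got {self.pos}")
        for name, base in (("ref", self.ref), ("alt", self.alt)):
            if base not in BASE_INDEX:
                raise ValidationError(
                    f"{self.id}: {name} allele {base!r} is not a single A/C/G/T base"
                )
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: ref and alt alleles are identical")
        if self.r2_to_lead is not None and not 0.0 <= self.r2_to_lead <= 1.0:
            raise ValidationError(
                f"{self.id}: r2_to_lead {self.r2_to_lead} outside [0, 1]"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.start >= self.end:
            raise ValidationError(
                f"interval [{self.start}, {self.end}) on {self.chrom} is empty "
                "or inverted"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, pos_1based: int) -> bool:
        """True if a 1-based position falls inside this half-open interval."""
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class AllelicCounts:
    """Reference/alternate read counts for one sample at one het site."""

    sample_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        for name, c in (("ref_count", self.ref_count), ("alt_count", self.alt_count)):
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise ValidationError(
                    f"{self.sample_id}: {name}={c!r} is not an integer"
                )
            if c < 0:
                raise ValidationError(f"{self.sample_id}: {name}={c} is negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ref_fraction(self) -> float:
        if self.depth == 0:
            raise ValidationError(f"{self.sample_id}: zero depth has no fraction")
        return self.ref_count / self.depth
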