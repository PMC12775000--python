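"""Readers and writers for the plain-text formats the pipeline touches.

Supported inputs: JASPAR-style PFM text (bracketed or whitespace rows,
plus the transposed HOCOMOCO PCM/PWM layout), minimal 5-column VCF, TSV
variant tables with an optional r2 column, BED3/BED6, bedGraph, and TSV
allelic count tables.  All downstream modules consume only the domain
types produced here.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from allelescan.types import (
    AllelicCounts,
    GenomicInterval,
    ParseError,
    PositionFrequencyMatrix,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_ROW_RE = re.compile(r"^\s*([ACGTacgt])\s*[:|]?\s*\[?\s*([-0-9.eE+\s]+?)\s*\]?\s*$")


def _parse_numbers(text: str, where: str) -> list[float]:
    try:
        return [float(tok) for tok in text.split()]
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric value ({exc})") from None


def read_pfm(path: str | Path, motif_id: str | None = None) -> PositionFrequencyMatrix:
    """Parse a motif matrix from JASPAR or HOCOMOCO style text.

    Accepts four labelled A/C/G/T rows of length L (bracketed JASPAR or
    plain whitespace), or the transposed HOCOMOCO layout of L unlabelled
    rows with 4 columns.  A ``>`` header supplies the motif id unless
    overridden.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty motif file")

    header_id = None
    if lines[0].lstrip().startswith(">"):
        header_id = lines[0].lstrip()[1:].split()[0] if lines[0].lstrip()[1:].split() else None
        lines = lines[1:]
    if not lines:
        raise ParseError(f"{path}: header but no matrix rows")

    rows: dict[str, list[float]] = {}
    labelled = True
    for ln in lines:
        m = _ROW_RE.match(ln)
        if m is None:
            labelled = False
            break
        base = m.group(1).upper()
        if base in rows:
            raise ParseError(f"{path}: duplicate row for base {base}")
        rows[base] = _parse_numbers(m.group(2), f"{path} row {base}")

    if labelled and set(rows) == set("ACGT"):
        lengths = {b: len(v) for b, v in rows.items()}
        if len(set(lengths.values())) != 1:
            ref_len = len(rows["A"])
            bad = next(b for b in "ACGT" if lengths[b] != ref_len)
            raise ParseError(
                f"{path}: ragged matrix — row {bad} has {lengths[bad]} columns, "
                f"row A has {ref_len}"
            )
        counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    else:
        # HOCOMOCO PCM/PWM layout: one row per motif position, columns A C G T.
        matrix = []
        for i, ln in enumerate(lines):
            vals = _parse_numbers(ln, f"{path} line {i + 1}")
            if len(vals) != 4:
                raise ParseError(
                    f"{path}: line {i + 1} has {len(vals)} columns; expected "
                    "labelled A/C/G/T rows or 4-column position rows"
                )
            matrix.append(vals)
        counts = np.array(matrix, dtype=float).T

    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative matrix entries")
    col_tot = counts.sum(axis=0)
    is_frequency = bool(np.all(np.abs(col_tot - 1.0) <= 1e-6))
    mid = motif_id or header_id or path.stem
    return PositionFrequencyMatrix(motif_id=mid, counts=counts, is_frequency=is_frequency)


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Write a PFM in JASPAR bracketed text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{pfm.motif_id}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(format(v, ".10g") for v in pfm.counts[i])
            fh.write(f"{base} [ {vals} ]\n")


def read_variants(
    path: str | Path, dialect: str = "vcf"
) -> tuple[list[VariantRecord], int]:
    """Read biallelic SNVs from a minimal VCF or TSV table.

    Returns ``(records, n_skipped)``; multi-allelic and indel rows are
    skipped with a logged warning so that rows_in = records_out + skipped.
    """
    if dialect not in ("vcf", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[VariantRecord] = []
    skipped = 0
    lines = path.read_text().splitlines()

    if dialect == "tsv":
        header = None
        for ln in lines:
            if not ln.strip():
                continue
            if header is None:
                header = ln.rstrip().split("\t")
                lowered = [h.strip().lower() for h in header]
                needed = ["chrom", "pos", "id", "ref", "alt"]
                for col in needed:
                    if col not in lowered:
                        raise ParseError(f"{path}: missing mandatory column {col!r}")
                idx = {c: lowered.index(c) for c in needed}
                r2_idx = lowered.index("r2_to_lead") if "r2_to_lead" in lowered else None
                continue
            fields = ln.rstrip().split("\t")
            rec, ok = _variant_from_fields(
                path,
                fields[idx["chrom"]],
                fields[idx["pos"]],
                fields[idx["id"]],
                fields[idx["ref"]],
                fields[idx["alt"]],
                float(fields[r2_idx]) if r2_idx is not None and r2_idx < len(fields) and fields[r2_idx] not in ("", ".") else None,
            )
            if ok:
                records.append(rec)
            else:
                skipped += 1
        if header is None:
            raise ParseError(f"{path}: empty TSV (no header)")
        return records, skipped

    for ln in lines:
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.rstrip().split("\t")
        if len(fields) < 5:
            raise ParseError(
                f"{path}: VCF row has {len(fields)} columns, need CHROM POS ID REF ALT"
            )
        rec, ok = _variant_from_fields(
            path, fields[0], fields[1], fields[2], fields[3], fields[4], None
        )
        if ok:
            records.append(rec)
        else:
            skipped += 1
    return records, skipped


def _variant_from_fields(
    path: Path,
    chrom: str,
    pos: str,
    vid: str,
    ref: str,
    alt: str,
    r2: float | None,
) -> tuple[VariantRecord | None, bool]:
    try:
        pos_i = int(pos)
    except ValueError:
        raise ParseError(f"{path}: non-integer POS {pos!r} for {vid}") from None
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1 or "," in alt or ref not in "ACGT" or alt not in "ACGT":
        logger.warning("skipping non-SNV row %s (%s>%s)", vid, ref, alt)
        return None, False
    return VariantRecord(chrom=chrom, pos=pos_i, id=vid, ref=ref, alt=alt, r2_to_lead=r2), True


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write variants as a minimal 5-column VCF."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("track", "browser", "#")):
            continue
        fields = ln.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{i}: BED needs at least 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{i}: non-integer coordinates") from None
        if start >= end or start < 0:
            raise ValidationError(
                f"{path}:{i}: invalid interval [{start}, {end})"
            )
        name = fields[3] if len(fields) > 3 else None
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        out.append(GenomicInterval(fields[0], start, end, name=name, score=score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
                if iv.score is not None:
                    cols.append(format(iv.score, ".10g"))
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(
    track: Sequence[tuple[GenomicInterval, float]], path: str | Path
) -> None:
    """Write (interval, value) pairs as bedGraph (chrom start end value)."""
    path = Path(path)
    with path.open("w") as fh:
        for iv, value in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format(value, '.10g')}\n")


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    path = Path(path)
    out: list[tuple[GenomicInterval, float]] = []
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("track", "#")):
            continue
        fields = ln.split()
        if len(fields) != 4:
            raise ParseError(f"{path}:{i}: bedGraph needs 4 columns")
        start, end = int(fields[1]), int(fields[2])
        if start >= end:
            raise ValidationError(f"{path}:{i}: invalid interval [{start}, {end})")
        out.append((GenomicInterval(fields[0], start, end), float(fields[3])))
    return out


def read_counts(path: str | Path) -> list[AllelicCounts]:
    """Read a TSV of per-sample allelic read counts.

    Header must name sample_id, ref_count, alt_count.  Fractional counts
    and duplicate sample ids are validation errors; zero-depth rows are
    accepted but flagged with a warning.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty counts file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in ("sample_id", "ref_count", "alt_count"):
        if col not in header:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    idx = {c: header.index(c) for c in ("sample_id", "ref_count", "alt_count")}
    out: list[AllelicCounts] = []
    seen: set[str] = set()
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        sid = fields[idx["sample_id"]].strip()
        if sid in seen:
            raise ValidationError(f"{path}:{i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        counts = []
        for col in ("ref_count", "alt_count"):
            raw = fields[idx[col]].strip()
            val = float(raw)
            if val != int(val):
                raise ValidationError(
                    f"{path}:{i}: {col}={raw} is not an integer count"
                )
            counts.append(int(val))
        rec = AllelicCounts(sample_id=sid, ref_count=counts[0], alt_count=counts[1])
        if rec.depth == 0:
            logger.warning("%s:%d: sample %s has zero depth", path, i, sid)
        out.append(rec)
    return out


def write_counts(counts: Iterable[AllelicCounts], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tref_count\talt_count\n")
        for c in counts:
            fh.write(f"{c.sample_id}\t{c.ref_count}\t{c.alt_count}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write named sequences as uncompressed FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence dict (small files only)."""
    path = Path(path)
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for ln in path.read_text().splitlines():
        if ln.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = ln[1:].split()[0]
            chunks = []
        elif ln.strip():
            chunks.append(ln.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise ParseError(f"{path}: no FASTA records")
    return seqs


def normalize_chrom(name: str, style: str) -> str:
    """Normalize 'chr1' <-> '1' naming.  style: 'as-is', 'add-chr', 'strip-chr'."""
    if style == "as-is":
        return name
    if style == "add-chr":
        return name if name.startswith("chr") else f"chr{name}"
    if style == "strip-chr":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome naming style {style!r}")
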