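"""End-to-end orchestration: prioritize -> motif scan -> imbalance.

A single YAML config names the inputs and parameters; stages run in
order, each only when its inputs are present, and their evidence is
aggregated into one summary per candidate variant (peak overlap,
binding-efficiency and p-value fold changes, pooled allelic-imbalance
test and its sensitivity across ploidy nulls).  Re-running with the same
config reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from allelescan import io_formats
from allelescan.allelic_imbalance import null_sensitivity, test_samples
from allelescan.motif_analysis import (
    DEFAULT_FLANK,
    DEFAULT_GRID_STEP,
    DEFAULT_PSEUDOCOUNT,
    binding_report,
    extract_windows,
    pfm_to_pwm,
    score_distribution,
)
from allelescan.types import ValidationError
from allelescan.variant_prioritization import filter_by_ld, intersect_variants_peaks

logger = logging.getLogger(__name__)


@dataclass
class EvidenceSummary:
    """Aggregated evidence for one candidate variant; a field is None iff
    the stage that computes it did not run."""

    variant_id: str
    in_peak: bool | None = None
    r2_to_lead: float | None = None
    ref_score: float | None = None
    alt_score: float | None = None
    efficiency_fold_change: float | None = None
    favored_allele: str | None = None
    pvalue_ref: float | None = None
    pvalue_alt: float | None = None
    pvalue_fold_change: float | None = None
    imbalance_pooled_p: float | None = None
    imbalance_pooled_fraction: float | None = None
    imbalance_direction: str | None = None
    imbalance_null_p: float | None = None
    null_sensitivity: list | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_chrom_consistency(chrom_sets: dict[str, set[str]]) -> None:
    """Fail before any stage if inputs mix 'chr1'-style and '1'-style names."""
    styles = {}
    for source, chroms in chrom_sets.items():
        for c in chroms:
            styles.setdefault(c.startswith("chr"), set()).add(source)
    if len(styles) > 1:
        detail = "; ".join(
            f"{'chr-prefixed' if k else 'bare'} in {sorted(v)}" for k, v in styles.items()
        )
        raise ValidationError(
            f"inconsistent chromosome naming across inputs ({detail}); "
            "set params.chrom_style to normalize"
        )


def run_pipeline(config_file: str | Path) -> list[EvidenceSummary]:
    """Run all configured stages and write TSV/JSON reports plus a manifest.

    Config layout::

        inputs:  {variants, variants_dialect, peaks, fasta, pfm, counts}
        params:  {r2_min, flank, pseudocount, grid_step, null_p | (ploidy,
                  ref_copies), method, sensitivity, chrom_style}
        output:  report directory (optional; omit to skip writing)
    """
    config_file = Path(config_file)
    cfg = yaml.safe_load(config_file.read_text()) or {}
    inputs = cfg.get("inputs", {}) or {}
    params = cfg.get("params", {}) or {}
    base = config_file.parent

    def resolve(key: str) -> Path | None:
        v = inputs.get(key)
        if v is None:
            return None
        p = Path(v)
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"input {key!r}: file not found: {p}")
        return p

    paths = {k: resolve(k) for k in ("variants", "peaks", "fasta", "pfm", "counts")}
    if not any(paths.values()):
        raise ValidationError("config names no inputs; nothing to run")

    chrom_style = params.get("chrom_style", "as-is")
    logger.info("pipeline parameters: %s", json.dumps(params, sort_keys=True))

    variants = None
    if paths["variants"]:
        dialect = inputs.get("variants_dialect", "vcf")
        variants, n_skip = io_formats.read_variants(paths["variants"], dialect=dialect)
        if n_skip:
            logger.warning("skipped %d non-SNV rows", n_skip)
        variants = [
            dataclasses.replace(v, chrom=io_formats.normalize_chrom(v.chrom, chrom_style))
            for v in variants
        ]
    peaks = None
    if paths["peaks"]:
        peaks = [
            dataclasses.replace(p, chrom=io_formats.normalize_chrom(p.chrom, chrom_style))
            for p in io_formats.read_bed(paths["peaks"])
        ]
    fasta = None
    if paths["fasta"]:
        fasta = {
            io_formats.normalize_chrom(k, chrom_style): v
            for k, v in io_formats.read_fasta(paths["fasta"]).items()
        }

    chrom_sets = {}
    if variants:
        chrom_sets["variants"] = {v.chrom for v in variants}
    if peaks:
        chrom_sets["peaks"] = {p.chrom for p in peaks}
    if fasta:
        chrom_sets["fasta"] = set(fasta)
    if len(chrom_sets) > 1:
        _check_chrom_consistency(chrom_sets)

    summaries: dict[str, EvidenceSummary] = {}

    def summary_for(vid: str) -> EvidenceSummary:
        return summaries.setdefault(vid, EvidenceSummary(variant_id=vid))

    # --- stage 1: prioritize ------------------------------------------------
    if variants is not None and peaks is not None:
        block = variants
        r2_min = params.get("r2_min")
        if r2_min is not None:
            with_r2 = [v for v in block if v.r2_to_lead is not None]
            if len(with_r2) < len(block):
                logger.warning(
                    "r2_min set but %d variants lack r2; they are excluded "
                    "from the LD filter stage", len(block) - len(with_r2),
                )
            block = filter_by_ld(with_r2, float(r2_min))
        annotated = intersect_variants_peaks(block, peaks)
        for v in annotated:
            s = summary_for(v.id)
            s.in_peak = v.in_peak
            s.r2_to_lead = v.r2_to_lead
        logger.info(
            "prioritize: %d/%d variants in accessible chromatin",
            sum(v.in_peak for v in annotated), len(annotated),
        )

    # --- stage 2: motif scan ------------------------------------------------
    if paths["pfm"] and fasta is not None and variants is not None:
        pfm = io_formats.read_pfm(paths["pfm"])
        pwm = pfm_to_pwm(
            pfm,
            pseudocount=float(params.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        )
        grid_step = float(params.get("grid_step", DEFAULT_GRID_STEP))
        dist = score_distribution(pwm, grid_step=grid_step)
        flank = int(params.get("flank", DEFAULT_FLANK))
        for v in variants:
            if v.chrom not in fasta:
                continue
            try:
                pair = extract_windows(fasta, v, flank=flank)
            except ValidationError as exc:
                logger.warning("scan skipped for %s: %s", v.id, exc)
                continue
            rep = binding_report(pwm, pair, dist=dist)
            s = summary_for(v.id)
            s.ref_score = rep.ref_hit.score
            s.alt_score = rep.alt_hit.score
            s.efficiency_fold_change = rep.efficiency_fold_change
            s.favored_allele = rep.favored_allele
            s.pvalue_ref = rep.ref_hit.pvalue
            s.pvalue_alt = rep.alt_hit.pvalue
            s.pvalue_fold_change = rep.pvalue_fold_change

    # --- stage 3: allelic imbalance ----------------------------------------
    if paths["counts"]:
        counts = io_formats.read_counts(paths["counts"])
        if "null_p" in params:
            null_p = float(params["null_p"])
        elif "ploidy" in params:
            from allelescan.allelic_imbalance import ploidy_null

            null_p = ploidy_null(
                int(params["ploidy"]), int(params.get("ref_copies", 1))
            )
        else:
            null_p = 0.5
        method = params.get("method", "minlike")
        per_sample, pooled = test_samples(counts, null_p, method=method)
        sens_nulls = params.get("sensitivity") or []
        sens = null_sensitivity(pooled.counts, [float(p) for p in sens_nulls], method)
        targets = list(summaries.values()) or [summary_for(inputs.get("counts_variant_id", "candidate"))]
        for s in targets:
            s.imbalance_pooled_p = pooled.pvalue
            s.imbalance_pooled_fraction = pooled.fraction
            s.imbalance_direction = pooled.direction
            s.imbalance_null_p = null_p
            s.null_sensitivity = [
                {"null_p": t.null_p, "pvalue": t.pvalue, "direction": t.direction}
                for t in sens
            ]

    out = list(summaries.values())
    outdir = cfg.get("output")
    if outdir:
        outdir = Path(outdir)
        outdir = outdir if outdir.is_absolute() else base / outdir
        write_reports(out, outdir)
        manifest = {
            "config": str(config_file),
            "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                       for k, p in paths.items() if p},
            "params": params,
        }
        with (outdir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out


_TSV_COLUMNS = [
    "variant_id", "in_peak", "r2_to_lead", "ref_score", "alt_score",
    "efficiency_fold_change", "favored_allele", "pvalue_ref", "pvalue_alt",
    "pvalue_fold_change", "imbalance_pooled_p", "imbalance_pooled_fraction",
    "imbalance_direction", "imbalance_null_p",
]


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return format(v, ".8g")
    return str(v)


def write_reports(summaries: list[EvidenceSummary], outdir: str | Path) -> None:
    """Write report.tsv and report.json (deterministic byte layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "report.tsv").open("w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in summaries:
            d = s.to_dict()
            fh.write("\t".join(_fmt(d[c]) for c in _TSV_COLUMNS) + "\n")
    with (outdir / "report.json").open("w") as fh:
        json.dump([s.to_dict() for s in summaries], fh, indent=2, sort_keys=True)
        fh.write("\n")
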