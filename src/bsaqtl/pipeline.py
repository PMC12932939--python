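"""End-to-end orchestration of the BSA-seq candidate-gene pipeline.

Stage order: read + filter variants → SNP indices and ΔSNP index →
sliding-window scan with a permutation threshold → region calling →
variant-effect annotation → DEG intersection and prioritization. All
artifacts are plain text (TSV/BED/JSON) with fixed float formatting, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import candidates_to_table, genes_in_regions, join_deg, prioritize
from .config import RunConfig
from .genome_scan import (
    call_regions,
    permutation_null,
    regions_to_bed,
    threshold_from_null,
    window_scan,
)
from .snp_index import apply_marker_filters, compute_delta, compute_snp_index, to_dataframe
from .variants import (
    GeneModelIndex,
    classify_variant_effect,
    contig_lengths,
    read_allele_depths,
    read_gene_models,
    select_homozygous_polymorphic,
)

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts into ``out_dir``.

    Returns a summary dict (threshold, regions, candidate genes, output
    paths). The manifest records the package version, the full config, and
    input checksums.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    try:
        records, read_report = read_allele_depths(config.vcf)
        lengths = contig_lengths(config.vcf)
        markers, sel_report = select_homozygous_polymorphic(
            records,
            min_parent_depth=config.min_parent_depth,
            max_minor_fraction=config.max_minor_fraction,
            track=config.track,
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("variants", e) from e

    try:
        idx_records = [compute_snp_index(r) for r in markers]
        kept, filter_report = apply_marker_filters(
            idx_records, min_index=config.min_index, min_depth=config.min_depth
        )
        kept = compute_delta(kept)
        snp_df = to_dataframe(kept)
        snp_df.to_csv(out / "snp_index.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
        (out / "filter_report.json").write_text(
            json.dumps(
                {
                    "read": read_report.__dict__,
                    "parental_selection": sel_report.__dict__,
                    "marker_filters": filter_report.__dict__,
                },
                indent=2,
            )
        )
    except Exception as e:
        raise StageError("snp_index", e) from e

    try:
        windows = window_scan(
            snp_df,
            lengths,
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            min_markers=config.min_markers,
        )
        null = permutation_null(
            snp_df,
            lengths,
            n_iterations=config.n_iterations,
            scheme=config.scheme,
            seed=config.seed,
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            min_markers=config.min_markers,
            bulk_size=config.bulk_size,
            cm_per_mb=config.cm_per_mb,
            error_rate=config.error_rate,
        )
        threshold = threshold_from_null(null, config.percentile)
        regions = call_regions(windows, threshold, snp_df)
        windows.to_csv(out / "windows.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
        pd.DataFrame({"max_abs_mean_delta": null.maxima}).to_csv(
            out / "null_maxima.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        regions_to_bed(regions).to_csv(
            out / "regions.bed", sep="\t", index=False, header=False, float_format=FLOAT_FORMAT
        )
        pd.DataFrame(
            {
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
                "peak_delta": [r.peak_delta for r in regions],
                "n_loci": [r.n_loci for r in regions],
                "member_windows": [r.member_windows for r in regions],
            }
        ).to_csv(out / "regions.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
        summary["threshold"] = threshold
        summary["n_regions"] = len(regions)
        summary["n_loci_in_regions"] = int(sum(r.n_loci for r in regions))
    except Exception as e:
        raise StageError("genome_scan", e) from e

    try:
        models = read_gene_models(config.gff3, config.cds_fasta)
        index = GeneModelIndex(models)
        effects = [(r, classify_variant_effect(r, index)) for r in markers]
        effect_counts: dict[str, int] = {}
        for _, eff in effects:
            effect_counts[eff.category] = effect_counts.get(eff.category, 0) + 1
        summary["effect_counts"] = effect_counts
    except Exception as e:
        raise StageError("annotate", e) from e

    try:
        deg = pd.read_csv(config.deg, sep="\t")
        hits = genes_in_regions(regions, models, effects)
        cands, missing = join_deg(
            hits, deg, fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold
        )
        ranked = prioritize(cands, min_abs_fold_change=config.min_abs_fold_change)
        table = candidates_to_table(ranked)
        table.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
        (out / "genes_without_deg.json").write_text(json.dumps(sorted(missing)))
        summary["n_region_genes"] = len(hits)
        summary["n_candidates"] = len(ranked)
        summary["candidates"] = table["gene_id"].tolist()
        summary["priority_genes"] = table.loc[table["priority_flag"], "gene_id"].tolist()
    except Exception as e:
        raise StageError("candidates", e) from e

    inputs = {
        name: _sha256(path)
        for name, path in (
            ("vcf", config.vcf),
            ("gff3", config.gff3),
            ("cds_fasta", config.cds_fasta),
            ("deg", config.deg),
        )
        if path
    }
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "input_sha256": inputs,
        "summary": {k: v for k, v in summary.items() if k != "candidates"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["out_dir"] = str(out)
    return summary
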