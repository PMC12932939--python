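"""Candidate-gene aggregation: regions × coding variants × differential expression.

A gene becomes a candidate when it lies in a candidate region, carries at
least one protein-altering variant (nonsynonymous, stop-gain or stop-loss)
inside that region, and its differential-expression record passes the
fold-change and FDR thresholds. Candidates are ranked by linear fold
change, with a priority flag for strong expression contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_scan import CandidateRegion
from .variants import AlleleDepthRecord, GeneModel, VariantEffect

DAMAGING = ("nonsynonymous", "stop_gain", "stop_loss")


@dataclass
class GeneHit:
    """Per-gene damaging-variant counts within a candidate region."""

    gene_id: str
    region: CandidateRegion
    nonsyn_count: int = 0
    stop_gain_count: int = 0
    stop_loss_count: int = 0


@dataclass
class CandidateGene:
    gene_id: str
    region: CandidateRegion
    nonsyn_count: int
    stop_gain_count: int
    stop_loss_count: int
    log2fc: float
    fdr: float
    fold_change: float  # signed linear scale: sign(log2fc) * 2**|log2fc|
    priority_flag: bool = False


def genes_in_regions(
    regions: list[CandidateRegion],
    gene_models: list[GeneModel],
    effects: list[tuple[AlleleDepthRecord, VariantEffect]],
    categories: tuple[str, ...] = DAMAGING,
) -> dict[str, GeneHit]:
    """Genes overlapping a region with ≥1 damaging variant inside it.

    A gene overlaps a region when any CDS base does (inclusive interval
    semantics). ``categories`` selects which effect classes count as
    damaging.
    """
    by_id = {m.gene_id: m for m in gene_models}
    hits: dict[str, GeneHit] = {}
    for record, effect in effects:
        if effect.category not in categories or effect.gene_id is None:
            continue
        model = by_id.get(effect.gene_id)
        if model is None:
            continue
        for region in regions:
            if region.chrom != record.chrom:
                continue
            span = model.span
            if not (span[0] <= region.end and span[1] >= region.start):
                continue
            if not (region.start <= record.pos <= region.end):
                continue
            hit = hits.setdefault(effect.gene_id, GeneHit(effect.gene_id, region))
            if effect.category == "nonsynonymous":
                hit.nonsyn_count += 1
            elif effect.category == "stop_gain":
                hit.stop_gain_count += 1
            else:
                hit.stop_loss_count += 1
            break
    return hits


def join_deg(
    gene_hits: dict[str, GeneHit],
    deg_table: pd.DataFrame,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> tuple[list[CandidateGene], list[str]]:
    """Intersect region genes with the DEG table.

    Keeps genes with |log2FC| > ``fc_threshold`` and FDR < ``fdr_threshold``.
    Returns (candidates, genes absent from the DEG table) — absentees are
    reported, never silently dropped. Duplicate gene ids in the DEG table
    make the join ambiguous and raise.
    """
    if deg_table["gene_id"].duplicated().any():
        dups = deg_table.loc[deg_table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id rows in DEG table: {sorted(set(dups))}")
    deg = deg_table.set_index("gene_id")
    candidates: list[CandidateGene] = []
    missing: list[str] = []
    for gene_id in sorted(gene_hits):
        hit = gene_hits[gene_id]
        if gene_id not in deg.index:
            missing.append(gene_id)
            continue
        row = deg.loc[gene_id]
        log2fc = float(row["log2fc"])
        fdr = float(row["fdr"])
        if abs(log2fc) <= fc_threshold or fdr >= fdr_threshold:
            continue
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                region=hit.region,
                nonsyn_count=hit.nonsyn_count,
                stop_gain_count=hit.stop_gain_count,
                stop_loss_count=hit.stop_loss_count,
                log2fc=log2fc,
                fdr=fdr,
                fold_change=float(np.sign(log2fc) * 2 ** abs(log2fc)),
            )
        )
    return candidates, missing


def prioritize(
    candidates: list[CandidateGene], min_abs_fold_change: float = 4.0
) -> list[CandidateGene]:
    """Rank by |fold change| descending (ties by gene id); flag strong contrasts."""
    ranked = sorted(candidates, key=lambda c: (-abs(c.fold_change), c.gene_id))
    for c in ranked:
        c.priority_flag = abs(c.fold_change) > min_abs_fold_change
    return ranked


def candidates_to_table(candidates: list[CandidateGene]) -> pd.DataFrame:
    """Candidate list table (fold change on the signed linear scale)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "fold_change": [c.fold_change for c in candidates],
            "log2fc": [c.log2fc for c in candidates],
            "fdr": [c.fdr for c in candidates],
            "nonsyn_count": [c.nonsyn_count for c in candidates],
            "stop_gain_count": [c.stop_gain_count for c in candidates],
            "stop_loss_count": [c.stop_loss_count for c in candidates],
            "region": [f"{c.region.chrom}:{c.region.start}-{c.region.end}" for c in candidates],
            "priority_flag": [c.priority_flag for c in candidates],
        }
    )
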