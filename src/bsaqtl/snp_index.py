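"""Per-bulk SNP indices, marker filters, and the ΔSNP index.

The SNP index of a pool at a locus is the fraction of its reads carrying
the tracked parental allele (parent B by default). ΔSNP index is the high
bulk's index minus the low bulk's; it drifts away from 0 near loci linked
to the selected trait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .variants import AlleleDepthRecord

FLAG_LOW_INDEX_BOTH = "low_index_both"
FLAG_LOW_DEPTH = "low_depth"
FLAG_MISSING_INDEX = "missing_index"


@dataclass
class SnpIndexRecord:
    chrom: str
    pos: int
    index_high: float | None
    index_low: float | None
    depth_high: int
    depth_low: int
    delta: float | None = None
    filter_flags: set[str] = field(default_factory=set)


def compute_snp_index(record: AlleleDepthRecord) -> SnpIndexRecord:
    """SNP index of each bulk: tracked-allele reads / total reads.

    The record must carry the ``b_allele`` annotation set by the parental
    homozygous-polymorphic filter. A pool with zero depth gets a missing
    index and the ``missing_index`` flag; missing is a distinct state,
    never coerced to 0.
    """
    if record.b_allele not in ("ref", "alt"):
        raise ValueError(
            f"record at {record.chrom}:{record.pos} lacks the tracked-allele "
            "annotation; run select_homozygous_polymorphic first"
        )
    sel = 0 if record.b_allele == "ref" else 1
    out = SnpIndexRecord(
        chrom=record.chrom,
        pos=record.pos,
        index_high=None,
        index_low=None,
        depth_high=sum(record.ad_bulk_high),
        depth_low=sum(record.ad_bulk_low),
    )
    if out.depth_high > 0:
        out.index_high = record.ad_bulk_high[sel] / out.depth_high
    if out.depth_low > 0:
        out.index_low = record.ad_bulk_low[sel] / out.depth_low
    if out.index_high is None or out.index_low is None:
        out.filter_flags.add(FLAG_MISSING_INDEX)
    return out


@dataclass
class FilterReport:
    """Counts of loci removed by each marker-filter clause.

    A locus failing several clauses is counted once, with precedence
    missing_index > low_depth > low_index_both (documented convention).
    """

    n_in: int = 0
    n_kept: int = 0
    n_missing_index: int = 0
    n_low_depth: int = 0
    n_low_index_both: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def apply_marker_filters(
    records: list[SnpIndexRecord],
    min_index: float = 0.3,
    min_depth: int = 7,
) -> tuple[list[SnpIndexRecord], FilterReport]:
    """Drop unreliable loci before the genome scan.

    A locus is removed when (a) its SNP index is below ``min_index`` in
    BOTH pools, or (b) its depth is below ``min_depth`` in EITHER pool, or
    (c) its index is missing in ANY pool. Clause (a) is joint over pools
    (the usual sequencing-error rationale); clause (b) is per pool, since a
    single under-sequenced pool already makes the locus unreliable.
    """
    kept: list[SnpIndexRecord] = []
    report = FilterReport(n_in=len(records))
    for rec in records:
        if rec.index_high is None or rec.index_low is None:
            rec.filter_flags.add(FLAG_MISSING_INDEX)
            report.n_missing_index += 1
            continue
        if rec.depth_high < min_depth or rec.depth_low < min_depth:
            rec.filter_flags.add(FLAG_LOW_DEPTH)
            report.n_low_depth += 1
            continue
        if rec.index_high < min_index and rec.index_low < min_index:
            rec.filter_flags.add(FLAG_LOW_INDEX_BOTH)
            report.n_low_index_both += 1
            continue
        kept.append(rec)
        report.n_kept += 1
    return kept, report


def compute_delta(records: list[SnpIndexRecord]) -> list[SnpIndexRecord]:
    """Populate delta = index_high − index_low where both indices exist."""
    for rec in records:
        if rec.index_high is not None and rec.index_low is not None:
            rec.delta = rec.index_high - rec.index_low
    return records


def to_dataframe(records: list[SnpIndexRecord]) -> pd.DataFrame:
    """Tabular view, coordinate-sorted; missing indices become NaN."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "index_high": [r.index_high for r in records],
            "index_low": [r.index_low for r in records],
            "depth_high": [r.depth_high for r in records],
            "depth_low": [r.depth_low for r in records],
            "delta": [r.delta for r in records],
            "filter_flags": [",".join(sorted(r.filter_flags)) for r in records],
        }
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
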