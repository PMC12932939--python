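"""Allele-depth VCF reading, parental marker selection, and coding-effect annotation.

The pipeline genotypes four samples — two inbred parents and two phenotypic
bulks — at biallelic SNPs. This module turns a VCF with per-sample allele
depths (FORMAT/AD) into :class:`AlleleDepthRecord` streams, keeps only loci
where the parents are homozygous for opposite alleles (the informative
markers of a biparental cross), and classifies the coding consequence of a
substitution against gene models carried as GFF3 + spliced-CDS FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio import SeqIO
import gffutils
from cyvcf2 import VCF

SAMPLE_ROLES = ("parent_a", "parent_b", "bulk_high", "bulk_low")

DEFAULT_SAMPLE_MAP = {
    "parent_a": "ParentA",
    "parent_b": "ParentB",
    "bulk_high": "BulkH",
    "bulk_low": "BulkL",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

EFFECT_CATEGORIES = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss", "noncoding")


@dataclass(frozen=True)
class AlleleDepthRecord:
    """One biallelic SNP with (ref, alt) read counts for the four samples.

    ``b_allele`` is set by :func:`select_homozygous_polymorphic`: ``"ref"``
    or ``"alt"``, naming which VCF allele the tracked parent (parent B by
    default) carries.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ad_parent_a: tuple[int, int]
    ad_parent_b: tuple[int, int]
    ad_bulk_high: tuple[int, int]
    ad_bulk_low: tuple[int, int]
    b_allele: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for ad in (self.ad_parent_a, self.ad_parent_b, self.ad_bulk_high, self.ad_bulk_low):
            if min(ad) < 0:
                raise ValueError(f"negative allele depth at {self.chrom}:{self.pos}")


@dataclass
class ReadReport:
    """Counts of VCF rows excluded while reading."""

    n_kept: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_missing_ad: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def read_allele_depths(
    vcf_path: str,
    sample_map: dict[str, str] | None = None,
    allow_unsorted: bool = False,
) -> tuple[list[AlleleDepthRecord], ReadReport]:
    """Read biallelic SNP rows with AD depths for the four named samples.

    Indel and multiallelic rows are skipped and counted in the report.
    Out-of-order rows within a chromosome raise unless ``allow_unsorted``
    is set, in which case the records are re-sorted.
    """
    sample_map = dict(DEFAULT_SAMPLE_MAP if sample_map is None else sample_map)
    vcf = VCF(vcf_path)
    missing = [s for s in sample_map.values() if s not in vcf.samples]
    if missing:
        raise ValueError(f"sample(s) {missing} not present in {vcf_path}")
    cols = {role: vcf.samples.index(sample_map[role]) for role in SAMPLE_ROLES}

    records: list[AlleleDepthRecord] = []
    report = ReadReport()
    last: dict[str, int] = {}
    unsorted = False
    for v in vcf:
        if len(v.ALT) != 1:
            report.n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            report.n_indel += 1
            continue
        ad = v.format("AD")
        if ad is None:
            report.n_missing_ad += 1
            continue
        depths = {}
        ok = True
        for role, col in cols.items():
            r, a = int(ad[col][0]), int(ad[col][1])
            if r < 0 or a < 0:  # cyvcf2 encodes missing as negative
                ok = False
                break
            depths[role] = (r, a)
        if not ok:
            report.n_missing_ad += 1
            continue
        if v.CHROM in last and v.POS < last[v.CHROM]:
            unsorted = True
        last[v.CHROM] = v.POS
        records.append(
            AlleleDepthRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                ad_parent_a=depths["parent_a"],
                ad_parent_b=depths["parent_b"],
                ad_bulk_high=depths["bulk_high"],
                ad_bulk_low=depths["bulk_low"],
            )
        )
        report.n_kept += 1
    if unsorted:
        if not allow_unsorted:
            raise ValueError(f"{vcf_path} is not coordinate-sorted (pass allow_unsorted to re-sort)")
        records.sort(key=lambda r: (r.chrom, r.pos))
    return records, report


def contig_lengths(vcf_path: str) -> dict[str, int]:
    """Chromosome lengths from the VCF ##contig header lines."""
    vcf = VCF(vcf_path)
    return dict(zip(vcf.seqnames, vcf.seqlens))


@dataclass
class SelectionReport:
    n_kept: int = 0
    n_low_parent_depth: int = 0
    n_het_parent: int = 0
    n_monomorphic: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def select_homozygous_polymorphic(
    records: list[AlleleDepthRecord],
    min_parent_depth: int = 7,
    max_minor_fraction: float = 0.1,
    track: str = "parent_b",
) -> tuple[list[AlleleDepthRecord], SelectionReport]:
    """Keep loci where both parents are homozygous for opposite alleles.

    Each kept record is annotated with which allele the tracked parent
    carries (``b_allele``); downstream SNP indices are fractions of reads
    carrying that allele. ``track`` may be flipped to ``"parent_a"``.
    """
    if track not in ("parent_a", "parent_b"):
        raise ValueError(f"track must be 'parent_a' or 'parent_b', got {track!r}")
    kept: list[AlleleDepthRecord] = []
    report = SelectionReport()
    for rec in records:
        calls = {}
        drop = None
        for role, ad in (("parent_a", rec.ad_parent_a), ("parent_b", rec.ad_parent_b)):
            total = ad[0] + ad[1]
            if total < min_parent_depth:
                drop = "depth"
                break
            if min(ad) / total > max_minor_fraction:
                drop = "het"
                break
            calls[role] = "ref" if ad[0] >= ad[1] else "alt"
        if drop == "depth":
            report.n_low_parent_depth += 1
            continue
        if drop == "het":
            report.n_het_parent += 1
            continue
        if calls["parent_a"] == calls["parent_b"]:
            report.n_monomorphic += 1
            continue
        kept.append(replace(rec, b_allele=calls[track]))
        report.n_kept += 1
    return kept, report


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments plus the spliced CDS.

    ``cds_segments`` are 1-based inclusive genomic intervals ordered 5'→3'
    in transcript orientation (descending genomic coordinates on the minus
    strand). ``cds_seq`` is the spliced coding sequence in transcript
    orientation. A model whose CDS length is not a multiple of three is
    flagged incomplete and excluded from effect calls.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_seq: str
    incomplete: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_segments:
            raise ValueError(f"{self.gene_id}: no CDS segments")
        for start, end in self.cds_segments:
            if start > end or start < 1:
                raise ValueError(f"{self.gene_id}: bad CDS segment ({start}, {end})")
        genomic_order = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if list(self.cds_segments) != expected:
            raise ValueError(f"{self.gene_id}: CDS segments not ordered 5'->3'")
        total = sum(e - s + 1 for s, e in self.cds_segments)
        if total != len(self.cds_seq):
            raise ValueError(
                f"{self.gene_id}: CDS segments span {total} bp but sequence has {len(self.cds_seq)}"
            )
        self.cds_seq = self.cds_seq.upper()
        self.incomplete = total % 3 != 0

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.cds_segments), max(e for _, e in self.cds_segments))

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based offset into the spliced CDS, or None outside the CDS."""
        offset = 0
        for start, end in self.cds_segments:
            if start <= pos <= end:
                return offset + (pos - start if self.strand == "+" else end - pos)
            offset += end - start + 1
        return None

    def cds_to_genomic(self, offset: int) -> int:
        remaining = offset
        for start, end in self.cds_segments:
            length = end - start + 1
            if remaining < length:
                return start + remaining if self.strand == "+" else end - remaining
            remaining -= length
        raise IndexError(f"{self.gene_id}: CDS offset {offset} out of range")


@dataclass(frozen=True)
class VariantEffect:
    """Coding consequence of a single-nucleotide substitution."""

    category: str
    gene_id: str | None = None
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None


def read_gene_models(gff_path: str, cds_fasta_path: str) -> list[GeneModel]:
    """Load gene models from GFF3 gene/mRNA/CDS features plus a CDS FASTA.

    The FASTA holds one spliced coding sequence per gene, keyed by gene id
    (the Phytozome-style annotation pair).
    """
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(cds_fasta_path, "fasta")}
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        segments = sorted(
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS")
        )
        if not segments:
            continue
        if gene.strand == "-":
            segments = segments[::-1]
        if gene_id not in seqs:
            raise ValueError(f"gene {gene_id} has no sequence in {cds_fasta_path}")
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_segments=segments,
                cds_seq=seqs[gene_id],
            )
        )
    return models


class GeneModelIndex:
    """Position lookup over gene models, one sorted segment list per chromosome."""

    def __init__(self, models: list[GeneModel]):
        self.models = list(models)
        self._by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for m in self.models:
            for start, end in m.cds_segments:
                self._by_chrom.setdefault(m.chrom, []).append((start, end, m))
        for segs in self._by_chrom.values():
            segs.sort(key=lambda t: t[:2])
        self.n_incomplete_hits = 0

    def find(self, chrom: str, pos: int) -> GeneModel | None:
        for start, end, model in self._by_chrom.get(chrom, ()):
            if start > pos:
                break
            if pos <= end:
                return model
        return None


def classify_variant_effect(
    record: AlleleDepthRecord, index: GeneModelIndex
) -> VariantEffect:
    """Classify a substitution as synonymous / nonsynonymous / stop_gain /
    stop_loss / noncoding by translating the affected codon before and after.

    Strand is honored: on minus-strand genes the genomic alleles are
    complemented into transcript orientation. Positions inside a CDS of an
    incomplete model (length not divisible by 3) are reported noncoding and
    counted on the index.
    """
    model = index.find(record.chrom, record.pos)
    if model is None:
        return VariantEffect(category="noncoding")
    if model.incomplete:
        index.n_incomplete_hits += 1
        return VariantEffect(category="noncoding", gene_id=model.gene_id)
    offset = model.genomic_to_cds(record.pos)
    assert offset is not None
    ref_t = record.ref if model.strand == "+" else record.ref.translate(_COMPLEMENT)
    alt_t = record.alt if model.strand == "+" else record.alt.translate(_COMPLEMENT)
    if model.cds_seq[offset] != ref_t:
        raise ValueError(
            f"{model.gene_id}: reference allele {record.ref} at {record.chrom}:{record.pos} "
            f"does not match CDS base {model.cds_seq[offset]}"
        )
    codon_i = offset // 3
    within = offset % 3
    codon_before = model.cds_seq[3 * codon_i : 3 * codon_i + 3]
    codon_after = codon_before[:within] + alt_t + codon_before[within + 1 :]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    if aa_before == aa_after:
        category = "synonymous"
    elif aa_after == "*":
        category = "stop_gain"
    elif aa_before == "*":
        category = "stop_loss"
    else:
        category = "nonsynonymous"
    return VariantEffect(
        category=category,
        gene_id=model.gene_id,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_before,
        aa_after=aa_after,
    )
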