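"""Synthetic RIL pool-seq study generator.

Emulates the design the analysis assumes: a biparental F8 recombinant
inbred line (RIL) population bred by single-seed descent, a normally
distributed quantitative trait with one major additive QTL, extreme-bulk
selection, and depth-limited pooled sequencing of the bulks and parents.
The default bundle mirrors the study design — 120 lines, F8, nine
chromosomes, 15+15 bulks, mean pool depth 23×, per-read error 0.1% — and
writes every input the pipeline consumes (VCF, GFF3 + CDS FASTA, phenotype
and DEG TSVs, YAML config, truth/manifest JSON).

Meiosis uses the Haldane map function with no crossover interference: a
gamete is a Markov walk along each chromosome that starts on a random
parental haplotype and switches between haplotypes with probability
r = (1 − e^{−2d})/2 per adjacent-marker interval of d Morgans.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .variants import AlleleDepthRecord

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    n_markers: int
    positions: tuple[int, ...] | None = None  # explicit marker positions override n_markers

    def marker_positions(self) -> np.ndarray:
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.int64)
        else:
            # evenly spaced, offset half a spacing from the ends
            step = self.length_bp / self.n_markers
            pos = (step * (np.arange(self.n_markers) + 0.5)).astype(np.int64) + 1
        return pos


@dataclass(frozen=True)
class GeneticMapSpec:
    chromosomes: tuple[ChromosomeSpec, ...]
    map_function: str = "haldane"
    cm_per_mb: float = 3.0

    def __post_init__(self) -> None:
        if self.map_function != "haldane":
            raise ValueError(f"unsupported map function {self.map_function!r}")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        for chrom in self.chromosomes:
            if chrom.length_bp <= 0:
                raise ValueError(f"chromosome {chrom.name}: length must be positive")
            pos = chrom.marker_positions()
            if len(pos) < 1:
                raise ValueError(f"chromosome {chrom.name}: needs at least one marker")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"chromosome {chrom.name}: marker positions must be strictly increasing"
                )
            if pos[0] < 1 or pos[-1] > chrom.length_bp:
                raise ValueError(f"chromosome {chrom.name}: marker positions off chromosome")


@dataclass(frozen=True)
class QTLSpec:
    chromosome: str
    position_bp: int
    additive_effect: float  # trait units per B-haplotype dose (dose in 0/0.5/1)
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class PoolSeqSpec:
    bulk_size: int = 15
    mean_depth: float = 23.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class RILPopulation:
    """Diploid RIL genotypes as two tracked haplotype matrices (0 = A, 1 = B)."""

    line_ids: list[str]
    chrom: np.ndarray  # per-marker chromosome name
    pos: np.ndarray  # per-marker 1-based position
    hap1: np.ndarray  # (n_lines, n_markers) uint8
    hap2: np.ndarray
    generation: int

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def dose(self) -> np.ndarray:
        """B-haplotype dose per line and marker, in {0, 0.5, 1}."""
        return (self.hap1 + self.hap2) / 2.0

    def genotype_codes(self) -> np.ndarray:
        """Three-symbol genotype matrix: AA, AB, BB."""
        s = self.hap1.astype(np.int16) + self.hap2
        return np.array(["AA", "AB", "BB"])[s]

    def ab_fraction(self) -> float:
        return float(np.mean(self.hap1 != self.hap2))

    def marker_index(self, chromosome: str, position_bp: int) -> int:
        """Index of the marker nearest to a chromosomal position."""
        on = np.flatnonzero(self.chrom == chromosome)
        if len(on) == 0:
            raise ValueError(f"no markers on chromosome {chromosome!r}")
        return int(on[np.argmin(np.abs(self.pos[on] - position_bp))])


def _switch_probs(chrom: np.ndarray, pos: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Per-meiosis gamete switch probabilities (Haldane), 0.5 at chromosome starts."""
    d_morgan = np.diff(pos) * cm_per_mb / 1e6 / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    switch = np.concatenate([[0.5], r])
    new_chrom = np.concatenate([[True], chrom[1:] != chrom[:-1]])
    switch[new_chrom] = 0.5
    return switch


def _gamete(hap1: np.ndarray, hap2: np.ndarray, switch: np.ndarray, rng) -> np.ndarray:
    flips = rng.random(hap1.shape) < switch
    use_h2 = np.logical_xor.accumulate(flips, axis=1)
    return np.where(use_h2, hap2, hap1)


def simulate_ril_genotypes(
    map_spec: GeneticMapSpec, n_lines: int, generation: int, seed: int
) -> RILPopulation:
    """Single-seed-descent RIL lines from a heterozygous F1.

    Each line is an independent lineage: every generation one selfed
    offspring (two independent gametes of the same plant) is carried
    forward, so heterozygosity halves each generation and the expected AB
    fraction at generation n is (1/2)^(n−1). Crossovers follow the Haldane
    map function with no interference. Deterministic for a fixed seed.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if generation < 2:
        raise ValueError("generation must be >= 2 (F2 or later)")
    chrom = np.concatenate(
        [np.repeat(c.name, len(c.marker_positions())) for c in map_spec.chromosomes]
    )
    pos = np.concatenate([c.marker_positions() for c in map_spec.chromosomes])
    switch = _switch_probs(chrom, pos, map_spec.cm_per_mb)
    rng = np.random.default_rng(seed)
    m = len(pos)
    hap1 = np.zeros((n_lines, m), dtype=np.uint8)  # F1: one A haplotype,
    hap2 = np.ones((n_lines, m), dtype=np.uint8)  # one B haplotype
    for _ in range(generation - 1):
        g1 = _gamete(hap1, hap2, switch, rng)
        g2 = _gamete(hap1, hap2, switch, rng)
        hap1, hap2 = g1, g2
    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RILPopulation(
        line_ids=line_ids, chrom=chrom, pos=pos, hap1=hap1, hap2=hap2, generation=generation
    )


def assign_phenotypes(
    pop: RILPopulation, qtl: QTLSpec, baseline: float, seed: int
) -> pd.DataFrame:
    """Trait values: baseline + additive_effect × B dose at the QTL + noise.

    The QTL is resolved to the nearest simulated marker on its chromosome;
    dose is the line's B-haplotype fraction there (0, 0.5 or 1). Residual
    noise is Normal(0, residual_sd). Returns a frame (line_id, trait).
    """
    idx = pop.marker_index(qtl.chromosome, qtl.position_bp)
    rng = np.random.default_rng(seed)
    dose = pop.dose[:, idx]
    trait = baseline + qtl.additive_effect * dose + rng.normal(0.0, qtl.residual_sd, pop.n_lines)
    return pd.DataFrame({"line_id": pop.line_ids, "trait": trait})


def sample_pool_depths(
    pop: RILPopulation,
    high_lines: list[str],
    low_lines: list[str],
    spec: PoolSeqSpec,
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
) -> list[AlleleDepthRecord]:
    """Pooled and parental allele depths at every marker.

    Per locus and pool the true B-allele frequency is the mean B dose over
    the pooled lines; total depth is Poisson(mean_depth) and B-supporting
    reads are Binomial(depth, freq adjusted by the per-read error rate).
    Parents are emitted as pure A / pure B samples under the same depth
    model. Markers are written with ref = parent-A allele and alt =
    parent-B allele (bases supplied or defaulted to A/T).
    """
    if not high_lines or not low_lines:
        raise ValueError("both pools must be non-empty")
    if set(high_lines) & set(low_lines):
        raise ValueError("high and low pools must be disjoint")
    index = {lid: i for i, lid in enumerate(pop.line_ids)}
    try:
        hi = [index[l] for l in high_lines]
        lo = [index[l] for l in low_lines]
    except KeyError as e:
        raise ValueError(f"line {e.args[0]!r} not in population") from None
    m = len(pop.pos)
    if ref_alleles is None:
        ref_alleles = np.repeat("A", m)
    if alt_alleles is None:
        alt_alleles = np.repeat("T", m)
    rng = np.random.default_rng(spec.seed)
    freqs = {
        "bulk_high": pop.dose[hi].mean(axis=0),
        "bulk_low": pop.dose[lo].mean(axis=0),
        "parent_a": np.zeros(m),
        "parent_b": np.ones(m),
    }
    counts = {}
    for role in ("parent_a", "parent_b", "bulk_high", "bulk_low"):
        depth = rng.poisson(spec.mean_depth, m)
        p = freqs[role] * (1 - spec.error_rate) + (1 - freqs[role]) * spec.error_rate
        b_reads = rng.binomial(depth, p)
        counts[role] = (depth - b_reads, b_reads)  # (ref, alt) = (A-allele, B-allele)
    records = []
    for j in range(m):
        records.append(
            AlleleDepthRecord(
                chrom=str(pop.chrom[j]),
                pos=int(pop.pos[j]),
                ref=str(ref_alleles[j]),
                alt=str(alt_alleles[j]),
                ad_parent_a=(int(counts["parent_a"][0][j]), int(counts["parent_a"][1][j])),
                ad_parent_b=(int(counts["parent_b"][0][j]), int(counts["parent_b"][1][j])),
                ad_bulk_high=(int(counts["bulk_high"][0][j]), int(counts["bulk_high"][1][j])),
                ad_bulk_low=(int(counts["bulk_low"][0][j]), int(counts["bulk_low"][1][j])),
            )
        )
    return records


def generate_deg_table(
    gene_ids: list[str],
    n_de: int = 6,
    log2fc_range: tuple[float, float] = (2.0, 5.0),
    fdr_alpha: float = 0.05,
    seed: int = 0,
    de_log2fc: dict[str, float] | None = None,
    comparison: str = "LN_tolerant_vs_LN_sensitive",
) -> pd.DataFrame:
    """Emulated differential-expression output (gene_id, log2fc, fdr, comparison).

    The first ``n_de`` genes (or the keys of ``de_log2fc``) are designated
    differentially expressed: |log2FC| in ``log2fc_range`` with random sign
    (or the supplied value) and FDR below ``fdr_alpha``. All other genes
    get |log2FC| < 1 and FDR ≥ ``fdr_alpha``.
    """
    if not gene_ids:
        raise ValueError("gene list must be non-empty")
    if de_log2fc is not None:
        de_genes = list(de_log2fc)
        unknown = set(de_genes) - set(gene_ids)
        if unknown:
            raise ValueError(f"designated DE genes not in gene list: {sorted(unknown)}")
    else:
        if n_de > len(gene_ids):
            raise ValueError("n_de exceeds the number of genes")
        de_genes = list(gene_ids[:n_de])
    rng = np.random.default_rng(seed)
    de_set = set(de_genes)
    rows = []
    for gid in gene_ids:
        if gid in de_set:
            if de_log2fc is not None:
                lfc = de_log2fc[gid]
            else:
                lo_fc, hi_fc = log2fc_range
                lfc = rng.uniform(lo_fc, hi_fc) * rng.choice([-1.0, 1.0])
            fdr = rng.uniform(0.0, fdr_alpha * 0.5)
        else:
            lfc = rng.uniform(0.0, 0.9) * rng.choice([-1.0, 1.0])
            fdr = rng.uniform(fdr_alpha, 1.0)
        rows.append((gid, lfc, fdr, comparison))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr", "comparison"])


# ---------------------------------------------------------------------------
# gene models and planted coding variants


@dataclass
class SyntheticGene:
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_seq: str


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + a stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(rng.choice(["TAA", "TAG", "TGA"]))
    return "".join(codons)


def make_gene(rng, gene_id: str, chrom: str, tss: int, n_codons: int = 120) -> SyntheticGene:
    """Two-exon gene with a random intron; strand drawn at random."""
    strand = str(rng.choice(["+", "-"]))
    seq = _random_cds(rng, n_codons)
    exon1 = 3 * int(rng.integers(10, n_codons - 10))
    intron = int(rng.integers(80, 400))
    length = len(seq)
    seg_a = (tss, tss + exon1 - 1)
    seg_b = (tss + exon1 + intron, tss + exon1 + intron + (length - exon1) - 1)
    segments = [seg_a, seg_b] if strand == "+" else [seg_b, seg_a]
    return SyntheticGene(gene_id, chrom, strand, segments, seq)


def _cds_to_genomic(gene: SyntheticGene, offset: int) -> int:
    remaining = offset
    for start, end in gene.cds_segments:
        length = end - start + 1
        if remaining < length:
            return start + remaining if gene.strand == "+" else end - remaining
        remaining -= length
    raise IndexError(offset)


def plant_coding_snp(rng, gene: SyntheticGene, category: str) -> tuple[int, str, str]:
    """Choose a substitution in the gene's CDS with the requested consequence.

    Returns (genomic position, ref base, alt base) in genomic-strand
    orientation; the reference base equals the gene's CDS base there. The
    consequence is verified by translating the affected codon with the
    standard code.
    """
    n_codons = len(gene.cds_seq) // 3
    for _ in range(10_000):
        if category == "stop_loss":
            ci = n_codons - 1
        elif category == "stop_gain":
            ci = int(rng.integers(1, n_codons - 1))
        else:
            ci = int(rng.integers(1, n_codons - 1))
        within = int(rng.integers(0, 3))
        offset = 3 * ci + within
        codon = gene.cds_seq[3 * ci : 3 * ci + 3]
        ref_t = codon[within]
        alt_t = str(rng.choice([b for b in "ACGT" if b != ref_t]))
        after = codon[:within] + alt_t + codon[within + 1 :]
        aa_before = str(Seq(codon).translate())
        aa_after = str(Seq(after).translate())
        if category == "synonymous" and aa_before != aa_after:
            continue
        if category == "nonsynonymous" and not (
            aa_before != aa_after and aa_before != "*" and aa_after != "*"
        ):
            continue
        if category == "stop_gain" and not (aa_before != "*" and aa_after == "*"):
            continue
        if category == "stop_loss" and not (aa_before == "*" and aa_after != "*"):
            continue
        pos = _cds_to_genomic(gene, offset)
        comp = str.maketrans("ACGT", "TGCA")
        if gene.strand == "+":
            return pos, ref_t, alt_t
        return pos, ref_t.translate(comp), alt_t.translate(comp)
    raise RuntimeError(f"could not plant a {category} substitution in {gene.gene_id}")


# ---------------------------------------------------------------------------
# fixture bundle


#: Fold changes assigned to the six planted candidate genes (signed linear
#: scale, as reported for a tolerant-vs-sensitive genotype contrast).
CANDIDATE_FOLD_CHANGES = (15.01, 30.36, -4.30, 4.10, -3.22, -3.80)


@dataclass
class FixtureSpec:
    """Full parameterization of the synthetic study bundle.

    Defaults mirror the emulated design: 120 F8 lines, nine 40-Mb
    chromosomes at 3 cM/Mb with 250 backbone markers each, one major QTL of
    heritability 0.5 on chromosome 3, 15+15 extreme bulks, 23× pools with
    0.1% per-read error, and six planted candidate genes carrying
    nonsynonymous variants plus DE records.
    """

    n_lines: int = 120
    generation: int = 8
    n_chromosomes: int = 9
    chrom_length_bp: int = 40_000_000
    markers_per_chrom: int = 250
    cm_per_mb: float = 3.0
    qtl_chrom: str = "Chr03"
    qtl_pos: int = 20_000_000
    additive_effect: float = 27.0
    residual_sd: float = 13.5
    baseline: float = 30.0
    bulk_size: int = 15
    mean_depth: float = 23.0
    error_rate: float = 0.001
    genes_per_chrom: int = 12
    n_candidates: int = 6
    candidate_fold_changes: tuple[float, ...] = CANDIDATE_FOLD_CHANGES
    fdr_alpha: float = 0.05
    seed: int = 1

    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class FixtureBundle:
    """Paths and ground truth of a written fixture set."""

    out_dir: Path
    vcf: Path
    gff3: Path
    cds_fasta: Path
    phenotypes: Path
    deg: Path
    config: Path
    truth: dict = field(default_factory=dict)


def _write_vcf(path: Path, records: list[AlleleDepthRecord], lengths: dict[str, int]) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=bsaqtl-simulate"]
    for chrom, length in lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "ParentA\tParentB\tBulkH\tBulkL")
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        ads = "\t".join(
            f"{a[0]},{a[1]}"
            for a in (r.ad_parent_a, r.ad_parent_b, r.ad_bulk_high, r.ad_bulk_low)
        )
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tAD\t{ads}")
    path.write_text("\n".join(lines) + "\n")


def _write_gff3(path: Path, genes: list[SyntheticGene]) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, min(s for s, _ in g.cds_segments))):
        start = min(s for s, _ in g.cds_segments)
        end = max(e for _, e in g.cds_segments)
        lines.append(
            f"{g.chrom}\tbsaqtl\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        lines.append(
            f"{g.chrom}\tbsaqtl\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.1;Parent={g.gene_id}"
        )
        for s, e in sorted(g.cds_segments):
            lines.append(
                f"{g.chrom}\tbsaqtl\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.1.cds;Parent={g.gene_id}.1"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_cds_fasta(path: Path, genes: list[SyntheticGene]) -> None:
    with path.open("w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.cds_seq), 60):
                fh.write(g.cds_seq[i : i + 60] + "\n")


def write_fixture_set(out_dir: str | Path, spec: FixtureSpec | None = None) -> FixtureBundle:
    """Write a complete, self-consistent input bundle for the pipeline.

    The bundle plants ``n_candidates`` genes near the QTL, each carrying a
    nonsynonymous substitution segregating between the parents and a DE
    record passing the default thresholds, plus decoys: an in-region gene
    with only a synonymous variant, an in-region nonsynonymous gene whose
    DE record fails the thresholds, and an out-of-region nonsynonymous gene
    with a strong DE record. A truth record and a seed manifest are
    written alongside.
    """
    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(spec.seed)
    seeds = {
        stage: int(root.integers(0, 2**31 - 1))
        for stage in ("genes", "genotypes", "phenotypes", "pools", "deg")
    }
    lengths = {name: spec.chrom_length_bp for name in spec.chrom_names()}

    # --- gene models ------------------------------------------------------
    # backbone genes spread along every chromosome (kept clear of the QTL
    # neighbourhood), plus a dedicated cluster of candidate/decoy genes
    # within ±2 Mb of the QTL so the called region covers them
    grng = np.random.default_rng(seeds["genes"])
    genes: list[SyntheticGene] = []
    for chrom in spec.chrom_names():
        spacing = spec.chrom_length_bp // (spec.genes_per_chrom + 1)
        for gi in range(spec.genes_per_chrom):
            tss = spacing * (gi + 1) + int(grng.integers(-spacing // 4, spacing // 4))
            if chrom == spec.qtl_chrom and abs(tss - spec.qtl_pos) < 3_000_000:
                continue
            genes.append(make_gene(grng, f"{chrom}.g{gi + 1:03d}", chrom, tss))

    needed = spec.n_candidates + 2  # candidates + two in-region decoys
    offsets = np.linspace(-2_000_000, 2_000_000, needed).astype(int)
    near = [
        make_gene(grng, f"{spec.qtl_chrom}.q{qi + 1:03d}", spec.qtl_chrom,
                  spec.qtl_pos + int(off))
        for qi, off in enumerate(offsets)
    ]
    genes.extend(near)
    candidates = near[: spec.n_candidates]
    syn_decoy, weak_deg_decoy = near[spec.n_candidates : spec.n_candidates + 2]
    far_chrom = spec.chrom_names()[-1]
    far_decoy = [g for g in genes if g.chrom == far_chrom][0]

    planted: list[tuple[SyntheticGene, str]] = [(g, "nonsynonymous") for g in candidates]
    planted.append((candidates[0], "stop_gain"))
    planted.append((candidates[1], "stop_loss"))
    planted.append((syn_decoy, "synonymous"))
    planted.append((weak_deg_decoy, "nonsynonymous"))
    planted.append((far_decoy, "nonsynonymous"))
    coding_snps = []  # (chrom, pos, ref, alt, gene_id, category)
    for gene, category in planted:
        pos, ref, alt = plant_coding_snp(grng, gene, category)
        coding_snps.append((gene.chrom, pos, ref, alt, gene.gene_id, category))

    # --- marker map: backbone + coding SNP positions ----------------------
    cds_intervals = {
        g.chrom: [] for g in genes
    }
    for g in genes:
        for s, e in g.cds_segments:
            cds_intervals[g.chrom].append((s, e))
    chrom_specs = []
    for chrom in spec.chrom_names():
        step = spec.chrom_length_bp / spec.markers_per_chrom
        backbone = (step * (np.arange(spec.markers_per_chrom) + 0.5)).astype(np.int64) + 1
        # keep backbone markers out of coding sequence so every coding variant
        # is deliberately planted
        for s, e in cds_intervals.get(chrom, []):
            inside = (backbone >= s) & (backbone <= e)
            backbone[inside] = e + 1 + np.arange(int(inside.sum()))
        extra = np.array(
            [p for c, p, *_ in coding_snps if c == chrom], dtype=np.int64
        )
        pos = np.unique(np.concatenate([backbone, extra]))
        chrom_specs.append(
            ChromosomeSpec(
                name=chrom,
                length_bp=spec.chrom_length_bp,
                n_markers=len(pos),
                positions=tuple(int(p) for p in pos),
            )
        )
    map_spec = GeneticMapSpec(chromosomes=tuple(chrom_specs), cm_per_mb=spec.cm_per_mb)

    # --- population, phenotypes, bulks ------------------------------------
    pop = simulate_ril_genotypes(map_spec, spec.n_lines, spec.generation, seeds["genotypes"])
    qtl = QTLSpec(
        chromosome=spec.qtl_chrom,
        position_bp=spec.qtl_pos,
        additive_effect=spec.additive_effect,
        residual_sd=spec.residual_sd,
    )
    pheno = assign_phenotypes(pop, qtl, spec.baseline, seeds["phenotypes"])
    ranked = pheno.sort_values(["trait", "line_id"], kind="stable")
    low_lines = ranked["line_id"].head(spec.bulk_size).tolist()
    high_lines = ranked["line_id"].tail(spec.bulk_size).tolist()

    # allele bases: parent A carries ref, parent B alt; coding SNPs use their
    # planted bases, backbone markers draw random distinct bases
    m = len(pop.pos)
    arng = np.random.default_rng(seeds["pools"])
    ref_alleles = arng.choice(_BASES, m)
    shift = arng.integers(1, 4, m)
    alt_alleles = _BASES[(np.searchsorted(_BASES, ref_alleles) + shift) % 4]
    by_locus = {(c, p): (r, a) for c, p, r, a, *_ in coding_snps}
    for j in range(m):
        key = (str(pop.chrom[j]), int(pop.pos[j]))
        if key in by_locus:
            ref_alleles[j], alt_alleles[j] = by_locus[key]
    pool_spec = PoolSeqSpec(
        bulk_size=spec.bulk_size,
        mean_depth=spec.mean_depth,
        error_rate=spec.error_rate,
        seed=seeds["pools"],
    )
    records = sample_pool_depths(
        pop, high_lines, low_lines, pool_spec, ref_alleles, alt_alleles
    )

    # --- DEG table ---------------------------------------------------------
    gene_ids = sorted(g.gene_id for g in genes)
    de_log2fc = {
        g.gene_id: float(np.sign(fc) * np.log2(abs(fc)))
        for g, fc in zip(candidates, spec.candidate_fold_changes)
    }
    de_log2fc[far_decoy.gene_id] = np.log2(12.0)  # strong DE, but outside any region
    deg = generate_deg_table(
        gene_ids,
        fdr_alpha=spec.fdr_alpha,
        seed=seeds["deg"],
        de_log2fc=de_log2fc,
    )
    # weak_deg_decoy keeps its non-DE row (|log2FC| < 1, FDR >= alpha)

    # --- serialize ---------------------------------------------------------
    vcf = out_dir / "variants.vcf"
    gff3 = out_dir / "genes.gff3"
    cds_fasta = out_dir / "genes.cds.fa"
    pheno_path = out_dir / "phenotypes.tsv"
    deg_path = out_dir / "deg.tsv"
    config_path = out_dir / "config.yaml"
    _write_vcf(vcf, records, lengths)
    _write_gff3(gff3, genes)
    _write_cds_fasta(cds_fasta, genes)
    dry_weight = 40.0 + np.random.default_rng(seeds["phenotypes"] + 1).normal(
        0.0, 4.0, len(pheno)
    )
    pheno_out = pd.DataFrame(
        {
            "line_id": pheno["line_id"],
            "dry_weight_g": dry_weight,
            "n_content_g": dry_weight / pheno["trait"],
        }
    )
    pheno_out.to_csv(pheno_path, sep="\t", index=False, float_format="%.6g")
    deg.to_csv(deg_path, sep="\t", index=False, float_format="%.6g")

    from .config import RunConfig  # local import to avoid a cycle

    config = RunConfig(
        vcf=str(vcf),
        gff3=str(gff3),
        cds_fasta=str(cds_fasta),
        deg=str(deg_path),
        phenotypes=str(pheno_path),
        seed=spec.seed,
        bulk_size=spec.bulk_size,
        cm_per_mb=spec.cm_per_mb,
        error_rate=spec.error_rate,
    )
    config.to_yaml(config_path)

    truth = {
        "qtl": {"chrom": spec.qtl_chrom, "pos": spec.qtl_pos},
        "candidate_genes": {
            g.gene_id: fc for g, fc in zip(candidates, spec.candidate_fold_changes)
        },
        "decoys": {
            "synonymous_in_region": syn_decoy.gene_id,
            "nonsyn_weak_deg_in_region": weak_deg_decoy.gene_id,
            "nonsyn_strong_deg_outside": far_decoy.gene_id,
        },
        "coding_snps": [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "gene_id": g, "category": cat}
            for c, p, r, a, g, cat in coding_snps
        ],
        "high_lines": high_lines,
        "low_lines": low_lines,
        "heritability": spec.additive_effect**2
        * 0.25
        / (spec.additive_effect**2 * 0.25 + spec.residual_sd**2),
        "seeds": seeds,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest = {
        "seed": spec.seed,
        "stage_seeds": seeds,
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()},
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in (vcf, gff3, cds_fasta, pheno_path, deg_path, config_path)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return FixtureBundle(
        out_dir=out_dir,
        vcf=vcf,
        gff3=gff3,
        cds_fasta=cds_fasta,
        phenotypes=pheno_path,
        deg=deg_path,
        config=config_path,
        truth=truth,
    )
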