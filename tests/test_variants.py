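"""VCF parsing, parental marker selection, and codon-level effect calls."""

import numpy as np
import pytest
from Bio.Seq import Seq

from bsaqtl.variants import (
    AlleleDepthRecord,
    GeneModel,
    GeneModelIndex,
    classify_variant_effect,
    read_allele_depths,
    select_homozygous_polymorphic,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=c1,length=100000>
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tParentA\tParentB\tBulkH\tBulkL
"""


def write_vcf(tmp_path, rows):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return str(path)


def ad_row(chrom, pos, ref, alt, *ads):
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tAD\t" + "\t".join(ads)


def test_read_parses_depth_pairs_and_skips_non_snps(tmp_path):
    path = write_vcf(
        tmp_path,
        [
            ad_row("c1", 100, "A", "T", "10,0", "0,12", "5,6", "8,3"),
            ad_row("c1", 200, "A", "AT", "9,0", "0,9", "4,4", "4,4"),  # indel
            "c1\t300\t.\tA\tT,G\t.\tPASS\t.\tAD\t9,0,0\t0,9,0\t4,4,0\t4,4,0",  # multiallelic
        ],
    )
    records, report = read_allele_depths(path)
    assert len(records) == 1
    rec = records[0]
    assert (rec.ad_parent_a, rec.ad_parent_b) == ((10, 0), (0, 12))
    assert (rec.ad_bulk_high, rec.ad_bulk_low) == ((5, 6), (8, 3))
    assert report.n_indel == 1 and report.n_multiallelic == 1 and report.n_kept == 1


def test_read_unsorted_errors_unless_resort_requested(tmp_path):
    rows = [
        ad_row("c1", 500, "A", "T", "9,0", "0,9", "4,4", "4,4"),
        ad_row("c1", 100, "C", "G", "9,0", "0,9", "4,4", "4,4"),
    ]
    path = write_vcf(tmp_path, rows)
    with pytest.raises(ValueError, match="sorted"):
        read_allele_depths(path)
    records, _ = read_allele_depths(path, allow_unsorted=True)
    assert [r.pos for r in records] == [100, 500]


def test_read_missing_sample_is_a_hard_error(tmp_path):
    path = write_vcf(tmp_path, [ad_row("c1", 100, "A", "T", "9,0", "0,9", "4,4", "4,4")])
    with pytest.raises(ValueError, match="NoSuch"):
        read_allele_depths(path, sample_map={"parent_a": "NoSuch", "parent_b": "ParentB",
                                             "bulk_high": "BulkH", "bulk_low": "BulkL"})


def make_record(pos=100, ad_a=(12, 0), ad_b=(0, 15), chrom="c1", ref="A", alt="T"):
    return AlleleDepthRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        ad_parent_a=ad_a, ad_parent_b=ad_b, ad_bulk_high=(5, 5), ad_bulk_low=(5, 5),
    )


def test_parental_selection_keeps_opposite_homozygotes_only():
    kept, report = select_homozygous_polymorphic(
        [
            make_record(100, (12, 0), (0, 15)),  # kept, B allele = alt
            make_record(200, (6, 6), (0, 15)),  # heterozygous parent A
            make_record(300, (12, 0), (14, 0)),  # monomorphic
            make_record(400, (3, 0), (0, 15)),  # parent A under-covered
            make_record(500, (0, 12), (15, 0)),  # kept, B allele = ref
        ]
    )
    assert [(r.pos, r.b_allele) for r in kept] == [(100, "alt"), (500, "ref")]
    assert report.n_het_parent == 1
    assert report.n_monomorphic == 1
    assert report.n_low_parent_depth == 1


def test_parental_selection_is_idempotent_and_a_subset():
    records = [make_record(pos=p, ad_a=(12, p % 3), ad_b=(0, 15)) for p in range(1, 40)]
    once, _ = select_homozygous_polymorphic(records)
    twice, _ = select_homozygous_polymorphic(once)
    assert [(r.chrom, r.pos) for r in once] == [(r.chrom, r.pos) for r in twice]
    assert {(r.chrom, r.pos) for r in once} <= {(r.chrom, r.pos) for r in records}


def test_gene_model_validation():
    with pytest.raises(ValueError, match="overlap"):
        GeneModel("g", "c1", "+", [(10, 20), (15, 30)], "A" * 27)
    with pytest.raises(ValueError, match="span"):
        GeneModel("g", "c1", "+", [(10, 20)], "A" * 5)
    incomplete = GeneModel("g", "c1", "+", [(10, 20)], "A" * 11)
    assert incomplete.incomplete

    model = GeneModel("g", "c1", "-", [(40, 48), (10, 18)], "ATGAAACCCGGGTTTTAA")
    for offset in range(18):
        assert model.genomic_to_cds(model.cds_to_genomic(offset)) == offset


def plus_gene(seq, start=1000, chrom="c1"):
    return GeneModel("gp", chrom, "+", [(start, start + len(seq) - 1)], seq)


@pytest.mark.parametrize(
    "codon,within,alt_t,category",
    [
        ("AAA", 2, "G", "synonymous"),  # AAA -> AAG, Lys -> Lys
        ("TGG", 2, "A", "stop_gain"),  # TGG -> TGA, Trp -> stop
        ("CAT", 1, "G", "nonsynonymous"),  # CAT -> CGT, His -> Arg
    ],
)
def test_effect_categories_on_plus_strand(codon, within, alt_t, category):
    seq = "ATG" + codon + "TAA"
    gene = plus_gene(seq)
    pos = 1000 + 3 + within
    rec = make_record(pos=pos, ref=seq[3 + within], alt=alt_t)
    effect = classify_variant_effect(rec, GeneModelIndex([gene]))
    assert effect.category == category
    assert effect.codon_before == codon


def test_minus_strand_his_to_arg_is_nonsynonymous():
    # transcript CAT codon; genomic sequence is its reverse complement
    tx = "ATGCATTAA"
    start = 2000
    gene = GeneModel("gm", "c1", "-", [(start, start + 8)], tx)
    # transcript offset 4 is the A of CAT; genomic pos = end - 4
    pos = (start + 8) - 4
    rec = make_record(pos=pos, ref="T", alt="C")  # A->G on the transcript
    effect = classify_variant_effect(rec, GeneModelIndex([gene]))
    assert effect.category == "nonsynonymous"
    assert (effect.codon_before, effect.codon_after) == ("CAT", "CGT")


def test_stop_loss_and_noncoding_and_incomplete():
    gene = plus_gene("ATGAAATGA")
    idx = GeneModelIndex([gene])
    rec = make_record(pos=1000 + 8, ref="A", alt="C")  # TGA -> TGC
    assert classify_variant_effect(rec, idx).category == "stop_loss"
    assert classify_variant_effect(make_record(pos=5), idx).category == "noncoding"

    broken = GeneModel("gb", "c1", "+", [(5000, 5010)], "ATGAAATGAAA")
    idx2 = GeneModelIndex([broken])
    assert classify_variant_effect(make_record(pos=5003, ref="A", alt="C"), idx2).category == "noncoding"
    assert idx2.n_incomplete_hits == 1


def test_reference_mismatch_is_an_error():
    gene = plus_gene("ATGAAATAA")
    rec = make_record(pos=1003, ref="C", alt="G")  # CDS has A there
    with pytest.raises(ValueError, match="does not match"):
        classify_variant_effect(rec, GeneModelIndex([gene]))


def _random_gene(rng, gene_id, chrom, start, n_codons=40):
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    codons.append("TAA")
    seq = "".join(codons)
    strand = rng.choice(["+", "-"])
    half = 3 * (n_codons // 2)
    gap = int(rng.integers(50, 200))
    seg_a = (start, start + half - 1)
    seg_b = (start + half + gap, start + half + gap + (len(seq) - half) - 1)
    segments = [seg_a, seg_b] if strand == "+" else [seg_b, seg_a]
    return GeneModel(gene_id, chrom, strand, segments, seq)


def test_strand_mirroring_preserves_effect_category():
    """Flipping a gene to the opposite strand (same transcript) gives the
    same category for the corresponding genomic substitution."""
    rng = np.random.default_rng(99)
    comp = str.maketrans("ACGT", "TGCA")
    checked = 0
    for trial in range(60):
        gene = _random_gene(rng, f"g{trial}", "c1", 1000)
        offset = int(rng.integers(0, len(gene.cds_seq)))
        ref_t = gene.cds_seq[offset]
        alt_t = str(rng.choice([b for b in "ACGT" if b != ref_t]))
        span = gene.span
        # mirrored gene: opposite strand, segments reflected around the span
        def reflect(seg):
            return (span[0] + span[1] - seg[1], span[0] + span[1] - seg[0])
        mirrored = GeneModel(
            gene.gene_id + "_m", "c1",
            "-" if gene.strand == "+" else "+",
            [reflect(s) for s in gene.cds_segments],
            gene.cds_seq,
        )
        for g in (gene, mirrored):
            pos = g.cds_to_genomic(offset)
            ref_g = ref_t if g.strand == "+" else ref_t.translate(comp)
            alt_g = alt_t if g.strand == "+" else alt_t.translate(comp)
            rec = make_record(pos=pos, ref=ref_g, alt=alt_g)
            eff = classify_variant_effect(rec, GeneModelIndex([g]))
            if g is gene:
                first = eff.category
            else:
                assert eff.category == first
                checked += 1
    assert checked == 60
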