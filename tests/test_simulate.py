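"""Generator statistics: Mendelian segregation, SSD inbreeding, pool sampling."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl.simulate import (
    ChromosomeSpec,
    FixtureSpec,
    GeneticMapSpec,
    PoolSeqSpec,
    QTLSpec,
    assign_phenotypes,
    generate_deg_table,
    sample_pool_depths,
    simulate_ril_genotypes,
    write_fixture_set,
)


def single_marker_map():
    return GeneticMapSpec(chromosomes=(ChromosomeSpec("c1", 1_000_000, 1),))


def test_f2_single_marker_segregates_one_to_two_to_one():
    pop = simulate_ril_genotypes(single_marker_map(), n_lines=8000, generation=2, seed=7)
    codes = pop.genotype_codes()[:, 0]
    freqs = {g: np.mean(codes == g) for g in ("AA", "AB", "BB")}
    se = 3 * np.sqrt(0.25 * 0.75 / 8000)
    assert abs(freqs["AA"] - 0.25) < se
    assert abs(freqs["BB"] - 0.25) < se
    assert abs(freqs["AB"] - 0.5) < 3 * np.sqrt(0.5 * 0.5 / 8000)


@pytest.mark.parametrize("generation", [2, 4, 6, 8])
def test_heterozygosity_halves_each_selfing_generation(generation):
    # ten unlinked markers to tighten the Monte-Carlo error
    chroms = tuple(ChromosomeSpec(f"c{i}", 1_000_000, 1) for i in range(10))
    pop = simulate_ril_genotypes(
        GeneticMapSpec(chromosomes=chroms), n_lines=5000, generation=generation, seed=11
    )
    expected = 0.5 ** (generation - 1)
    n_draws = 5000 * 10
    se = np.sqrt(expected * (1 - expected) / n_draws)
    assert abs(pop.ab_fraction() - expected) < 3 * se


def brute_force_ssd_two_markers(r, n_lines, generation, rng):
    """Gamete-by-gamete single-seed descent at two linked markers.

    Independent oracle: explicit per-meiosis simulation with scalar draws,
    no shared code with the vectorized simulator.
    """

    def gamete(plant):
        h1, h2 = plant
        first = rng.integers(2)
        g0 = (h1, h2)[first][0]
        if rng.random() < r:
            first = 1 - first
        g1 = (h1, h2)[first][1]
        return (g0, g1)

    recombinant = 0
    for _ in range(n_lines):
        plant = (((0, 0)), ((1, 1)))
        for _ in range(generation - 1):
            plant = (gamete(plant), gamete(plant))
        for hap in plant:
            if hap[0] != hap[1]:
                recombinant += 1
    return recombinant / (2 * n_lines)


def test_f8_recombinant_fraction_matches_gamete_oracle():
    # 1 Mb apart at 3 cM/Mb: d = 0.03 Morgan, Haldane r = (1 - e^-0.06)/2
    map_spec = GeneticMapSpec(
        chromosomes=(ChromosomeSpec("c1", 2_000_000, 2, positions=(500_000, 1_500_000)),)
    )
    r = 0.5 * (1 - np.exp(-2 * 0.03))
    n = 6000
    pop = simulate_ril_genotypes(map_spec, n_lines=n, generation=8, seed=13)
    frac_sim = np.mean(
        [np.mean(pop.hap1[:, 0] != pop.hap1[:, 1]), np.mean(pop.hap2[:, 0] != pop.hap2[:, 1])]
    )
    frac_oracle = brute_force_ssd_two_markers(r, n, 8, np.random.default_rng(13))
    # both are Monte-Carlo estimates of the same RIL recombination fraction;
    # treat the two haplotypes of a line as one effective draw (conservative)
    p = (frac_sim + frac_oracle) / 2
    se = np.sqrt(2 * p * (1 - p) / n)
    assert abs(frac_sim - frac_oracle) < 3 * se


def test_invalid_map_rejected_naming_chromosome():
    with pytest.raises(ValueError, match="bad_chrom"):
        GeneticMapSpec(
            chromosomes=(ChromosomeSpec("bad_chrom", 1000, 2, positions=(500, 500)),)
        )


def test_simulate_requires_f2_or_later_and_two_lines():
    with pytest.raises(ValueError):
        simulate_ril_genotypes(single_marker_map(), n_lines=1, generation=8, seed=0)
    with pytest.raises(ValueError):
        simulate_ril_genotypes(single_marker_map(), n_lines=10, generation=1, seed=0)


def test_phenotypes_noiseless_additive_effect():
    pop = simulate_ril_genotypes(single_marker_map(), n_lines=400, generation=8, seed=3)
    qtl = QTLSpec("c1", 500_000, additive_effect=10.0, residual_sd=0.0)
    ph = assign_phenotypes(pop, qtl, baseline=50.0, seed=5)
    dose = pop.dose[:, 0]
    assert np.allclose(ph["trait"][dose == 0.0], 50.0)
    assert np.allclose(ph["trait"][dose == 1.0], 60.0)


def test_phenotype_variance_fraction_matches_request():
    # effect and residual chosen for a 50% QTL variance fraction:
    # var_g = effect^2 * var(dose) with var(dose) ~ 0.25 in a RIL
    chroms = tuple(ChromosomeSpec(f"c{i}", 1_000_000, 1) for i in range(2))
    pop = simulate_ril_genotypes(GeneticMapSpec(chromosomes=chroms), 1500, 8, seed=23)
    effect, resid = 20.0, 10.0
    ph = assign_phenotypes(pop, QTLSpec("c1", 500_000, effect, resid), 30.0, seed=29)
    dose = pop.dose[:, 0]
    var_g = np.var(effect * dose)
    realized = var_g / np.var(ph["trait"])
    assert abs(realized - 0.5) < 0.1


def test_phenotype_qtl_off_map_rejected():
    pop = simulate_ril_genotypes(single_marker_map(), 10, 8, seed=1)
    with pytest.raises(ValueError, match="nowhere"):
        assign_phenotypes(pop, QTLSpec("nowhere", 1, 1.0, 1.0), 0.0, seed=1)


def test_pure_pools_give_degenerate_allele_counts():
    pop = simulate_ril_genotypes(single_marker_map(), n_lines=40, generation=20, seed=31)
    # at F20 essentially every line is fixed; split by fixed genotype
    dose = pop.dose[:, 0]
    aa = [lid for lid, d in zip(pop.line_ids, dose) if d == 0.0][:5]
    bb = [lid for lid, d in zip(pop.line_ids, dose) if d == 1.0][:5]
    recs = sample_pool_depths(pop, bb, aa, PoolSeqSpec(5, 50.0, 0.0, seed=7))
    (rec,) = recs
    assert rec.ad_bulk_high[0] == 0  # pure B pool: no A reads
    assert rec.ad_bulk_low[1] == 0  # pure A pool: no B reads
    assert rec.ad_parent_a[1] == 0 and rec.ad_parent_b[0] == 0


def test_pool_frequency_unbiased_over_many_loci():
    chroms = (ChromosomeSpec("c1", 10_000_000, 1200),)
    pop = simulate_ril_genotypes(GeneticMapSpec(chromosomes=chroms), 30, 8, seed=37)
    high = pop.line_ids[:15]
    low = pop.line_ids[15:30]
    recs = sample_pool_depths(pop, high, low, PoolSeqSpec(15, 30.0, 0.0, seed=41))
    idx = {lid: i for i, lid in enumerate(pop.line_ids)}
    true_freq = pop.dose[[idx[l] for l in high]].mean(axis=0)
    est = np.array(
        [r.ad_bulk_high[1] / sum(r.ad_bulk_high) for r in recs if sum(r.ad_bulk_high) > 0]
    )
    mask = np.array([sum(r.ad_bulk_high) > 0 for r in recs])
    resid = est - true_freq[mask]
    se = resid.std(ddof=1) / np.sqrt(len(resid))
    assert abs(resid.mean()) < 3 * se


def test_pool_validation_rejects_overlap_and_empty():
    pop = simulate_ril_genotypes(single_marker_map(), 10, 8, seed=1)
    spec = PoolSeqSpec(2, 10.0, 0.0, seed=1)
    with pytest.raises(ValueError, match="disjoint"):
        sample_pool_depths(pop, pop.line_ids[:2], pop.line_ids[1:3], spec)
    with pytest.raises(ValueError, match="non-empty"):
        sample_pool_depths(pop, [], pop.line_ids[:2], spec)


def test_deg_table_marks_exactly_the_designated_genes():
    genes = [f"g{i}" for i in range(30)]
    deg = generate_deg_table(genes, n_de=0, seed=5)
    assert ((deg["log2fc"].abs() < 1) & (deg["fdr"] >= 0.05)).all()

    deg = generate_deg_table(genes, n_de=6, log2fc_range=(2.1, 4.9), fdr_alpha=0.05, seed=5)
    de = deg[deg["gene_id"].isin(genes[:6])]
    assert (de["log2fc"].abs() > 2).all() and (de["fdr"] < 0.05).all()
    rest = deg[~deg["gene_id"].isin(genes[:6])]
    assert ((rest["log2fc"].abs() < 1) & (rest["fdr"] >= 0.05)).all()

    deg = generate_deg_table(genes, de_log2fc={"g3": float(np.log2(30.36))}, seed=5)
    fc = 2 ** float(deg.set_index("gene_id").loc["g3", "log2fc"])
    assert fc == pytest.approx(30.36, rel=1e-9)

    with pytest.raises(ValueError):
        generate_deg_table([], n_de=0, seed=1)


def test_fixture_bundle_is_seed_deterministic(tmp_path):
    spec = FixtureSpec(seed=9, n_lines=40, markers_per_chrom=40, n_chromosomes=3,
                       qtl_chrom="Chr02")
    a = write_fixture_set(tmp_path / "a", spec)
    b = write_fixture_set(tmp_path / "b", spec)
    for name in ("variants.vcf", "genes.gff3", "genes.cds.fa", "phenotypes.tsv",
                 "deg.tsv", "truth.json"):
        assert (a.out_dir / name).read_bytes() == (b.out_dir / name).read_bytes()


def test_fixture_vcf_roundtrips_allele_depths(default_bundle):
    from bsaqtl.variants import contig_lengths, read_allele_depths

    records, report = read_allele_depths(str(default_bundle.vcf))
    assert report.n_indel == 0 and report.n_multiallelic == 0
    lengths = contig_lengths(str(default_bundle.vcf))
    assert len(lengths) == 9 and all(v == 40_000_000 for v in lengths.values())
    # every planted coding SNP is present with its planted alleles
    by_locus = {(r.chrom, r.pos): r for r in records}
    for snp in default_bundle.truth["coding_snps"]:
        rec = by_locus[(snp["chrom"], snp["pos"])]
        assert (rec.ref, rec.alt) == (snp["ref"], snp["alt"])
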