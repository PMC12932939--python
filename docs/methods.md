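# Methods

## Scope and model

`bsaqtl` implements the analysis route from extreme-phenotype pool
sequencing to prioritized candidate genes for a biparental RIL population:
per-bulk SNP indices against parental references, ΔSNP index, sliding
window smoothing, an empirical genome-wide significance threshold,
candidate-region calling, codon-level variant-effect annotation, and
intersection with differential-expression tables. Upstream read
processing, alignment, variant calling and DEG model fitting are out of
scope: the pipeline consumes a VCF with per-sample allele depths, gene
models (GFF3 plus a spliced-CDS FASTA), and a DEG TSV.

## SNP index and marker filters

For each biallelic SNP the parental filter keeps loci where both parents
have depth ≥ 7, minor-allele fraction ≤ 0.1, and opposite alleles; the
kept record is annotated with the allele of the tracked parent (parent B
by default, switchable — |Δ| and the threshold are orientation-invariant).
The SNP index of a pool is tracked-allele reads over total reads; zero
depth yields a *missing* index, a distinct state never coerced to 0.

The marker filter removes a locus when (a) the index is below 0.3 in
**both** pools, (b) depth is below 7 in **either** pool, or (c) an index
is missing in **any** pool. The grouping of clause (a) over both pools
follows the standard error-removal rationale of QTL-seq practice (an
artifact produces a low index in both bulks), while the depth clause is
per pool because one under-sequenced pool already makes Δ unreliable. A
locus failing several clauses is counted once in the filter report, with
precedence missing > depth > low-index. Both thresholds are configurable.

## Window scan

Windows of 1 Mb advance by 100 kb, anchored at position 1 of each
chromosome; the terminal window is truncated. The window statistic is the
unweighted mean Δ of member markers, computed as a direct slice mean so it
is bit-identical to averaging the member values. Windows with fewer than
`min_markers = 3` markers report a missing mean and are excluded from null
maxima — this guards the genome-wide maximum against single-marker spikes.
The default is a documented choice; the windowing parameters and
`min_markers` are all configurable.

## Permutation threshold

The genome-wide threshold is the 95th percentile (linear interpolation
between closest ranks — the convention is fixed so results are bit-exact
reproducible) of per-iteration genome-wide maxima of |windowed Δ| over
1,000 iterations. What to resample is a genuine design decision; three
schemes are implemented:

- **`genetic_null`** (default): a parametric null for the RIL pool-seq
  design. Each iteration simulates near-homozygous inbred-line haplotypes
  at the observed marker positions — a Markov walk per chromosome with
  switch probability R = 2r/(1+2r), where r is the Haldane recombination
  fraction of the inter-marker distance (genetic length set by
  `cm_per_mb`) — for two bulks of `bulk_size` lines, then redraws each
  pool's reads Binomial(observed depth, pool frequency adjusted by the
  error rate). Because lines are exchangeable and resimulated each
  iteration, two disjoint bulks of independent lines are distributionally
  identical to bulks drawn from a larger population.
- **`label_swap`**: per locus, swap the two pools' depth pairs with
  probability 1/2 (a sign flip of Δ).
- **`binomial_null`**: per locus and pool, redraw tracked-allele reads as
  Binomial(observed depth, 0.5), the expected null frequency in an inbred
  biparental population.

The per-locus schemes preserve each locus's marginal index distribution
but break two properties of the real no-QTL null: the *shared
bulk-composition variance* (the same 15 lines underlie every locus of a
bulk, so Δ at linked loci is strongly correlated) and hence the linkage
correlation of Δ within a window. Window means of independently resampled
loci shrink by roughly √(markers per window), so their genome-wide maxima
are far too small: in simulation the observed null maximum exceeded the
`label_swap` threshold in ~90% and the `binomial_null` threshold in ~100%
of no-QTL datasets, against a nominal 5%. The `genetic_null` scheme
reproduces both properties and calibrates at the nominal rate (test
suite), which is why it is the default. The approximation it makes —
treating inbred lines as fully homozygous single haplotypes with the
limiting RIL recombination fraction instead of generation-exact values —
leaves a residual heterozygosity of (1/2)^(n−1) ≈ 0.8% at F8 unmodelled
and is negligible at these depths.

Significant windows (|mean Δ| ≥ threshold) merge into regions when
overlapping or book-ended; region bounds are the union extent, the peak is
the extremal windowed value with its sign, and the locus count is the
number of filtered markers inside.

## Variant effects

Gene models carry ordered CDS segments and the spliced coding sequence;
models whose CDS length is not a multiple of three are flagged incomplete
and excluded from effect calls (positions inside them report noncoding
plus a warning count). A substitution is classified by translating the
affected codon before and after the change with the standard genetic code,
complementing alleles into transcript orientation on minus-strand genes:
same amino acid → synonymous, sense→stop → stop_gain, stop→sense →
stop_loss, otherwise nonsynonymous (start-codon loss is not a separate
category). Only single-nucleotide substitutions are annotated; indels,
splice sites and regulatory annotation are out of scope. Coordinates are
1-based inclusive throughout (VCF/GFF3 convention); BED output converts at
serialization only. The annotator is property-tested against an
independent oracle that rebuilds the entire CDS, translates both versions,
and diffs the proteins.

## Candidate genes

A gene enters the candidate set when it overlaps a region (any CDS base,
inclusive) and carries ≥ 1 protein-altering variant inside the region;
both nonsynonymous and stop variants count, and the category set is
configurable since either convention is defensible. The DEG join keeps
genes with |log2FC| > 1 and FDR < 0.05 (a `strict` preset switches to
|log2FC| > 3, FDR < 0.01); genes missing from the DEG table are reported
separately, never silently dropped, and duplicate DEG rows are an error.
Ranking uses the signed linear fold change sign(log2FC)·2^|log2FC|
(negative = higher in the sensitive genotype), descending by magnitude
with lexicographic tie-breaks, and flags |fold change| > 4.

## Phenotype utilities

NUtE is whole-plant dry weight over whole-plant nitrogen content (g·g⁻¹).
Extreme bulks are taken from class-qualifying lines (low class 25–35
g·g⁻¹, high class > 75 g·g⁻¹ by default) by within-class ranking up to the
pool size — a deterministic rule that maximizes pool contrast when more
lines qualify than fit the pool. Distribution moments use the adjusted
Fisher–Pearson skewness G1 = g1·√(n(n−1))/(n−2) and bias-corrected excess
kurtosis G2 = (n−1)/((n−2)(n−3))·((n+1)·g2 + 6), the conventions common
desktop statistics suites print. The qPCR utility returns 2^−ΔΔCt.

## The simulator and what it does (not) show

The generator's defaults emulate the study design the pipeline targets:
120 lines bred by single-seed descent to F8 (each generation advances one
selfed offspring per line, so expected heterozygosity is (1/2)^(n−1)),
nine 40-Mb chromosomes, Haldane meioses with no interference at 3 cM/Mb,
one additive QTL at Chr03:20 Mb with additive effect 27, residual SD 13.5
and baseline 30 (trait units g·g⁻¹), i.e. heritability 0.5 — a "major
QTL" setting chosen once since the real variance fraction is unknown —
15+15 extreme bulks, Poisson(23) per-locus pool depth, and a per-read
allele-flip error of 0.001 (the order of magnitude of modern short-read
error rates). Chromosome count, marker density (250/chromosome) and map
length are free parameters, not estimates of any real population. One
global seed spawns per-stage substreams, so bundles are byte-reproducible.

The default bundle plants six candidate genes within ±2 Mb of the QTL,
each with a parent-segregating nonsynonymous variant and a DE record
passing the default thresholds (linear fold changes 15.01, 30.36, −4.30,
4.10, −3.22, −3.80, so four exceed the priority cutoff), plus three
decoys: an in-region gene with only a synonymous variant, an in-region
nonsynonymous gene with a sub-threshold DE record, and an out-of-region
nonsynonymous gene with a strong DE record. Backbone markers are nudged
out of coding sequence so every coding variant is deliberate.

What the simulation does **not** model: alignment and mapping artifacts,
indels and multiallelic sites, crossover interference, segregation
distortion, epistasis or multi-QTL architectures, depth heterogeneity
beyond Poisson, and batch structure in expression data. Passing tests
therefore demonstrate the statistical machinery under the stated
generative assumptions, not performance on any particular real dataset.

## Numerical and interface choices

- Percentile convention: linear interpolation; percentile 100 = max.
- Missing indices/means propagate as NaN in tables, never as 0.
- TSV/BED floats use `%.6g`, making reruns byte-identical; values that
  round-trip through tables are therefore exact to six significant digits.
- Pipeline stages abort on first failure naming the stage; CLI exit codes:
  0 ok, 2 validation, 3 data error.
- Problem sizes in the test suite and acceptance script (200 null datasets
  × 200 iterations for calibration; 50 replicates for recovery; reduced
  in-test iteration counts) are chosen to give stable Monte-Carlo
  estimates at interactive runtimes.

## Known limitations

- The genetic null is parametric, not a re-randomization of the observed
  reads; its calibration rests on the design parameters (`bulk_size`,
  `cm_per_mb`, error rate) being roughly right for the data at hand.
- Effect annotation assumes the VCF reference allele matches the CDS base
  at coding positions and raises otherwise rather than guessing.
- Window means are unweighted; depth-weighted or Bayesian per-locus index
  estimators are out of scope.
- `select_extreme_bulks` requires the class bounds to be attainable; it
  does not fall back to pure rank selection.
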