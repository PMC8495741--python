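# Methods

`paralogdiverge` implements the quantitative toolkit used to study how a
duplicated gene pair divides an ancestral function between its copies,
with the budding-yeast MutL-homolog (MLH) family as the model: Pms1
specialised for post-replicative mismatch repair (MMR), Mlh3 for
resolving meiotic recombination intermediates into crossovers.  Four
analyses are covered: evolutionary rate covariation (ERC) between
protein/domain trees, discovery of specificity-determining alignment
positions between the two paralog subfamilies, mutation-rate estimation
from fluctuation assays, and crossover classification from tetrad
counts.  A synthetic-data module generates statistically faithful inputs
for every stage so the whole pipeline is testable without external data.

## Relative evolutionary rates and ERC

**Model.** For each gene or domain, branch lengths on a shared species
topology are compared with a genome-wide expectation.  Branch identity
is by leaf bipartition, so rooting is irrelevant; gene trees missing
taxa are matched against the master topology pruned to the taxa present,
with fused branch paths carrying summed lengths.

Branch lengths are square-root transformed (variance stabilisation: raw
branch-length variance grows with the mean).  The normalization vector
`a_b` is the per-branch mean of transformed lengths over a reference set
of genes (branches supported by fewer than `min_support = 5` reference
genes are dropped).  Each gene's transformed vector `x_b` is projected
on `a_b` by least squares through the origin; the residuals
`RER_b = x_b − β a_b` are the gene's relative evolutionary rates.  Genes
sharing fewer than `min_branches = 10` branches with the normalization
vector are reported as undefined rather than forced to zero.  The
through-origin, unweighted, sqrt-transform choices are this package's
fixed convention; rescaling a gene's raw lengths by `c` scales its RER
vector by `√c` and leaves every downstream correlation unchanged, so the
per-gene rate scale never matters.  An exact fit leaves float-rounding
residue; residuals below `1e-10 × max(1, max|x|)` are snapped to zero so
a rate-deviation-free gene yields RER ≡ 0 and an undefined (NA) ERC
instead of a correlation of numerical noise.

**ERC.** The ERC of a pair is the Pearson correlation of the two RER
vectors over shared branches after per-vector Winsorization: in each
tail, the two most extreme values are limited to the third most extreme
value (vectors with fewer than three distinct finite values pass
through).  This keeps one aberrant lineage from dominating a
33-branch correlation.  Empirical significance ranks the observed ERC in
a null built from the ERC of both focal genes against every member of a
reference panel, with an add-one correction:
`p = (1 + #{null ≥ obs}) / (1 + m)`.  The null construction is this
package's convention (the one-sided direction reflects that elevated
covariation is the signal of interest); a panel of several hundred genes
is recommended — the null is shared across pairs, and small panels make
the realized false-positive rate drift visibly around its nominal level.

**What the generator emulates.** `simulate_gene_trees` draws, per gene,
`sqrt-length = β_g a_b + ε` with `β_g` log-normal (σ = 0.25), `ε`
Gaussian (σ = 0.08 on the sqrt scale) and raw lengths the squares,
floored at zero, on a fixed 18-taxon budding-yeast topology (33
branches).  A covarying pair shares its deviation through
`ε = ρ z_shared + √(1−ρ²) z_own`; note the induced residual correlation
is ρ², so ρ = 1 gives ERC ≈ 1 and intermediate ρ gives proportionally
weaker signal.  Under independence (ρ = 0) the empirical-p pipeline is
calibrated: measured type-I error at p < 0.05 is within 0.05 ± 0.02 over
800 pairs against a 400-gene panel.  The mean *absolute* null ERC is
≈ √(2/(π·32)) ≈ 0.14 — an unavoidable property of correlations on 33
branches, not a miscalibration; the null is centred (mean ERC ≈ 0).
The generator does not emulate phylogenetic non-independence among
branches, alignment/tree-inference error, or shared-pathway structure
beyond designated pairs; a passing calibration therefore shows the
statistic behaves correctly given trees, not that inferred trees are
good.

## Specificity-determining positions

Two per-column scores over a two-subfamily alignment (group A =
Mlh3-like, group B = Pms1-like):

* **Sequence harmony** `sh = 1 − JSD(p_A, p_B)` with base-2 logs and
  equal weights, where `p_A`, `p_B` are the groups' residue frequency
  distributions (gaps and ambiguous residues B/Z/X excluded).  Identical
  distributions give 1, disjoint give 0.
* **Multi-relief**: a two-group RELIEF weight.  For each of
  `iterations = 10,000` draws, sample a sequence uniformly, find its
  nearest hit (same group) and nearest miss (other group) by Hamming
  distance over unmasked columns (random tie-breaking), and score each
  column `+1` if the miss differs there, `−1` if the hit differs; the
  averaged weight lies in [−1, 1].  The seed is mandatory and logged.

Columns where either group is more than 50% gapped are masked.
Candidates combine both scores — `mr > 0.8` and `sh < 0.5` — the cutoff
pair used in the MLH study.  Candidate columns are mapped to 1-based
ungapped residue numbers in a chosen member of each subfamily and
grouped into blocks by linear proximity (successive gaps ≤ 15 residues).
Linear grouping is a deliberate proxy for clustering on the folded
structure, which requires a 3-D model and is out of scope.  A simplified
conserved-column filter (gap fraction, gap adjacency, majority-residue
frequency) stands in for full conserved-block alignment trimming.

**Generator.** Planted alignments use the study's subfamily sizes
(29 + 34) and 300 columns with 10 specificity columns (disjoint
group consensi).  Divergence from a column's consensus (10% overall) is
split two-level: 70% of the deviation rate is drawn once per
within-group lineage cluster of 2 sequences, 30% independently per
sequence.  The split mimics the phylogenetic correlation of real
subfamily alignments — close relatives share substitutions — which is
precisely the structure RELIEF's nearest-hit step exploits; with fully
independent per-sequence noise the expected weight of a genuinely
group-specific column is ≈ 0.79, below the 0.8 cutoff, and no scorer of
this family would recover it.  Under the two-level model recovery is
9–10/10 planted columns with ≈ 0 false positives.  The generator does
not emulate indels (planted alignments are gap-free), rate variation
along the sequence, or non-uniform amino-acid composition.  A caveat
observed in simulation: with very small subfamilies (≈ 4 lineages per
group) chance lineage structure can mimic group divergence; the dual
cutoff (harmony must also be low) suppresses most but not all of it.

## Fluctuation-assay mutation rates

**Estimator.** The method of the median for Luria–Delbrück parallel
cultures: per-culture reversion frequencies `f_i = r_i / N_i`, median
frequency `f`, representative viable count `N = median(N_i)`, and the
rate as the root of `μ ln(N μ) = f` on its increasing branch
(`N μ > 1`), solved by bracketed bisection to relative tolerance 1e-12.
`f = 0` reports rate 0 with a flag; `0 < f ≤ e/N` is below the
equation's detection floor and is flagged likewise.  The 95% CI uses
binomial order-statistic ranks `floor((n − 1.96√n)/2)` and
`ceil(1 + (n + 1.96√n)/2)` (clamped to [1, n], requiring n ≥ 6) applied
to per-culture rates; per-culture rates share the common `N` so their
order follows the frequencies and the interval always brackets the point
estimate.  Strains are compared with the Mann–Whitney U test (exact
enumeration when the smaller sample ≤ 8 without ties; tie-corrected,
continuity-corrected normal approximation otherwise — measured to track
the exact branch within 0.011 at n = 8).  Relative rates are reported
both raw and rounded to 3 significant figures (half-to-even), because
published tables round from unrounded intermediates.

**Generator and fidelity.** Cultures grow by discrete generation
doubling from a mutant-free inoculum (N₀ = 10³) to ≥ 2×10⁸ cells; each
generation new mutants arise binomially among non-mutant births at rate
μ and existing mutant lineages double.  This reproduces the
Luria–Delbrück signature (mean ≫ median, variance ≫ Poisson).  Measured
fidelity at 30 cultures: the median estimate is within a factor 1.5 of
truth across μ = 10⁻⁷…10⁻³ (ratios ≈ 1.09, 0.90, 0.73), and CI coverage
at the assay-relevant rate μ = 10⁻⁷ is ≈ 93%.  **Known limitation:** the
order-statistic CI captures sampling spread only; at high rates the
median method's systematic bias (relative to this growth model) exceeds
the shrinking sampling spread and coverage degrades badly (≈ 77% at
10⁻⁵, ≈ 0% at 10⁻³).  The CI should be read as approximate and
rate-regime dependent.  Maximum-likelihood (Ma–Sandri–Sarkar) estimation
and plating-efficiency corrections are out of scope.

## Tetrad crossover classification

The spore-autonomous fluorescence assay scores tetrads in a two-marker
interval as parental ditype (no crossover) or tetratype (single
crossover); the readout is `% TT = 100·TT/(TT+PD)` (reference anchors:
37.1% for wild type over 1023 tetrads, 18.3% for the mlh3 null over
1239).  Each genotype is compared against both references with Pearson's
chi-squared on the 2×2 table (no continuity correction; the Yates
variant is available behind a flag).  Both p-values of every genotype
enter a single Benjamini–Hochberg family at q = 0.05, and the
significance pattern yields the call: `+` (≠ null only), `−` (≠ wild
type only), `+/−` (≠ both), `indeterminate` (≠ neither; logged — with
assay-scale counts it essentially never occurs).  Planted alleles at the
null, intermediate (27%), and wild-type fractions (n = 800 tetrads) are
called `−`, `+/−`, `+` in ≥ 95% of replicates.  The BH cutoff reported
is the largest significant raw p and depends on the whole family; map
distances (centiMorgans) and non-parental-ditype classes are out of
scope.

## Numerical and design conventions

* Alignment columns are 1-based; residue coordinates are 1-based
  ungapped indices (Mlh3 domains: ATP-binding 1–375, linker 376–488,
  endonuclease 489–715; Pms1: 1–361, 362–638, 639–877).
* Gap character `-`; B, Z, X and other non-standard residues are treated
  as gaps for all scoring.
* One tabular dialect everywhere: TSV, UTF-8, header row.
* Winsorization ties are resolved by value (everything above/below the
  third order statistic is clipped to it), preserving element order.
* All generators derive per-gene/per-culture sub-streams from the run
  seed, so outputs are byte-identical across runs and stable when counts
  change; every CLI run logs its seed and writes a manifest.
* Median-of-frequencies (compute `f_i`, then the median) is the fixed
  convention; the alternative orderings the literature occasionally uses
  are not implemented.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run every analysis at sizes
chosen to match the assays while keeping a full run in the order of
seconds: 800 null pairs against a 400-gene panel for calibration, 100
fluctuation experiments of 30 cultures, 29+34-sequence alignments of 300
columns with 10,000 RELIEF iterations, and 100–200 tetrad replicates at
800–1300 tetrads per genotype.
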