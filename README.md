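# paralogdiverge

Quantitative analyses of paralog sub-functionalization, built around the
budding-yeast MutL-homolog (MLH) family — Pms1 specialised for DNA
mismatch repair, Mlh3 for resolving meiotic recombination intermediates
into crossovers.  The package is for molecular evolution and yeast
genetics groups who want to run, on their own or on simulated data, the
four analyses that together make the sub-functionalization argument:

1. **Evolutionary rate covariation (ERC)** — branch lengths of each
   gene/domain tree are normalised into relative evolutionary rates
   (RERs): sqrt-transformed lengths `x_b` are projected on a genome-wide
   expectation `a_b` through the origin, `RER_b = x_b − β a_b`.  ERC of
   a pair is the Pearson correlation of Winsorized RER vectors over
   shared branches (each tail's two most extreme values limited to the
   third), with an empirical p-value from ranking against a reference
   panel: `p = (1 + #{null ≥ obs}) / (1 + m)`.
2. **Specificity-determining positions** — per-column sequence harmony
   `sh = 1 − JSD(p_A, p_B)` (base-2, equal weights) and a two-group
   multi-relief weight `mr` (nearest hit/miss by Hamming distance);
   candidate positions satisfy `mr > 0.8` and `sh < 0.5`, are mapped to
   1-based residue numbers in each paralog, and grouped into blocks.
3. **Fluctuation-assay mutation rates** — the method of the median for
   `lys2::insE-A14` reversion: `μ = f / ln(N·μ)` solved on its
   increasing branch, order-statistic 95% CIs, Mann–Whitney strain
   comparisons, and relative-to-wild-type ratios.
4. **Tetrad crossover classification** — `%TT = 100·TT/(TT+PD)` per
   genotype, Pearson chi-squared against wild-type and null references,
   Benjamini–Hochberg control at 5% FDR, and the three-way call
   `{+, −, +/−}`.

A first-class synthetic-data module (`paralogdiverge.simulate`)
generates every input — covarying gene trees on an 18-taxon yeast
topology, Luria–Delbrück culture tables, binomial tetrad draws, and
two-subfamily alignments with planted specificity columns — so each
stage can be exercised and validated end to end.  See
`docs/methods.md` for the models, assumptions, and limitations.

## Worked example

```python
from paralogdiverge import datasets
from paralogdiverge.fluctuation import estimate_rate, relative_rate
from paralogdiverge.simulate import (SimulationConfig, simulate_cultures,
                                     simulate_tetrads)
from paralogdiverge.tetrad import classify_table

# Relative mutation rates from the packaged published reversion table
panel = datasets.REVERSION_REFERENCE["sk1_integrated"]
wt = panel["strains"][0]["rate"] * panel["scale"]
for row in panel["strains"][1:3]:
    raw, rounded = relative_rate(row["rate"] * panel["scale"], wt)
    print(f"{row['strain']:<12} relative rate {rounded:g} "
          f"(reported {row['reported_relative']:g})")

# A simulated fluctuation experiment, estimated by the method of the median
cfg = SimulationConfig(seed=7, mu=1e-7, n_cultures=30)
est = estimate_rate(simulate_cultures(cfg))
print(f"simulated mu=1e-07: estimate {est.mu:.2e} "
      f"(95% CI {est.ci_low:.2e}-{est.ci_high:.2e})")

# Tetrad classification of an intermediate allele against both references
wt_pct, wt_n = datasets.TETRATYPE_REFERENCE["wild_type"]
null_pct, null_n = datasets.TETRATYPE_REFERENCE["mlh3_null"]
tetrads = simulate_tetrads(cfg, [("WT", wt_pct / 100, wt_n),
                                 ("mlh3-null", null_pct / 100, null_n),
                                 ("allele", 0.27, 800)])
print(classify_table(tetrads, "WT", "mlh3-null")
      [["genotype", "percent_tt", "call"]].to_string(index=False))
```

prints

```
mlh3-null    relative rate 6.06 (reported 6.05)
PPP-chimera  relative rate 8.05 (reported 8.1)
simulated mu=1e-07: estimate 1.07e-07 (95% CI 7.92e-08-1.38e-07)
 genotype  percent_tt      call
   allele        27.6       +/-
       WT        40.2 reference
mlh3-null        19.9 reference
```

The recomputed relative rates agree with the published column to one
unit in the last printed digit (published tables round from unrounded
intermediates); the median-method estimate recovers the planted rate and
its CI covers it; the allele planted at an intermediate tetratype
fraction is called distinguishable from both references (`+/-`).

## Command line

```sh
paralogdiverge demo --seed 7 --out demo/          # simulate + run everything
paralogdiverge simulate trees --seed 1 --pairs 3 --rho 0.9 --out sim/
paralogdiverge rer --trees sim/genes.nwk --reference sim/genes.nwk \
    --master sim/master.nwk --out rer.tsv
paralogdiverge erc --rer rer.tsv --out erc_matrix.tsv
paralogdiverge harmony --aln aln.fasta --groups groups.tsv --out scores.tsv
paralogdiverge flucrate --cultures cultures.tsv --reference-strain WT --out rates.tsv
paralogdiverge tetrad --counts tetrads.tsv --wt WT --null mlh3del --out calls.tsv
```

Every run writes a JSON manifest (subcommand, seed, inputs, outputs,
version, timestamp) next to its outputs; stochastic stages log their
seed and are byte-reproducible.

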