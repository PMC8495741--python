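"""Synthetic data generators for every pipeline input.

Each generator emulates the statistical structure its analysis assumes,
at the scale of the assays the package models:

* gene trees with rate covariation on an 18-taxon yeast topology (33
  branches) — per-gene scale times per-branch deviation on the
  square-root scale, with a mixing parameter ``rho`` controlling how
  much of the deviation a covarying pair shares;
* Luria-Delbruck fluctuation cultures by discrete generation doubling
  from a small mutant-free inoculum (15-44 cultures, rates spanning
  1e-7 to 1e-3 per generation);
* tetrad draws as binomial TT counts at a planted tetratype fraction
  (fractions 0.18-0.37 at a few hundred to ~1300 tetrads, the scale of
  the crossover assay);
* two-subfamily alignments with planted specificity columns (group
  sizes 29 and 34, matching the Mlh3/Pms1 subfamily alignments).

All generators are reproducible: the same seed and parameters give
byte-identical outputs.  Sub-streams are derived per gene/culture so
outputs stay stable when counts change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .alignments import AMINO_ACIDS, SubfamilyAlignment
from .errors import ValidationError
from .tables import CultureTable, TetradTable
from .trees import GeneTreeSet, branch_lengths, parse_tree


@dataclass
class SimulationConfig:
    """Parameters for all four generators (one seed governs each run)."""

    seed: int = 0
    # gene trees
    master_newick: str = datasets.MASTER_TREE_NEWICK
    n_reference_genes: int = 200
    n_pairs: int = 0
    rho: float = 0.0            # pairwise covariation mixing in [0, 1]
    sigma: float = 0.08         # branch-deviation s.d. (sqrt scale)
    beta_sigma: float = 0.25    # s.d. of log per-gene scale
    # fluctuation cultures
    mu: float = 1e-6
    n_cultures: int = 15
    n0: int = 1_000
    n_final: float = 2e8
    # tetrads
    p_tt: float = datasets.TETRATYPE_REFERENCE["wild_type"][0] / 100.0
    n_tetrads: int = 1023
    # alignments
    group_sizes: tuple[int, int] = (29, 34)
    length: int = 300
    n_specificity_columns: int = 10
    background_conservation: float = 0.9
    specificity_conservation: float = 0.9
    cluster_size: int = 2       # sequences per within-group lineage cluster
    lineage_fraction: float = 0.7  # share of divergence inherited per cluster

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [0, 1]")
        if not 0.0 <= self.p_tt <= 1.0:
            raise ValidationError("p_tt must lie in [0, 1]")


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def simulate_gene_trees(config: SimulationConfig) -> GeneTreeSet:
    """Reference genes plus covarying focal pairs on the master topology.

    On the square-root scale each gene's branch is
    ``beta_g * a_b + eps``, with ``a_b`` the master branch's sqrt length,
    ``beta_g`` log-normal and ``eps ~ N(0, sigma)``; raw lengths are the
    squares, floored at 0.  For a covarying pair the deviation is
    ``rho * z_shared + sqrt(1 - rho^2) * z_own``, so ``rho = 1`` gives
    identical deviations and ``rho = 0`` independent ones.

    Genes are named ``ref_i`` and ``pair{k}_a`` / ``pair{k}_b``.
    """
    master = parse_tree(config.master_newick)
    taxa, mbranches = branch_lengths(master)
    branches = sorted(mbranches, key=lambda s: tuple(sorted(s)))
    a = np.sqrt(np.array([mbranches[b] for b in branches]))
    ts = GeneTreeSet(taxa=taxa, master_branches=mbranches, master_tree=master)

    def make_gene(rng: np.random.Generator, eps: np.ndarray) -> dict:
        beta = float(np.exp(rng.normal(0.0, config.beta_sigma)))
        sqrt_lengths = np.maximum(beta * a + eps, 0.0)
        return dict(zip(branches, sqrt_lengths ** 2))

    for i in range(config.n_reference_genes):
        rng = _substream(config.seed, 0, i)
        eps = rng.normal(0.0, config.sigma, size=a.size)
        ts.add_gene_branches(f"ref_{i}", make_gene(rng, eps))
    for k in range(config.n_pairs):
        rng = _substream(config.seed, 1, k)
        z_shared = rng.normal(0.0, config.sigma, size=a.size)
        for member in ("a", "b"):
            z_own = rng.normal(0.0, config.sigma, size=a.size)
            eps = config.rho * z_shared + np.sqrt(1 - config.rho ** 2) * z_own
            ts.add_gene_branches(f"pair{k}_{member}", make_gene(rng, eps))
    return ts


def simulate_cultures(config: SimulationConfig,
                      strain: str = "sim") -> CultureTable:
    """Parallel cultures under Luria-Delbruck growth.

    Each culture doubles from ``n0`` mutant-free cells until it reaches
    at least ``n_final`` cells; every generation, non-mutant divisions
    produce new mutants binomially at rate ``mu`` while existing mutant
    lineages double.  Revertant counts are therefore jackpot-skewed
    (variance far above Poisson at the same mean).
    """
    if config.n_final <= config.n0:
        raise ValidationError("n_final must exceed n0")
    generations = int(np.ceil(np.log2(config.n_final / config.n0)))
    if generations > 60:
        raise ValidationError(f"{generations} generations would overflow")
    rows = []
    for i in range(config.n_cultures):
        rng = _substream(config.seed, 2, i)
        nonmut, mut = int(config.n0), 0
        for _ in range(generations):
            new = int(rng.binomial(nonmut, config.mu)) if config.mu > 0 else 0
            mut = 2 * mut + new
            nonmut = 2 * nonmut - new
        rows.append({"strain": strain, "batch": f"batch_{i % 2}",
                     "revertants": mut, "viable": nonmut + mut})
    return CultureTable(pd.DataFrame(rows))


def simulate_tetrads(config: SimulationConfig,
                     genotypes: list[tuple[str, float, int]] | None = None
                     ) -> TetradTable:
    """Binomial tetrad draws: ``TT ~ Binomial(n_tetrads, p_tt)``.

    ``genotypes`` optionally lists ``(name, p_tt, n_tetrads)`` rows; by
    default a single genotype at the configured fraction is drawn.
    """
    if genotypes is None:
        genotypes = [("sim", config.p_tt, config.n_tetrads)]
    rows = []
    for i, (name, p_tt, n) in enumerate(genotypes):
        if not 0.0 <= p_tt <= 1.0:
            raise ValidationError("p_tt must lie in [0, 1]")
        rng = _substream(config.seed, 3, i)
        tt = int(rng.binomial(n, p_tt))
        rows.append({"genotype": name, "TT": tt, "PD": n - tt})
    return TetradTable(pd.DataFrame(rows))


@dataclass
class PlantedAlignment:
    alignment: SubfamilyAlignment
    specificity_columns: list[int] = field(default_factory=list)  # 1-based


def simulate_paralog_alignment(config: SimulationConfig) -> PlantedAlignment:
    """Two-subfamily alignment with planted specificity columns.

    Background columns share one consensus residue across both groups at
    the configured conservation; specificity columns give each group its
    own (disjoint) consensus.  Divergence from the consensus is split
    between two levels, mimicking the phylogenetic correlation of real
    subfamily alignments: a ``lineage_fraction`` of the deviation rate is
    drawn once per within-group cluster of ``cluster_size`` sequences
    (close relatives share substitutions), the rest independently per
    sequence.  The planted column positions are returned as ground truth.
    """
    n_a, n_b = config.group_sizes
    if min(n_a, n_b) < 4:
        raise ValidationError("each group needs at least 4 sequences")
    if config.n_specificity_columns > config.length:
        raise ValidationError("more specificity columns than columns")
    rng = _substream(config.seed, 4)
    n = n_a + n_b
    aa = np.array(list(AMINO_ACIDS))
    matrix = np.empty((n, config.length), dtype="<U1")
    spec_cols = sorted(rng.choice(config.length,
                                  size=config.n_specificity_columns,
                                  replace=False).tolist())
    spec_set = set(spec_cols)
    # cluster id per sequence, never spanning the group boundary
    cluster = np.empty(n, dtype=int)
    k = max(1, config.cluster_size)
    offset = 0
    for start, size in ((0, n_a), (n_a, n_b)):
        ids = np.arange(size) // k
        cluster[start:start + size] = offset + ids
        offset += int(ids[-1]) + 1
    n_clusters = offset

    def _deviate(cons: np.ndarray, rate: float, m: int) -> np.ndarray:
        hit = rng.random(m) < rate
        shift = rng.integers(1, 20, size=m)
        return np.where(hit, (cons + shift) % 20, cons)

    for col in range(config.length):
        if col in spec_set:
            cons_a, cons_b = rng.choice(20, size=2, replace=False)
            cons = np.array([cons_a] * n_a + [cons_b] * n_b)
            divergence = 1.0 - config.specificity_conservation
        else:
            cons = np.full(n, rng.integers(20))
            divergence = 1.0 - config.background_conservation
        d_cluster = divergence * config.lineage_fraction
        d_seq = divergence * (1.0 - config.lineage_fraction)
        cluster_cons = np.zeros(n_clusters, dtype=int)
        for cid in range(n_clusters):
            members = np.flatnonzero(cluster == cid)
            cluster_cons[cid] = _deviate(cons[members[:1]], d_cluster, 1)[0]
        residues = _deviate(cluster_cons[cluster], d_seq, n)
        matrix[:, col] = aa[residues]
    ids = [f"mlh3like_{i}" for i in range(n_a)] + \
          [f"pms1like_{i}" for i in range(n_b)]
    labels = ["A"] * n_a + ["B"] * n_b
    aln = SubfamilyAlignment(ids, labels, matrix)
    return PlantedAlignment(alignment=aln,
                            specificity_columns=[c + 1 for c in spec_cols])
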