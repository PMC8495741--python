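"""Relative evolutionary rates (RERs) from branch-length vectors.

A gene's branch lengths confound two things: how fast that lineage
evolves overall (shared by all genes) and how fast the gene itself
evolves on each lineage.  RER normalization removes the shared part:

1. Branch lengths are square-root transformed (variance stabilization —
   raw branch lengths have variance growing with their mean).
2. A *normalization vector* ``a_b`` is the per-branch mean of the
   transformed lengths over a large reference set of genes; it estimates
   the genome-wide expectation for each branch.
3. Each gene's transformed vector ``x_b`` is projected onto the
   normalization vector by least squares through the origin
   (``beta = sum(a x) / sum(a^2)``); the residuals
   ``RER_b = x_b - beta * a_b`` are the gene's relative rates.

Rescaling a gene's raw lengths by ``c`` scales its RER vector by
``sqrt(c)``, so all downstream correlations are invariant to per-gene
rate scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .trees import GeneTreeSet


@dataclass
class NormalizationVector:
    """Per-branch expected sqrt-transformed length with support counts."""

    values: dict   # BranchId -> a_b
    support: dict  # BranchId -> number of reference genes contributing

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RERProfile:
    """Per-branch rate residuals for one gene, plus its scaling fit."""

    gene: str
    branches: tuple
    residuals: np.ndarray
    beta: float

    def as_dict(self) -> dict:
        return dict(zip(self.branches, self.residuals))


def _gene_mapping(trees) -> Mapping[str, Mapping]:
    if isinstance(trees, GeneTreeSet):
        return trees.genes
    return trees


def estimate_normalization(trees, min_support: int = 5) -> NormalizationVector:
    """Estimate the per-branch expectation from a reference gene set.

    ``a_b`` is the mean of sqrt-transformed branch lengths across the
    reference genes that have branch ``b``; branches supported by fewer
    than ``min_support`` genes are dropped.
    """
    genes = _gene_mapping(trees)
    if not genes:
        raise InsufficientDataError("empty reference gene set")
    sums: dict = {}
    counts: dict = {}
    for branches in genes.values():
        for b, length in branches.items():
            sums[b] = sums.get(b, 0.0) + float(np.sqrt(length))
            counts[b] = counts.get(b, 0) + 1
    values = {b: sums[b] / counts[b] for b in sums if counts[b] >= min_support}
    support = {b: counts[b] for b in values}
    return NormalizationVector(values=values, support=support)


def compute_rer(gene_branches: Mapping, norm: NormalizationVector,
                gene: str = "?", min_branches: int = 10) -> RERProfile:
    """Fit one gene against the normalization vector and return residuals."""
    shared = sorted(set(gene_branches) & set(norm.values),
                    key=lambda s: tuple(sorted(s)))
    if len(shared) < min_branches:
        raise InsufficientDataError(
            f"gene {gene!r}: {len(shared)} shared branches < {min_branches}")
    x = np.sqrt(np.array([gene_branches[b] for b in shared], dtype=float))
    a = np.array([norm.values[b] for b in shared], dtype=float)
    denom = float(a @ a)
    if denom == 0.0:
        raise InsufficientDataError("normalization vector is identically zero")
    beta = float(a @ x) / denom
    residuals = x - beta * a
    # snap float-rounding residue of an exact fit to zero so a gene with
    # no rate deviation reports RER 0 (and downstream ERC undefined)
    tol = 1e-10 * max(1.0, float(np.max(np.abs(x))))
    residuals[np.abs(residuals) < tol] = 0.0
    return RERProfile(gene=gene, branches=tuple(shared),
                      residuals=residuals, beta=beta)


def rer_profiles(trees, norm: NormalizationVector | None = None,
                 min_support: int = 5,
                 min_branches: int = 10) -> dict[str, RERProfile]:
    """RER profiles for every gene in ``trees``.

    When ``norm`` is omitted it is estimated from the same gene set.
    Genes with too few shared branches are skipped.
    """
    genes = _gene_mapping(trees)
    if norm is None:
        norm = estimate_normalization(genes, min_support=min_support)
    out: dict[str, RERProfile] = {}
    for name, branches in genes.items():
        try:
            out[name] = compute_rer(branches, norm, gene=name,
                                    min_branches=min_branches)
        except InsufficientDataError:
            continue
    return out


def rer_table(profiles: Iterable[RERProfile]) -> pd.DataFrame:
    """Branch x gene matrix of RERs (NaN where a branch is absent).

    Branch ids are rendered as '|'-joined taxon labels of the canonical
    bipartition side.
    """
    profiles = list(profiles)
    all_branches = sorted({b for p in profiles for b in p.branches},
                          key=lambda s: tuple(sorted(s)))
    data = {}
    for p in profiles:
        d = p.as_dict()
        data[p.gene] = [d.get(b, np.nan) for b in all_branches]
    index = ["|".join(sorted(b)) for b in all_branches]
    return pd.DataFrame(data, index=index)
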