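"""Evolutionary rate covariation (ERC) between RER profiles.

ERC between two genes/domains is the Pearson correlation of their RER
vectors over shared branches, after per-vector Winsorization: in each
tail, the two most extreme values are limited to the third most extreme
value, which keeps a single aberrant lineage from dominating the
correlation.  An empirical p-value for a pair is obtained by ranking the
observed ERC within a null distribution built from the ERC of each focal
member against every gene of a reference panel, with an add-one
correction so p is never exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .rer import RERProfile

logger = logging.getLogger("paralogdiverge")


@dataclass
class ERCResult:
    pair: tuple[str, str]
    erc: float          # NaN when undefined (zero variance, too few branches)
    n_branches: int
    empirical_p: float | None = None
    null_size: int | None = None


def winsorize(values: Sequence[float]) -> np.ndarray:
    """Limit the two most extreme values in each tail to the third.

    Applied per tail by rank: everything above the third-largest value is
    set to it, everything below the third-smallest likewise.  Vectors
    with fewer than three distinct finite values pass through unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    vals = x[finite]
    if np.unique(vals).size < 3:
        return x
    srt = np.sort(vals)
    lo, hi = srt[2], srt[-3]
    x[finite] = np.clip(vals, lo, hi)
    return x


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    su = float(u @ u)
    sv = float(v @ v)
    if su == 0.0 or sv == 0.0:
        return float("nan")
    return float(u @ v) / math.sqrt(su * sv)


def erc_pair(a: RERProfile, b: RERProfile, min_branches: int = 10) -> ERCResult:
    """Winsorized Pearson ERC of two profiles over their shared branches."""
    if a.branches == b.branches:
        u, v = a.residuals, b.residuals
        n = len(u)
    else:
        shared = sorted(set(a.branches) & set(b.branches),
                        key=lambda s: tuple(sorted(s)))
        n = len(shared)
        if n < min_branches:
            raise InsufficientDataError(
                f"pair ({a.gene}, {b.gene}): {n} shared branches < {min_branches}")
        da, db = a.as_dict(), b.as_dict()
        u = np.array([da[s] for s in shared])
        v = np.array([db[s] for s in shared])
    if n < min_branches:
        raise InsufficientDataError(
            f"pair ({a.gene}, {b.gene}): {n} shared branches < {min_branches}")
    r = _pearson(winsorize(u), winsorize(v))
    if math.isnan(r):
        logger.info("ERC undefined for (%s, %s): zero variance after "
                    "Winsorization", a.gene, b.gene)
    return ERCResult(pair=(a.gene, b.gene), erc=r, n_branches=n)


def empirical_p(a: RERProfile, b: RERProfile,
                reference_profiles: Iterable[RERProfile],
                min_branches: int = 10) -> ERCResult:
    """ERC of a pair with an empirical p-value from a reference panel.

    The null distribution pools the ERC of each focal member against
    every reference profile; ``p = (1 + #{null >= observed}) / (1 + m)``
    with ``m`` the null size (one-sided: elevated covariation).
    """
    obs = erc_pair(a, b, min_branches=min_branches)
    null: list[float] = []
    for ref in reference_profiles:
        if ref.gene in (a.gene, b.gene):
            continue
        for focal in (a, b):
            try:
                r = erc_pair(focal, ref, min_branches=min_branches).erc
            except InsufficientDataError:
                continue
            if not math.isnan(r):
                null.append(r)
    m = len(null)
    if m < 50:
        logger.warning("empirical null for (%s, %s) has only %d values",
                       a.gene, b.gene, m)
    if m == 0 or math.isnan(obs.erc):
        return ERCResult(obs.pair, obs.erc, obs.n_branches, None, m)
    p = (1 + sum(1 for r in null if r >= obs.erc)) / (1 + m)
    return ERCResult(obs.pair, obs.erc, obs.n_branches, p, m)


def _winsorized_standardized_matrix(profiles: Sequence[RERProfile]) -> np.ndarray:
    """Rows = winsorized, mean-centred, unit-norm RER vectors.

    Requires all profiles to share an identical branch tuple (the common
    case when every gene is observed in every taxon); rows with zero
    variance become all-NaN.
    """
    mat = np.vstack([winsorize(p.residuals) for p in profiles])
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norms > 0, mat / norms, np.nan)


def empirical_p_panel(pairs: Sequence[tuple[RERProfile, RERProfile]],
                      reference_profiles: Sequence[RERProfile]) -> list[ERCResult]:
    """Vectorized :func:`empirical_p` for many pairs sharing one branch set.

    All focal and reference profiles must carry the same branch tuple.
    Intended for simulation studies where thousands of pairs are ranked
    against one panel.
    """
    refs = list(reference_profiles)
    branch_sets = {p.branches for a, b in pairs for p in (a, b)}
    branch_sets.update(r.branches for r in refs)
    if len(branch_sets) != 1:
        raise ValueError("empirical_p_panel requires identical branch sets; "
                         "use empirical_p for ragged profiles")
    ref_mat = _winsorized_standardized_matrix(refs)
    out: list[ERCResult] = []
    for a, b in pairs:
        fa, fb = _winsorized_standardized_matrix([a, b])
        obs = float(fa @ fb) if not (np.isnan(fa).any() or np.isnan(fb).any()) \
            else float("nan")
        null = ref_mat @ np.vstack([fa, fb]).T  # (n_ref, 2)
        null = null[np.isfinite(null)]
        m = null.size
        if m == 0 or math.isnan(obs):
            out.append(ERCResult((a.gene, b.gene), obs, len(a.branches), None, m))
            continue
        p = (1 + int((null >= obs).sum())) / (1 + m)
        out.append(ERCResult((a.gene, b.gene), obs, len(a.branches), p, m))
    return out


def erc_matrix(profiles: Sequence[RERProfile],
               reference_profiles: Sequence[RERProfile] | None = None,
               min_branches: int = 10) -> pd.DataFrame:
    """Symmetric pairwise ERC matrix (diagonal 1 by convention).

    When ``reference_profiles`` is given, the returned frame keeps ERC
    above the diagonal and empirical p-values below it, mirroring the
    usual presentation of domain-level ERC matrices; otherwise both
    triangles hold ERC.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("need at least 2 profiles")
    names = [p.gene for p in profiles]
    k = len(profiles)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                if reference_profiles is not None:
                    res = empirical_p(profiles[i], profiles[j],
                                      reference_profiles,
                                      min_branches=min_branches)
                    mat[i, j] = res.erc
                    mat[j, i] = res.empirical_p if res.empirical_p is not None \
                        else np.nan
                else:
                    res = erc_pair(profiles[i], profiles[j],
                                   min_branches=min_branches)
                    mat[i, j] = mat[j, i] = res.erc
            except InsufficientDataError:
                continue
    return pd.DataFrame(mat, index=names, columns=names)
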