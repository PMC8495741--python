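"""Fluctuation-assay mutation rates by the method of the median.

In a Luria-Delbruck fluctuation experiment, parallel cultures grown from
small mutant-free inocula accumulate mutants in jackpot-skewed numbers.
The method of the median estimates the mutation rate ``mu`` (mutations
per cell per generation) from the median reversion frequency ``f`` and
the number of cells ``N`` per culture through the implicit equation

    mu = f / ln(N * mu)

solved on its increasing branch (``N * mu > 1``).  Nonparametric 95%
confidence intervals come from binomial order-statistic ranks on the
per-culture rates; strains are compared with the Mann-Whitney U test and
reported as rate ratios relative to a reference (wild-type) strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, NoRootError, ValidationError
from .tables import CultureTable


@dataclass
class RateEstimate:
    strain: str
    mu: float
    f: float             # median reversion frequency
    N: float             # representative (median) viable count
    ci_low: float        # NaN when undefined
    ci_high: float
    n_cultures: int
    flags: list[str] = field(default_factory=list)


def solve_drake(f: float, N: float) -> float:
    """Solve ``mu * ln(N * mu) = f`` for mu on the increasing branch.

    ``f = 0`` returns 0 (no revertants observed).  For ``0 < f <= e/N``
    no admissible root with ``N * mu > 1`` exists and
    :class:`NoRootError` is raised.
    """
    if N <= 0:
        raise ValidationError("N must be positive")
    if f < 0:
        raise ValidationError("frequency must be non-negative")
    if f == 0:
        return 0.0
    if f <= math.e / N:
        raise NoRootError(f"f={f:g} <= e/N={math.e / N:g}: no root with N*mu > 1")

    def g(mu: float) -> float:
        return mu * math.log(N * mu) - f

    lo = math.e / N          # g(lo) = e/N - f < 0
    hi = max(f, 2 * lo)
    while g(hi) < 0:
        hi *= 2
    return float(optimize.brentq(g, lo, hi, rtol=1e-12, xtol=1e-300))


def ci95_median(sorted_rates, n: int) -> tuple[float, float]:
    """Nonparametric 95% CI on the median via order-statistic ranks.

    Ranks are ``floor((n - 1.96*sqrt(n)) / 2)`` and
    ``ceil(1 + (n + 1.96*sqrt(n)) / 2)`` (1-based), clamped to [1, n].
    Requires ``n >= 6``; the returned interval is the pair of order
    statistics at those ranks.
    """
    if n < 6:
        raise InsufficientDataError(f"CI undefined for n={n} < 6")
    rates = np.asarray(sorted_rates, dtype=float)
    if rates.size != n:
        raise ValidationError("length of sorted rates must equal n")
    half = 1.96 * math.sqrt(n)
    lo_rank = max(1, math.floor((n - half) / 2))
    hi_rank = min(n, math.ceil(1 + (n + half) / 2))
    return float(rates[lo_rank - 1]), float(rates[hi_rank - 1])


def per_culture_rates(revertants, viable) -> tuple[np.ndarray, float, list[str]]:
    """Per-culture rate estimates sharing one representative N.

    Each culture's frequency ``f_i = r_i / N_i`` is converted to a rate
    with the median viable count as the common N, so the order of rates
    follows the order of frequencies exactly.  Frequencies at or below
    the detection floor ``e/N`` yield rate 0 (flagged).
    """
    r = np.asarray(revertants, dtype=float)
    Nv = np.asarray(viable, dtype=float)
    N = float(np.median(Nv))
    flags: list[str] = []
    rates = np.zeros_like(r)
    for i, fi in enumerate(r / Nv):
        if fi == 0:
            continue
        try:
            rates[i] = solve_drake(fi, N)
        except NoRootError:
            flags.append("culture below detection floor")
            rates[i] = 0.0
    return rates, N, flags


def estimate_rate(table: CultureTable | pd.DataFrame,
                  strain: str | None = None) -> RateEstimate:
    """Method-of-the-median rate estimate for one strain's cultures.

    Invariant to culture ordering and batch labels.  Requires at least
    5 cultures; the CI additionally requires 6.
    """
    if isinstance(table, CultureTable):
        df = table.for_strain(strain) if strain is not None else table.data
    else:
        df = table
    if strain is None:
        strains = df["strain"].unique()
        if len(strains) != 1:
            raise ValidationError("multiple strains present; pass strain=")
        strain = str(strains[0])
    n = len(df)
    if n < 5:
        raise InsufficientDataError(f"{strain}: {n} cultures < 5")

    r = df["revertants"].to_numpy(dtype=float)
    Nv = df["viable"].to_numpy(dtype=float)
    f = float(np.median(r / Nv))
    N = float(np.median(Nv))
    flags: list[str] = []
    if np.all(r == 0):
        mu = 0.0
        flags.append("no revertants")
    else:
        try:
            mu = solve_drake(f, N)
        except NoRootError:
            mu = 0.0
            flags.append("median frequency below detection floor")
        if f == 0:
            flags.append("no revertants in median culture")

    rates, _, rate_flags = per_culture_rates(r, Nv)
    flags.extend(sorted(set(rate_flags)))
    try:
        ci_low, ci_high = ci95_median(np.sort(rates), n)
    except InsufficientDataError:
        ci_low = ci_high = float("nan")
        flags.append("CI undefined (n < 6)")
    return RateEstimate(strain=strain, mu=mu, f=f, N=N, ci_low=ci_low,
                        ci_high=ci_high, n_cultures=n, flags=flags)


def mann_whitney(rates_a, rates_b) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact enumeration when the smaller sample has <= 8 observations and
    there are no ties; continuity-corrected normal approximation with
    tie correction otherwise.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures, ties half-to-even."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


def relative_rate(mu_strain: float, mu_reference: float) -> tuple[float, float]:
    """Rate ratio vs. a reference strain: (raw, 3-significant-figure).

    The rounded value uses half-to-even rounding; the raw ratio is kept
    because published tables round from unrounded intermediates.
    """
    if mu_reference <= 0:
        raise ValidationError("reference rate must be positive")
    raw = mu_strain / mu_reference
    return raw, round_sig(raw, 3)


def analyze_culture_table(table: CultureTable,
                          reference_strain: str) -> pd.DataFrame:
    """Per-strain rates, CIs, relative rates and Mann-Whitney p-values.

    The comparison sample for the U test is the per-culture rate vector
    of each strain against the reference strain's.
    """
    if reference_strain not in table.strains():
        raise ValidationError(f"reference strain {reference_strain!r} absent")
    ref_est = estimate_rate(table, reference_strain)
    ref_df = table.for_strain(reference_strain)
    ref_rates, _, _ = per_culture_rates(ref_df["revertants"], ref_df["viable"])
    rows = []
    for strain in table.strains():
        est = estimate_rate(table, strain)
        df = table.for_strain(strain)
        rates, _, _ = per_culture_rates(df["revertants"], df["viable"])
        if strain == reference_strain:
            rel_raw, rel = 1.0, 1.0
            p = float("nan")
        else:
            rel_raw, rel = relative_rate(est.mu, ref_est.mu)
            _, p = mann_whitney(rates, ref_rates)
        rows.append({
            "strain": strain, "n": est.n_cultures, "mu": est.mu,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "relative_to_reference": rel, "relative_raw": rel_raw,
            "mann_whitney_p_vs_reference": p,
            "flags": ";".join(est.flags),
        })
    return pd.DataFrame(rows)
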