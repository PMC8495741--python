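"""Meiotic crossover classification from tetrad counts.

The spore-autonomous fluorescence assay scores each tetrad in a
two-marker interval as parental ditype (PD, no crossover) or tetratype
(TT, single crossover); the crossover readout is the percent tetratype
``100 * TT / (TT + PD)``.  Each genotype is compared against both a
wild-type and a null reference by a Pearson chi-squared contingency test
(no continuity correction), the two p-values per genotype enter one
Benjamini-Hochberg family at a 5% false discovery rate, and the pattern
of significant differences yields a three-way call:

* ``+``   indistinguishable from wild type (significant vs. null only);
* ``-``   indistinguishable from the null (significant vs. wild type only);
* ``+/-`` distinguishable from both;
* ``indeterminate`` distinguishable from neither (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables import TetradTable

logger = logging.getLogger("paralogdiverge")


def percent_tetratype(tt: int, pd_count: int) -> float:
    """Percent tetratype, reported to one decimal."""
    if tt < 0 or pd_count < 0:
        raise ValidationError("negative tetrad count")
    n = tt + pd_count
    if n == 0:
        raise ValidationError("no tetrads scored")
    return round(100.0 * tt / n, 1)


def chi2_2x2(tt1: int, pd1: int, tt2: int, pd2: int,
             continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 TT/PD table (1 df).

    No continuity correction by default; set ``continuity=True`` for the
    Yates-corrected variant.  Empty margins raise.
    """
    table = np.array([[tt1, pd1], [tt2, pd2]], dtype=float)
    if (table < 0).any():
        raise ValidationError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("empty margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at FDR ``q``.

    Returns the significance mask and the cutoff (largest significant
    raw p; NaN when nothing is significant or the input is empty).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else float("nan")
    return reject, cutoff


@dataclass
class CrossoverCall:
    genotype: str
    percent_tt: float
    p_vs_wt: float
    p_vs_null: float
    sig_vs_wt: bool
    sig_vs_null: bool
    call: str  # one of {+, -, +/-, indeterminate}


def classify_allele(genotype: str, percent_tt: float, p_vs_wt: float,
                    p_vs_null: float, sig_vs_wt: bool,
                    sig_vs_null: bool) -> CrossoverCall:
    """Three-way call from BH-adjusted significance against both references."""
    if sig_vs_wt and sig_vs_null:
        call = "+/-"
    elif sig_vs_null:
        call = "+"
    elif sig_vs_wt:
        call = "-"
    else:
        call = "indeterminate"
        logger.info("genotype %s distinguishable from neither reference",
                    genotype)
    return CrossoverCall(genotype, percent_tt, p_vs_wt, p_vs_null,
                         sig_vs_wt, sig_vs_null, call)


def classify_table(table: TetradTable, wt: str, null: str,
                   q: float = 0.05) -> pd.DataFrame:
    """Classify every non-reference genotype in a tetrad table.

    Both p-values of every genotype enter a single BH family; the
    references themselves are reported with their percent tetratype but
    no call.
    """
    for name in (wt, null):
        table.counts(name)  # raises KeyError if absent
    genotypes = [g for g in table.data["genotype"].unique()
                 if g not in (wt, null)]
    wt_tt, wt_pd = table.counts(wt)
    null_tt, null_pd = table.counts(null)
    pvals, stats_rows = [], []
    for g in genotypes:
        tt, pdc = table.counts(g)
        _, p_wt = chi2_2x2(tt, pdc, wt_tt, wt_pd)
        _, p_null = chi2_2x2(tt, pdc, null_tt, null_pd)
        pvals.extend([p_wt, p_null])
        stats_rows.append((g, tt, pdc, p_wt, p_null))
    mask, cutoff = bh_adjust(pvals, q=q)
    rows = []
    for i, (g, tt, pdc, p_wt, p_null) in enumerate(stats_rows):
        call = classify_allele(g, percent_tetratype(tt, pdc), p_wt, p_null,
                               bool(mask[2 * i]), bool(mask[2 * i + 1]))
        rows.append({
            "genotype": g, "TT": tt, "PD": pdc,
            "percent_tt": call.percent_tt,
            "p_vs_wt": p_wt, "p_vs_null": p_null,
            "bh_sig_vs_wt": call.sig_vs_wt, "bh_sig_vs_null": call.sig_vs_null,
            "call": call.call,
        })
    for name, (tt, pdc) in ((wt, (wt_tt, wt_pd)), (null, (null_tt, null_pd))):
        rows.append({
            "genotype": name, "TT": tt, "PD": pdc,
            "percent_tt": percent_tetratype(tt, pdc),
            "p_vs_wt": float("nan"), "p_vs_null": float("nan"),
            "bh_sig_vs_wt": False, "bh_sig_vs_null": False,
            "call": "reference",
        })
    df = pd.DataFrame(rows)
    df.attrs["bh_cutoff"] = cutoff
    df.attrs["bh_family_size"] = len(pvals)
    return df
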