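"""Specificity-determining positions between two paralog subfamilies.

Columns of a two-group alignment are scored two ways:

* **sequence harmony** (``sh``): 1 minus the Jensen-Shannon divergence
  (base-2 logs, equal weights) between the two groups' residue
  distributions at the column.  Identical distributions score 1,
  disjoint distributions score 0 — *low* harmony marks group-specific
  columns.
* **multi-relief** (``mr``): a two-group RELIEF weight.  Repeatedly
  sample a sequence, find its nearest hit (same group) and nearest miss
  (other group) by Hamming distance over unmasked columns, and credit a
  column when the miss differs there but penalize it when the hit does;
  the averaged weight lies in [-1, 1] and *high* values mark
  group-separating columns.

Candidate positions combine both scores (``mr > 0.8`` and ``sh < 0.5``
by default), are mapped to 1-based ungapped residue numbers in each
paralog, and grouped into linear-proximity blocks as a sequence-space
proxy for clusters on the folded structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignments import AMINO_ACIDS, SubfamilyAlignment, ungapped_index
from .errors import ValidationError


def column_masks(aln: SubfamilyAlignment,
                 max_group_gap_frac: float = 0.5) -> np.ndarray:
    """True for columns excluded from scoring.

    A column is masked when either group is more than
    ``max_group_gap_frac`` gapped (entirely gapped groups included).
    """
    gaps = aln.is_gap_matrix()
    masked = np.zeros(aln.length, dtype=bool)
    for label in ("A", "B"):
        rows = aln.group_rows(label)
        frac = gaps[rows].mean(axis=0)
        masked |= frac > max_group_gap_frac
    return masked


def _group_frequencies(aln: SubfamilyAlignment, label: str) -> np.ndarray:
    """(20, L) residue frequencies per column, gaps excluded.

    Columns where the group is entirely gapped are all-NaN.
    """
    sub = aln.group_matrix(label)
    counts = np.stack([(sub == aa).sum(axis=0) for aa in AMINO_ACIDS]) \
        .astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals
    freqs[:, totals == 0] = np.nan
    return freqs


def _jsd_base2(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column-wise Jensen-Shannon divergence of two (20, L) distributions."""
    m = 0.5 * (p + q)

    def _kl(a, b):
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(a > 0, a * np.log2(np.where(a > 0, a, 1.0) / b), 0.0)
        return terms.sum(axis=0)

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def sequence_harmony(aln: SubfamilyAlignment,
                     max_group_gap_frac: float = 0.5) -> np.ndarray:
    """Per-column sh score in [0, 1]; NaN for masked columns."""
    sh = 1.0 - _jsd_base2(_group_frequencies(aln, "A"),
                          _group_frequencies(aln, "B"))
    sh = np.clip(sh, 0.0, 1.0)
    sh[column_masks(aln, max_group_gap_frac)] = np.nan
    return sh


def multi_relief(aln: SubfamilyAlignment, iterations: int = 10_000,
                 seed: int = 0,
                 max_group_gap_frac: float = 0.5) -> np.ndarray:
    """Per-column RELIEF weights in [-1, 1]; NaN for masked columns.

    Deterministic for a fixed ``seed``; equidistant hits/misses are
    broken uniformly at random.  Each group needs at least two
    sequences, otherwise no hit exists for its members.
    """
    for label in ("A", "B"):
        if aln.group_rows(label).size < 2:
            raise ValidationError(
                f"group {label} has fewer than 2 sequences; no hit available")
    masked = column_masks(aln, max_group_gap_frac)
    active = ~masked
    mat = aln.matrix
    n = aln.n_sequences
    labels = np.asarray(aln.group_labels)

    # Pairwise Hamming distances over unmasked columns (gap is a symbol).
    sub = mat[:, active]
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        dist[i] = (sub != sub[i]).sum(axis=1)

    rng = np.random.default_rng(seed)
    acc = np.zeros(aln.length, dtype=np.int64)
    samples = rng.integers(0, n, size=iterations)
    for s in samples:
        same = labels == labels[s]
        hits = np.flatnonzero(same)
        hits = hits[hits != s]
        misses = np.flatnonzero(~same)
        h_d = dist[s, hits]
        m_d = dist[s, misses]
        hit = rng.choice(hits[h_d == h_d.min()])
        miss = rng.choice(misses[m_d == m_d.min()])
        acc += (mat[miss] != mat[s]).astype(np.int64)
        acc -= (mat[hit] != mat[s]).astype(np.int64)
    weights = np.clip(acc / iterations, -1.0, 1.0)
    weights[masked] = np.nan
    return weights


def score_columns(aln: SubfamilyAlignment, iterations: int = 10_000,
                  seed: int = 0, mr_cut: float = 0.8, sh_cut: float = 0.5,
                  max_group_gap_frac: float = 0.5) -> pd.DataFrame:
    """Score all columns; returns a frame indexed by 1-based column."""
    masked = column_masks(aln, max_group_gap_frac)
    sh = sequence_harmony(aln, max_group_gap_frac)
    mr = multi_relief(aln, iterations=iterations, seed=seed,
                      max_group_gap_frac=max_group_gap_frac)
    gaps = aln.is_gap_matrix()
    cov_a = 1.0 - gaps[aln.group_rows("A")].mean(axis=0)
    cov_b = 1.0 - gaps[aln.group_rows("B")].mean(axis=0)
    df = pd.DataFrame({
        "column": np.arange(1, aln.length + 1),
        "sh": sh,
        "mr": mr,
        "coverage_a": cov_a,
        "coverage_b": cov_b,
        "masked": masked,
    })
    df["selected"] = (~df["masked"]) & (df["mr"] > mr_cut) & (df["sh"] < sh_cut)
    return df


def select_positions(scores: pd.DataFrame, mr_cut: float = 0.8,
                     sh_cut: float = 0.5) -> list[int]:
    """1-based columns passing the dual cutoff, unmasked only."""
    keep = (~scores["masked"]) & (scores["mr"] > mr_cut) & (scores["sh"] < sh_cut)
    return [int(c) for c in scores.loc[keep.fillna(False), "column"]]


def map_to_paralog_coordinates(aln: SubfamilyAlignment, columns,
                               member_id: str) -> dict[int, int | None]:
    """1-based ungapped residue numbers of ``columns`` in one sequence.

    Columns gapped in that sequence map to ``None`` (absent).
    """
    row = aln.row(member_id)
    return {int(c): ungapped_index(row, int(c)) for c in columns}


def group_into_blocks(positions, block_gap: int = 15) -> list[list[int]]:
    """Maximal runs of sorted positions with successive gaps <= block_gap."""
    positions = sorted(int(p) for p in positions)
    blocks: list[list[int]] = []
    for p in positions:
        if blocks and p - blocks[-1][-1] <= block_gap:
            blocks[-1].append(p)
        else:
            blocks.append([p])
    return blocks


@dataclass
class SpecificityBlock:
    """A linear cluster of candidate positions in both paralogs' coordinates."""

    positions_a: list[int]
    positions_b: list[int | None]
    span: tuple[int, int]  # first..last residue in paralog-A coordinates


def blocks_from_columns(aln: SubfamilyAlignment, columns, member_a: str,
                        member_b: str,
                        block_gap: int = 15) -> list[SpecificityBlock]:
    """Group selected alignment columns into blocks along paralog A.

    Columns gapped in ``member_a`` carry no A-coordinate and are dropped;
    the matching position in ``member_b`` is reported alongside
    (``None`` where B is gapped).
    """
    a_map = map_to_paralog_coordinates(aln, columns, member_a)
    b_map = map_to_paralog_coordinates(aln, columns, member_b)
    pos_to_b = {a_map[c]: b_map[c] for c in a_map if a_map[c] is not None}
    out = []
    for run in group_into_blocks(pos_to_b, block_gap):
        out.append(SpecificityBlock(
            positions_a=run,
            positions_b=[pos_to_b[p] for p in run],
            span=(run[0], run[-1])))
    return out


def conserved_column_filter(aln: SubfamilyAlignment, max_gap_frac: float = 0.5,
                            min_conservation: float = 0.5) -> list[int]:
    """Simplified conserved-block column selection (1-based columns).

    Retains columns that (1) have gap fraction <= ``max_gap_frac``,
    (2) are not adjacent to a column exceeding it, and (3) have a
    majority residue at frequency >= ``min_conservation`` among non-gap
    symbols.  This is a linear stand-in for full conserved-block
    trimming of divergent alignments.
    """
    gaps = aln.is_gap_matrix()
    gap_frac = gaps.mean(axis=0)
    gappy = gap_frac > max_gap_frac
    near_gappy = gappy.copy()
    near_gappy[:-1] |= gappy[1:]
    near_gappy[1:] |= gappy[:-1]

    counts = np.stack([(aln.matrix == aa).sum(axis=0) for aa in AMINO_ACIDS])
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        majority = np.where(totals > 0, counts.max(axis=0) / totals, 0.0)

    keep = (~gappy) & (~near_gappy) & (majority >= min_conservation)
    return [int(i + 1) for i in np.flatnonzero(keep)]
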