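"""Sequence-harmony / multi-relief scoring and position mapping."""

import math

import numpy as np
import pytest

from paralogdiverge.datasets import DOMAIN_BOUNDARIES
from paralogdiverge.errors import ValidationError
from paralogdiverge.simulate import SimulationConfig, \
    simulate_paralog_alignment
from paralogdiverge.specificity import (blocks_from_columns, column_masks,
                                        conserved_column_filter,
                                        group_into_blocks,
                                        map_to_paralog_coordinates,
                                        multi_relief, score_columns,
                                        select_positions, sequence_harmony)

from conftest import make_alignment


def oracle_jsd_sh(col_a, col_b):
    """Direct-summation sequence harmony for one column (gaps excluded)."""
    def dist(col):
        res = [c for c in col if c != "-"]
        return {aa: res.count(aa) / len(res) for aa in set(res)}

    p, q = dist(col_a), dist(col_b)
    support = set(p) | set(q)
    jsd = 0.0
    for aa in support:
        pa, qa = p.get(aa, 0.0), q.get(aa, 0.0)
        m = (pa + qa) / 2
        if pa > 0:
            jsd += 0.5 * pa * math.log2(pa / m)
        if qa > 0:
            jsd += 0.5 * qa * math.log2(qa / m)
    return 1.0 - jsd


def oracle_mr_expectation(aln):
    """Exhaustive enumeration over (sampled sequence, hit tie-set,
    miss tie-set) of the expected multi-relief weight per column."""
    mat = aln.matrix
    labels = np.asarray(aln.group_labels)
    masked = column_masks(aln)
    n = mat.shape[0]
    sub = mat[:, ~masked]
    dist = np.array([[(sub[i] != sub[j]).sum() for j in range(n)]
                     for i in range(n)])
    exp = np.zeros(mat.shape[1])
    for s in range(n):
        same = labels == labels[s]
        hits = [i for i in np.flatnonzero(same) if i != s]
        misses = list(np.flatnonzero(~same))
        hmin = min(dist[s][i] for i in hits)
        mmin = min(dist[s][i] for i in misses)
        h_ties = [i for i in hits if dist[s][i] == hmin]
        m_ties = [i for i in misses if dist[s][i] == mmin]
        miss_term = np.mean([(mat[m] != mat[s]).astype(float)
                             for m in m_ties], axis=0)
        hit_term = np.mean([(mat[h] != mat[s]).astype(float)
                            for h in h_ties], axis=0)
        exp += miss_term - hit_term
    exp /= n
    exp[masked] = np.nan
    return exp


class TestSequenceHarmony:
    def test_disjoint_residues_score_zero(self):
        aln = make_alignment(["K"] * 4, ["T"] * 4)
        assert sequence_harmony(aln)[0] == pytest.approx(0.0)

    def test_identical_distributions_score_one(self):
        aln = make_alignment(["K", "K", "T", "T"], ["K", "K", "T", "T"])
        assert sequence_harmony(aln)[0] == pytest.approx(1.0)

    def test_partial_overlap_matches_summation_oracle(self):
        col_a, col_b = ["K"] * 6, ["K", "K", "K", "T", "T", "T"]
        aln = make_alignment(col_a, col_b)
        assert sequence_harmony(aln)[0] == \
            pytest.approx(oracle_jsd_sh(col_a, col_b), abs=1e-12)

    def test_symmetric_in_groups_and_within_group_permutation(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("KTRAG"), size=12)) for _ in range(10)]
        a, b = seqs[:5], seqs[5:]
        sh_ab = sequence_harmony(make_alignment(a, b))
        sh_ba = sequence_harmony(make_alignment(b, a))
        sh_perm = sequence_harmony(make_alignment(a[::-1], b))
        assert np.allclose(sh_ab, sh_ba, equal_nan=True)
        assert np.allclose(sh_ab, sh_perm, equal_nan=True)

    def test_fully_gapped_group_is_masked(self):
        aln = make_alignment(["-A", "-A"], ["KA", "TA"])
        sh = sequence_harmony(aln)
        assert math.isnan(sh[0])
        assert not math.isnan(sh[1])


class TestMultiRelief:
    def test_perfectly_separating_column_scores_one(self, toy_separating_alignment):
        mr = multi_relief(toy_separating_alignment, iterations=500, seed=0)
        assert mr[0] == pytest.approx(1.0)

    def test_constant_column_scores_zero(self, toy_separating_alignment):
        mr = multi_relief(toy_separating_alignment, iterations=500, seed=0)
        assert mr[1] == pytest.approx(0.0)

    def test_deterministic_for_fixed_seed(self, toy_separating_alignment):
        a = multi_relief(toy_separating_alignment, iterations=200, seed=5)
        b = multi_relief(toy_separating_alignment, iterations=200, seed=5)
        assert (a == b).all()

    def test_singleton_group_rejected(self):
        aln = make_alignment(["KA"], ["TA", "TG"])
        with pytest.raises(ValidationError):
            multi_relief(aln, iterations=10, seed=0)

    def test_sampled_weights_match_enumeration(self, toy_separating_alignment):
        exp = oracle_mr_expectation(toy_separating_alignment)
        got = multi_relief(toy_separating_alignment, iterations=10_000, seed=1)
        assert np.allclose(got, exp, atol=0.02, equal_nan=True)

    def test_enumeration_matches_on_random_small_alignments(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            n_a, n_b = rng.integers(2, 6, size=2)
            seqs = ["".join(rng.choice(list("KTRA"), size=8))
                    for _ in range(n_a + n_b)]
            aln = make_alignment(seqs[:n_a], seqs[n_a:])
            exp = oracle_mr_expectation(aln)
            got = multi_relief(aln, iterations=20_000, seed=trial)
            # 3-sigma Monte-Carlo envelope (per-draw contributions in [-1,1])
            assert np.allclose(got, exp, atol=3 / np.sqrt(20_000) * 1.5,
                               equal_nan=True)


class TestSelection:
    def test_dual_cutoff_rule(self):
        import pandas as pd
        scores = pd.DataFrame({
            "column": [1, 2, 3],
            "sh": [0.3, 0.7, 0.3],
            "mr": [0.9, 0.9, 0.5],
            "masked": [False, False, False],
        })
        assert select_positions(scores) == [1]

    def test_planted_columns_recovered(self):
        planted = simulate_paralog_alignment(SimulationConfig(seed=2))
        scores = score_columns(planted.alignment, iterations=10_000, seed=2)
        sel = set(select_positions(scores))
        truth = set(planted.specificity_columns)
        assert len(sel & truth) >= 9
        assert len(sel - truth) <= 2

    def test_null_alignments_yield_no_selections(self):
        """At the assay's subfamily sizes (29 + 34), alignments with no
        group structure essentially never pass the dual cutoff."""
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, length=150,
                                   n_specificity_columns=0)
            aln = simulate_paralog_alignment(cfg).alignment
            scores = score_columns(aln, iterations=1500, seed=seed)
            clean += len(select_positions(scores)) == 0
        assert clean >= 0.95 * n_seeds


class TestCoordinateMapping:
    def test_basic_mapping(self):
        aln = make_alignment(["MAK", "-AK"], ["MAK", "MAK"])
        assert map_to_paralog_coordinates(aln, [1, 3], "A0") == {1: 1, 3: 3}
        assert map_to_paralog_coordinates(aln, [1, 3], "A1") == {1: None, 3: 2}

    def test_unknown_member_rejected(self):
        aln = make_alignment(["MA"], ["MA", "MT"])
        with pytest.raises(KeyError):
            map_to_paralog_coordinates(aln, [1], "nope")

    def test_mapped_positions_respect_domain_partition(self):
        """Ungapped residue numbers of selected columns fall into the
        Mlh3 domain spans (ATP-binding 1-375, linker 376-488,
        endonuclease 489-715) consistently with their alignment order."""
        rng = np.random.default_rng(0)
        length = 715
        mlh3 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        other = mlh3[:100] + "-" * 30 + mlh3[130:]
        aln = make_alignment([mlh3, mlh3], [other, other])
        columns = [17, 400, 500, 700]
        mapped = map_to_paralog_coordinates(aln, columns, "A0")
        domains = DOMAIN_BOUNDARIES["Mlh3"]
        expected = ["atp_binding", "linker", "endonuclease", "endonuclease"]
        for col, dom in zip(columns, expected):
            lo, hi = domains[dom]
            assert lo <= mapped[col] <= hi


class TestBlocks:
    def test_clustered_positions_form_one_block(self):
        blocks = group_into_blocks([17, 20, 24, 30, 34], block_gap=15)
        assert blocks == [[17, 20, 24, 30, 34]]

    def test_distant_positions_form_singletons(self):
        assert group_into_blocks([10, 200]) == [[10], [200]]

    def test_empty_input(self):
        assert group_into_blocks([]) == []

    def test_blocks_carry_both_coordinate_systems(self):
        aln = make_alignment(["MAKRW", "MAKRW"], ["M-KRW", "M-KRW"])
        blocks = blocks_from_columns(aln, [1, 2, 4], "A0", "B0", block_gap=15)
        assert len(blocks) == 1
        assert blocks[0].positions_a == [1, 2, 4]
        assert blocks[0].positions_b == [1, None, 3]
        assert blocks[0].span == (1, 4)


class TestConservedColumnFilter:
    def test_clean_alignment_fully_retained(self):
        aln = make_alignment(["MAKR", "MAKR"], ["MAKR", "MAKR"])
        assert conserved_column_filter(aln) == [1, 2, 3, 4]

    def test_gappy_column_and_neighbors_dropped(self):
        aln = make_alignment(["MAKRW", "M-KRW", "M-KRW"],
                             ["M-KRW", "MAKRW"])
        # column 2 is 60% gapped at max_gap_frac 0.5
        kept = conserved_column_filter(aln, max_gap_frac=0.5)
        assert 2 not in kept and 1 not in kept and 3 not in kept
        assert {4, 5} <= set(kept)

    def test_matches_rule_by_rule_oracle(self):
        cfg = SimulationConfig(seed=6, group_sizes=(5, 5), length=100,
                               n_specificity_columns=0,
                               background_conservation=0.6)
        aln = simulate_paralog_alignment(cfg).alignment
        # inject gap runs
        aln.matrix[0:4, 10:13] = "-"
        aln.matrix[2:9, 50] = "-"
        max_gap, min_cons = 0.3, 0.5
        got = conserved_column_filter(aln, max_gap, min_cons)
        expected = []
        n, L = aln.matrix.shape
        gap_frac = [sum(c not in "ACDEFGHIKLMNPQRSTVWY"
                        for c in aln.matrix[:, j]) / n for j in range(L)]
        for j in range(L):
            if gap_frac[j] > max_gap:
                continue
            if j > 0 and gap_frac[j - 1] > max_gap:
                continue
            if j < L - 1 and gap_frac[j + 1] > max_gap:
                continue
            residues = [c for c in aln.matrix[:, j]
                        if c in "ACDEFGHIKLMNPQRSTVWY"]
            top = max(residues.count(a) for a in set(residues))
            if top / len(residues) >= min_cons:
                expected.append(j + 1)
        assert got == expected
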