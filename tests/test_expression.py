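import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import make_count_matrix
from oracles import bh_oracle, conditional_binomial_p
from unigene.expression import (
    ExpressionTable,
    bh_adjust,
    call_de,
    call_specific,
    coexpression,
    compute_fpkm,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_nb_test,
    top_abundant,
)
from unigene.io import CountMatrix
from unigene.simulate import FixtureConfig, TruthTable, simulate_counts


class TestComputeFpkm:
    def test_closed_form(self):
        m = make_count_matrix([[10], [999_990]])
        table = compute_fpkm(m, {"t1": 2000, "t2": 1000})
        assert table.fpkm.iloc[0, 0] == pytest.approx(5.0)

    def test_zero_count_zero_fpkm(self):
        m = make_count_matrix([[0], [5]])
        table = compute_fpkm(m, {"t1": 500, "t2": 500})
        assert table.fpkm.iloc[0, 0] == 0.0

    def test_scale_invariance(self, rng):
        counts = rng.integers(1, 100, size=(20, 3)).astype(float)
        lengths = {f"t{i + 1}": int(L) for i, L in enumerate(rng.integers(200, 3000, 20))}
        t1 = compute_fpkm(make_count_matrix(counts), lengths)
        t2 = compute_fpkm(make_count_matrix(counts * 2), lengths)
        np.testing.assert_allclose(t1.fpkm.values, t2.fpkm.values)

    def test_identity_on_random_matrices(self, rng):
        counts = rng.integers(0, 500, size=(30, 4)).astype(float)
        counts[0, :] += 1  # keep library sizes positive
        lengths = {f"t{i + 1}": int(L) for i, L in enumerate(rng.integers(200, 3000, 30))}
        m = make_count_matrix(counts, ["A", "A", "B", "B"])
        table = compute_fpkm(m, lengths)
        libsize = counts.sum(axis=0)
        L = np.array([lengths[f"t{i + 1}"] for i in range(30)])
        expected = counts * 1e9 / (L[:, None] * libsize[None, :])
        np.testing.assert_allclose(table.fpkm.values, expected)
        np.testing.assert_allclose(
            table.group_means["A"].values, table.fpkm.values[:, :2].mean(axis=1)
        )

    def test_zero_library_raises(self):
        m = make_count_matrix([[0], [0]])
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(m, {"t1": 100, "t2": 100})

    def test_missing_length_raises(self):
        m = make_count_matrix([[1]])
        with pytest.raises(KeyError):
            compute_fpkm(m, {})


class TestExactNbTest:
    def test_identical_groups_p_one(self):
        assert exact_nb_test([5, 5, 5], [5, 5, 5], 0.1) == pytest.approx(1.0)

    def test_all_zero_p_one(self):
        assert exact_nb_test([0], [0], 0.3) == 1.0

    def test_poisson_conditional_matches_enumeration(self):
        # a=(10), b=(0), dispersion 0: exhaustive binomial split enumeration
        assert exact_nb_test([10], [0], 0.0) == pytest.approx(conditional_binomial_p(10, 0))
        for ya, yb in [(7, 3), (2, 8), (5, 5), (12, 1)]:
            assert exact_nb_test([ya], [yb], 0.0) == pytest.approx(
                conditional_binomial_p(ya, yb)
            )

    def test_large_difference_small_p(self):
        assert exact_nb_test([200, 210, 190], [20, 25, 15], 0.05) < 1e-6

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test([1], [1], -0.1)

    def test_null_calibration(self):
        # NB null, common dispersion 0.1, 3 vs 3, 2000 transcripts
        rng = np.random.default_rng(606)
        phi, r = 0.1, 10.0
        mu = np.exp(rng.normal(np.log(100), 0.7, 2000))
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        p = np.array([exact_nb_test(row[:3], row[3:], phi) for row in counts])
        frac = (p <= 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_literal_oracle_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            got = bh_adjust(p)
            np.testing.assert_allclose(got, bh_oracle(p))
            np.testing.assert_allclose(
                got, multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    def test_monotone_in_rank_order(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEqualizeAndDispersion:
    def test_equalized_library_sizes_near_target(self, rng):
        counts = rng.integers(0, 200, size=(50, 4)).astype(float)
        counts[:, 0] *= 3  # unbalanced library
        m = make_count_matrix(counts, ["A", "A", "B", "B"])
        eq = equalize_library_sizes(m)
        target = np.exp(np.mean(np.log(m.library_sizes)))
        assert np.allclose(eq.library_sizes, target, rtol=0.02)
        assert np.allclose(eq.counts, np.rint(eq.counts))

    def test_dispersion_recovery(self):
        rng = np.random.default_rng(9)
        phi, r = 0.15, 1 / 0.15
        mu = np.exp(rng.normal(np.log(200), 0.5, 3000))
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(3000, 6))
        m = make_count_matrix(counts, ["A"] * 3 + ["B"] * 3)
        est = estimate_common_dispersion(m)
        assert 0.10 <= est <= 0.22

    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(100, size=(2000, 6))
        m = make_count_matrix(counts, ["A"] * 3 + ["B"] * 3)
        assert estimate_common_dispersion(m) < 0.02


def _de_table(rng, n=300, n_de=60, fold=10.0, phi=0.1):
    r = 1 / phi
    mu = np.exp(rng.normal(np.log(80), 0.7, n))
    mean = np.tile(mu[:, None], (1, 2))
    mean[:n_de, 1] *= fold
    counts = np.zeros((n, 6))
    for gi in range(2):
        for rep in range(3):
            counts[:, gi * 3 + rep] = rng.negative_binomial(r, r / (r + mean[:, gi]))
    m = make_count_matrix(counts, ["A"] * 3 + ["B"] * 3)
    lengths = {t: 1000 for t in m.transcript_ids}
    return compute_fpkm(m, lengths), [f"t{i + 1}" for i in range(n_de)]


class TestCallDe:
    def test_planted_fold_changes_recovered(self):
        rng = np.random.default_rng(77)
        table, planted = _de_table(rng)
        results = call_de(table, "A", "B", "auto")
        de = {r.transcript_id for r in results if r.is_de}
        assert len(de & set(planted)) / len(planted) >= 0.9

    def test_identical_groups_few_false_positives(self):
        rng = np.random.default_rng(88)
        table, _ = _de_table(rng, n=2000, n_de=0)
        results = call_de(table, "A", "B", "auto")
        assert sum(r.is_de for r in results) / len(results) <= 0.05

    def test_conjunction_of_criteria(self):
        # large fold change but no statistical support -> not DE
        counts = np.array([[1.0, 0.0, 10.0, 3.0], [100, 120, 110, 105]])
        m = make_count_matrix(counts, ["A", "A", "B", "B"])
        table = compute_fpkm(m, {"t1": 1000, "t2": 1000})
        results = call_de(table, "A", "B", 0.5)
        r1 = results[0]
        assert abs(r1.log2_fold_change) >= 0 and not r1.is_de

    def test_unknown_group_raises(self):
        m = make_count_matrix([[1, 2]], ["A", "B"])
        table = compute_fpkm(m, {"t1": 100})
        with pytest.raises(KeyError):
            call_de(table, "A", "Z")


def _table_from_group_means(values, groups=("g1", "g2", "g3", "g4")):
    df = pd.DataFrame([values], index=["t1"], columns=list(groups))
    return ExpressionTable(counts=None, effective_lengths={}, fpkm=df, group_means=df)


class TestCallSpecific:
    def test_rule_satisfied(self):
        calls = call_specific(_table_from_group_means([5.0, 0.5, 0.2, 0.9]))
        assert calls[0].specific_in == "g1"

    def test_rule_violated_not_below_lo(self):
        calls = call_specific(_table_from_group_means([5.0, 2.0, 0.2, 0.9]))
        assert calls[0].specific_in is None

    def test_strict_hi_inequality(self):
        calls = call_specific(_table_from_group_means([3.0, 0.5, 0.5, 0.5]))
        assert calls[0].specific_in is None

    def test_hi_below_lo_raises(self):
        with pytest.raises(ValueError):
            call_specific(_table_from_group_means([1, 1, 1, 1]), hi=0.5, lo=1.0)

    def test_exhaustive_grid_against_rule(self):
        grid = [0.0, 0.5, 1.0, 3.0, 3.5]
        for values in itertools.product(grid, repeat=4):
            got = call_specific(_table_from_group_means(list(values)))[0].specific_in
            expected = None
            for i in range(4):
                if values[i] > 3.0 and all(values[j] < 1.0 for j in range(4) if j != i):
                    expected = f"g{i + 1}"
                    break
            assert got == expected, values


class TestTopAbundant:
    def _table(self):
        df = pd.DataFrame(
            {"g1": [1.0, 5.0, 3.0]}, index=["t1", "t2", "t3"]
        )
        return ExpressionTable(counts=None, effective_lengths={}, fpkm=df, group_means=df)

    def test_sorting(self):
        assert top_abundant(self._table(), "g1", 2) == ["t2", "t3"]

    def test_n_larger_than_set(self):
        assert top_abundant(self._table(), "g1", 10) == ["t2", "t3", "t1"]

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame({"g1": [2.0, 2.0, 9.0]}, index=["b", "a", "c"])
        t = ExpressionTable(counts=None, effective_lengths={}, fpkm=df, group_means=df)
        assert top_abundant(t, "g1", 2) == ["c", "a"]


class TestCoexpression:
    def _table(self, matrix, ids):
        df = pd.DataFrame(matrix, index=ids, columns=[f"s{i}" for i in range(len(matrix[0]))])
        return ExpressionTable(counts=None, effective_lengths={}, fpkm=df, group_means=df)

    def test_proportional_perfect_correlation(self):
        t = self._table([[1, 2, 4, 8], [2, 4, 8, 16]], ["seed", "cand"])
        pairs = coexpression(t, ["seed"], ["cand"], 0.5)
        assert len(pairs) == 1 and pairs[0][2] != pytest.approx(0)
        # log2(FPKM+1) of proportional series is not exactly linear; use exact copy
        t2 = self._table([[1, 2, 4, 8], [1, 2, 4, 8]], ["seed", "cand"])
        assert coexpression(t2, ["seed"], ["cand"], 0.5)[0][2] == pytest.approx(1.0)

    def test_constant_candidate_skipped(self):
        t = self._table([[1, 2, 4, 8], [3, 3, 3, 3]], ["seed", "cand"])
        with pytest.warns(UserWarning, match="zero variance"):
            assert coexpression(t, ["seed"], ["cand"], 0.0) == []

    def test_unknown_id_raises(self):
        t = self._table([[1, 2, 4]], ["seed"])
        with pytest.raises(KeyError):
            coexpression(t, ["seed"], ["ghost"], 0.5)

    def test_matches_direct_formula(self, rng):
        matrix = rng.random((6, 8)) * 50
        ids = [f"t{i}" for i in range(6)]
        t = self._table(matrix, ids)
        pairs = coexpression(t, ids[:2], ids[2:], 0.0)
        logm = np.log2(matrix + 1)
        for s, c, r in pairs:
            i, j = ids.index(s), ids.index(c)
            x, y = logm[i], logm[j]
            expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert r == pytest.approx(expected)


class TestFixtureExpression:
    def test_planted_specific_all_recovered(self, fixture_inputs):
        truth = fixture_inputs["truth"]
        config = fixture_inputs["config"]
        counts = simulate_counts(truth, config)
        lengths = {tid: truth.rep_lengths[tid] for tid in counts.transcript_ids}
        table = compute_fpkm(counts, lengths)
        calls = {c.transcript_id: c.specific_in for c in call_specific(table)}
        for tid, group in truth.planted_specific.items():
            assert calls[tid] == group

    def test_planted_de_power(self, fixture_inputs):
        truth = fixture_inputs["truth"]
        config = fixture_inputs["config"]
        counts = simulate_counts(truth, config)
        lengths = {tid: truth.rep_lengths[tid] for tid in counts.transcript_ids}
        table = compute_fpkm(counts, lengths)
        groups = counts.groups
        results = call_de(table, groups[0], groups[1], "auto")
        de = {r.transcript_id for r in results if r.is_de}
        planted = set(truth.planted_de)
        assert len(de & planted) / len(planted) >= 0.9
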