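"""Kappa statistics and agreement proportions against independent oracles.

Brute-force reference implementations (plain loops over raters and rater
pairs, no shared code with the package) are defined here and used to
check the vectorized implementations; third-party implementations
(sklearn's Cohen kappa, statsmodels' Fleiss kappa) give a second,
external route.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnagree import (
    agreement_report,
    agreement_with_majority,
    cohen_kappa,
    compute_majority,
    fleiss_kappa,
    fleiss_kappa_binary,
    merge_stages,
    observed_agreement,
    pairwise_matrix,
    per_majority_stage_breakdown,
)
from tests.conftest import hset_from_labels, random_counts


# ---------------------------------------------------------------------------
# brute-force oracles


def bf_cohen(a, b):
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    cats = sorted(set(a) | set(b))
    p_e = sum(
        (sum(1 for x in a if x == k) / n) * (sum(1 for y in b if y == k) / n)
        for k in cats
    )
    if p_e == 1:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def bf_fleiss(counts):
    counts = [list(map(int, row)) for row in counts]
    n_epochs = len(counts)
    s = sum(counts[0])
    p_bar_o = (
        sum(sum(n * (n - 1) for n in row) / (s * (s - 1)) for row in counts)
        / n_epochs
    )
    totals = [sum(row[k] for row in counts) for k in range(len(counts[0]))]
    grand = sum(totals)
    p_bar_e = sum((t / grand) ** 2 for t in totals)
    if p_bar_e == 1:
        return float("nan")
    return (p_bar_o - p_bar_e) / (1 - p_bar_e)


def bf_observed(counts):
    """Enumerate every rater pair explicitly."""
    total = 0.0
    for row in counts:
        raters = [k for k, n in enumerate(row) for _ in range(int(n))]
        pairs = list(itertools.combinations(range(len(raters)), 2))
        agree = sum(1 for i, j in pairs if raters[i] == raters[j])
        total += agree / len(pairs)
    return total / len(counts)


# ---------------------------------------------------------------------------


class TestCohenKappa:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 2, 3, 4, 2, 2])
        assert cohen_kappa(a, a) == 1.0

    def test_hand_tabulated_two_stage_example(self):
        # [W,W,N2,N2] vs [W,N2,N2,W]: p_o=0.5, both marginals (.5,.5), p_e=0.5
        a = np.array([0, 0, 2, 2])
        b = np.array([0, 2, 2, 0])
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=1e-15)
        assert cohen_kappa(a, b) == pytest.approx(bf_cohen(list(a), list(b)))

    def test_null_on_independent_raters(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, 10_000)
        b = rng.integers(0, 5, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_symmetry_and_label_permutation(self, rng):
        a = rng.integers(0, 5, 200)
        b = rng.integers(0, 5, 200)
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a), abs=1e-15)
        perm = rng.permutation(5)
        assert cohen_kappa(perm[a], perm[b]) == pytest.approx(
            cohen_kappa(a, b), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 5, 80)
            b = rng.integers(0, 5, 80)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.array([0, 1]), np.array([0]))
        with pytest.raises(ValueError):
            cohen_kappa(np.array([], dtype=int), np.array([], dtype=int))


class TestFleissKappa:
    def test_unanimous_two_stages_is_one(self):
        counts = np.array([[10, 0, 0, 0, 0], [0, 0, 10, 0, 0]])
        assert fleiss_kappa(counts) == pytest.approx(1.0)

    def test_null_on_independent_raters(self, rng):
        counts = random_counts(rng, 10_000, 10)
        assert abs(fleiss_kappa(counts)) < 0.02

    def test_toy_matrix_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        counts = np.array([[2, 1, 0], [0, 3, 0], [1, 1, 1], [0, 0, 3]])
        ours = fleiss_kappa(counts)
        assert ours == pytest.approx(bf_fleiss(counts), abs=1e-12)
        assert ours == pytest.approx(sm_fleiss(counts), abs=1e-12)

    def test_degenerate_single_stage_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            out = fleiss_kappa(np.array([[5, 0], [5, 0]]))
        assert np.isnan(out)

    def test_unequal_row_sums_rejected(self):
        with pytest.raises(ValueError, match="same number of raters"):
            fleiss_kappa(np.array([[3, 0], [2, 2]]))

    def test_s2_relation_to_cohen(self, rng):
        """For two raters, Fleiss and Cohen share p_o but Fleiss uses pooled
        marginals for chance; check both quantities explicitly."""
        a = rng.integers(0, 5, 400)
        b = rng.integers(0, 5, 400)
        counts = np.zeros((400, 5), dtype=int)
        for k in range(5):
            counts[:, k] = (a == k).astype(int) + (b == k).astype(int)
        p_o = np.mean(a == b)
        pooled = np.bincount(np.concatenate([a, b]), minlength=5) / 800
        p_e_fleiss = float(pooled @ pooled)
        expect = (p_o - p_e_fleiss) / (1 - p_e_fleiss)
        assert fleiss_kappa(counts) == pytest.approx(expect, abs=1e-12)
        # same observed agreement as Cohen's route, different chance term
        ma = np.bincount(a, minlength=5) / 400
        mb = np.bincount(b, minlength=5) / 400
        assert p_e_fleiss != pytest.approx(float(ma @ mb), abs=1e-6)


class TestBinaryKappa:
    def test_unanimous_rem_vs_wake_mix(self):
        counts = np.array([[0, 0, 0, 0, 10], [10, 0, 0, 0, 0], [0, 0, 0, 0, 10]])
        assert fleiss_kappa_binary(counts, 4) == pytest.approx(1.0)

    def test_collapse_matches_two_category_oracle(self):
        counts = np.array([[2, 1, 0], [0, 3, 0], [1, 1, 1], [0, 0, 3]])
        for stage in range(3):
            collapsed = [[row[stage], sum(row) - row[stage]] for row in counts]
            assert fleiss_kappa_binary(counts, stage) == pytest.approx(
                bf_fleiss(collapsed), abs=1e-12
            )

    def test_absent_stage_nan_with_warning(self):
        counts = np.array([[5, 5, 0, 0, 0], [10, 0, 0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(fleiss_kappa_binary(counts, 4))


class TestObservedAgreement:
    def test_eight_two_split(self):
        # (N2:8, N3:2): C(8,2)+C(2,2) = 29 of C(10,2) = 45 pairs agree
        counts = np.array([[0, 0, 8, 2, 0]])
        assert observed_agreement(counts) == pytest.approx(29 / 45)
        assert observed_agreement(counts) == pytest.approx(bf_observed(counts))

    def test_unanimous_is_one_and_s2_disagreement_zero(self):
        assert observed_agreement(np.array([[0, 7, 0, 0, 0]])) == 1.0
        assert observed_agreement(np.array([[1, 1, 0, 0, 0]])) == 0.0

    def test_empty_mask_rejected(self, rng):
        counts = random_counts(rng, 5, 4)
        with pytest.raises(ValueError, match="no epochs"):
            observed_agreement(counts, restrict_to=np.zeros(5, dtype=bool))


class TestAgreementWithMajority:
    def test_fraction_of_modal_votes(self):
        counts = np.array([[0, 0, 8, 2, 0]])
        res = compute_majority(hset_from_labels([["N2"]] * 8 + [["N3"]] * 2))
        assert agreement_with_majority(counts, res) == pytest.approx(0.8)

    def test_worked_split_epoch_is_half(self):
        labels = ["N2", "N2", "W", "N1", "W", "W", "W", "W", "N1", "N1"]
        h = hset_from_labels([[lab] for lab in labels])
        res = compute_majority(h)
        assert agreement_with_majority(res.counts, res) == pytest.approx(0.5)

    def test_monotone_in_unanimity(self, rng):
        """Moving one scorer to the modal stage never lowers agreement."""
        counts = random_counts(rng, 50, 8)
        res = compute_majority_from_counts(counts)
        base_obs = observed_agreement(counts)
        base_maj = agreement_with_majority(counts, res)
        bumped = counts.copy()
        i = next(
            r for r in range(len(bumped)) if (bumped[r] > 0).sum() >= 2
        )
        modal = bumped[i].argmax()
        donor = next(k for k in range(5) if bumped[i, k] > 0 and k != modal)
        bumped[i, donor] -= 1
        bumped[i, modal] += 1
        res2 = compute_majority_from_counts(bumped)
        assert observed_agreement(bumped) >= base_obs
        assert agreement_with_majority(bumped, res2) >= base_maj


def compute_majority_from_counts(counts):
    from hypnagree.majority import majority_score

    return majority_score(counts)


class TestBreakdownAndMerge:
    def test_per_stage_uses_majority_mask(self):
        h = hset_from_labels(
            [
                ["R", "N2", "W"],
                ["R", "N2", "N1"],
                ["R", "N3", "W"],
            ]
        )
        res = compute_majority(h)
        table = per_majority_stage_breakdown(res.counts, res)
        assert table["R"] == (1.0, 1.0)  # all majority-R epochs unanimous
        assert table["N2"] == (pytest.approx(2 / 3), pytest.approx(1 / 3))
        assert "N1" not in table  # never a majority stage

    def test_merge_relabels_and_pools_counts(self):
        h = hset_from_labels(
            [["N1", "N1", "N1"], ["N2", "N2", "N2"], ["N2", "N3", "N2"],
             ["N1", "N3", "W"], ["N2", "N3", "N2"], ["N1", "N3", "N2"],
             ["N2", "N3", "N2"], ["N1", "N3", "N2"], ["N2", "N3", "N2"],
             ["N2", "N3", "N2"]]
        )
        merged = merge_stages(h)
        assert merged.stage_labels == ("W", "L", "N3", "R")
        res = compute_majority(merged)
        # epoch 0: N1:4 + N2:6 -> L:10
        np.testing.assert_array_equal(res.counts[0], [0, 10, 0, 0])
        # epoch 1: (N1:1, N2:1, N3:8) -> (L:2, N3:8); majority N3
        np.testing.assert_array_equal(res.counts[1], [0, 2, 8, 0])
        assert merged.stage_labels[res.majority[1]] == "N3"
        table = per_majority_stage_breakdown(res.counts, res)
        assert set(table) <= {"W", "L", "N3", "R"}

    def test_merged_majority_from_forced_counts(self):
        # (N1:3, N2:4, N3:3) -> merged (L:7, N3:3), majority L
        h = hset_from_labels(
            [["N1"]] * 3 + [["N2"]] * 4 + [["N3"]] * 3
        )
        res = compute_majority(merge_stages(h))
        np.testing.assert_array_equal(res.counts[0], [0, 7, 3, 0])
        assert res.majority[0] == 1

    def test_identity_map_is_noop(self, small_hset):
        assert merge_stages(small_hset, {}) == small_hset

    def test_non_total_map_rejected(self, small_hset):
        with pytest.raises(ValueError, match="unknown stages"):
            merge_stages(small_hset, {"N9": "L"})


class TestPairwiseMatrix:
    def test_duplicate_scorers_give_ones(self):
        h = hset_from_labels([["W", "N2", "R"]] * 3)
        mat = pairwise_matrix(h)
        np.testing.assert_allclose(mat, np.ones((3, 3)))

    def test_consistency_with_scalar_calls(self, rng):
        h = hset_from_labels(
            [list(rng.choice(["W", "N1", "N2", "N3", "R"], 60)) for _ in range(3)]
        )
        mat = pairwise_matrix(h)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mat[i, j] == pytest.approx(
                    cohen_kappa(h.stages[i], h.stages[j])
                )
                assert mat[j, i] == pytest.approx(
                    np.mean(h.stages[i] == h.stages[j])
                )


@settings(max_examples=40, deadline=None)
@given(
    n_epochs=st.integers(2, 25),
    n_raters=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_observed_agreement_equals_pair_enumeration(n_epochs, n_raters, seed):
    rng = np.random.default_rng(seed)
    counts = random_counts(rng, n_epochs, n_raters)
    assert observed_agreement(counts) == pytest.approx(
        bf_observed(counts), abs=1e-12
    )


def test_agreement_report_schema(small_hset):
    rep = agreement_report(small_hset)
    d = rep.to_dict()
    assert set(d["kappa_fleiss_binary"]) == {"W", "N1", "N2", "N3", "R"}
    assert 0 <= d["observed_agreement"] <= 1
    assert 0 <= d["mean_agreement_with_majority"] <= 1
    assert len(d["per_scorer_agreement_with_majority"]) == 3
    mat = np.array(d["pairwise_matrix"])
    np.testing.assert_allclose(np.diag(mat), 1.0)
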