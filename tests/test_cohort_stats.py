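"""Rank statistics: Spearman with censoring, Mann-Whitney with exact
enumeration oracle, %GP4 grouping, RSEM transform."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hpmri import (
    correlation_matrix,
    group_by_gp4,
    mann_whitney,
    reference_cohort,
    spearman,
    transform_rsem,
)
from hpmri.cohort_stats import benjamini_hochberg


def rank_midrank(v):
    """Independent midrank implementation for the Spearman oracle."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size)
    i = 0
    sorted_v = v[order]
    while i < v.size:
        j = i
        while j < v.size and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks, computed from first principles."""
    rx, ry = rank_midrank(x), rank_midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def mann_whitney_enumeration_p(a, b):
    """Exact two-sided p by exhaustive enumeration of all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman(x, x).rs == pytest.approx(1.0)
        assert spearman(x, -x).rs == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4: rs = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rs == pytest.approx(0.8)
        assert res.rs == pytest.approx(spearman_oracle([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert res.n == 5

    def test_censored_entries_tie_together_between_zero_and_five(self):
        x = ["<5", "<5", 0, 5, 10]
        y = [1, 2, 3, 4, 5]
        res = spearman(x, y)
        ranks = rank_midrank([2.5, 2.5, 0, 5, 10])
        assert res.rs == pytest.approx(spearman_oracle(ranks, y))
        # the two censored entries share a rank above the exact zero
        assert ranks[0] == ranks[1] and ranks[0] > ranks[2] and ranks[0] < ranks[3]

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pairwise_deletion_of_missing(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 1, 9, 3, 5])
        assert res.n == 4

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=4, max_size=12),
        st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_midrank_oracle_with_ties(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 8), min_size=len(xs), max_size=len(xs)))
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        assert spearman(xs, ys).rs == pytest.approx(spearman_oracle(xs, ys), abs=1e-12)

    @given(st.permutations(list(range(8))))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, perm):
        x = np.arange(8.0)
        y = np.asarray(perm, dtype=float)
        base = spearman(x, y).rs
        assert spearman(np.exp(x), y).rs == pytest.approx(base)
        assert spearman(x, y**3 + 5 * y).rs == pytest.approx(base)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.flagged and res.direction == "equal"

    def test_separated_samples_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)  # 2 * 1/20 labelings
        assert res.mode == "exact"
        assert res.direction == "less"

    def test_u_plus_uprime_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(rng.integers(2, 10))
            b = rng.random(rng.integers(2, 10))
            u_ab = mann_whitney(a, b).u
            u_ba = mann_whitney(b, a).u
            assert u_ab + u_ba == pytest.approx(a.size * b.size)

    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=1, max_value=6),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_mode_equals_enumeration_oracle(self, n1, n2, rnd):
        if n1 + n2 > 8 or n1 + n2 < 3:
            return
        pool = rnd.sample(range(1000), n1 + n2)  # tie-free
        a, b = pool[:n1], pool[n1:]
        res = mann_whitney(a, b, mode="exact")
        assert res.p == pytest.approx(mann_whitney_enumeration_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGroupByGP4:
    def test_reference_cohort_partition(self):
        cohort = reference_cohort()
        groups = group_by_gp4(cohort)
        # censored "<5" and the 5/10% lesions are low; ISUP 1 excluded entirely
        assert len(groups["low"]) == 6
        assert set(groups["low"]["pctGP4_value"]) <= {2.5, 5.0, 10.0}
        assert (groups["high"]["pctGP4_value"] > 10).all()
        assert not set(groups["low"]["ISUP"]) & {1}
        assert not set(groups["high"]["ISUP"]) & {1}

    def test_boundary_and_censored_rules(self):
        df = pd.DataFrame(
            {
                "lesion_id": ["a", "b", "c", "d"],
                "ISUP": [2, 2, 2, 1],
                "pctGP4": ["<5", 10, 15, 0],
            }
        )
        groups = group_by_gp4(df)
        assert list(groups["low"]["lesion_id"]) == ["a", "b"]
        assert list(groups["high"]["lesion_id"]) == ["c"]

    def test_exclusion_list_honoured(self):
        df = pd.DataFrame(
            {"lesion_id": ["a", "b", "c"], "ISUP": [2, 2, 3], "pctGP4": [20, 30, 40]}
        )
        groups = group_by_gp4(df, exclude=["b"])
        assert list(groups["high"]["lesion_id"]) == ["a", "c"]


class TestTransformRSEM:
    def test_default_values(self):
        out, meta = transform_rsem([0.0, 7.0])
        assert out[0] == 0.0 and out[1] == pytest.approx(3.0)
        assert meta["transform"] == "log2(value + 1)"

    def test_monotone(self):
        v = np.linspace(0, 100, 50)
        out, _ = transform_rsem(v)
        assert np.all(np.diff(out) > 0)

    def test_minus_one_variant_masks_small_values(self):
        out, meta = transform_rsem([0.5, 3.0], variant="minus-one")
        assert np.isnan(out[0]) and out[1] == pytest.approx(1.0)
        assert "- 1" in meta["transform"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_rsem([-1.0])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        cohort = reference_cohort()
        tidy = correlation_matrix(cohort, ["lactateSNR", "pyruvateSNR", "meanADC"])
        diag = tidy[tidy.var1 == tidy.var2]
        assert (diag.rs == 1.0).all()
        off = tidy[tidy.var1 != tidy.var2]
        for _, row in off.iterrows():
            assert spearman(cohort[row.var2], cohort[row.var1]).rs == pytest.approx(row.rs)

    def test_flagged_lesions_dropped_only_for_gp4_pairs(self):
        cohort = reference_cohort()
        tidy = correlation_matrix(cohort, ["lactateSNR", "pctGP4_value"])
        cell = tidy[(tidy.var1 == "lactateSNR") & (tidy.var2 == "pctGP4_value")].iloc[0]
        assert cell.n == 12  # one lesion flagged for uncertain %GP4
        imaging = correlation_matrix(cohort, ["lactateSNR", "meanADC"])
        assert imaging[imaging.var1 != imaging.var2].iloc[0].n == 13


def test_benjamini_hochberg_hand_case():
    p = np.array([0.01, 0.04, 0.03, 0.20])
    adj = benjamini_hochberg(p)
    assert adj == pytest.approx([0.04, 0.0533333333, 0.0533333333, 0.2])
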