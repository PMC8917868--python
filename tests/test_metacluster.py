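"""Lattice-contiguous metaclustering, model selection and metacluster stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_model
from somgrn.metacluster import (
    _rss,
    assign_items_to_metaclusters,
    check_contiguity,
    constrained_kmeans,
    experiment_hierarchy,
    hypothesis_test,
    member_profiles,
    metacluster_foldchange,
    metacluster_profiles,
    select_k,
)
from somgrn.som import AssignmentMap, HexLattice


def exhaustive_best_contiguous_2partition(weights, lattice):
    """Minimum-RSS 2-colouring with both classes lattice-connected."""
    adj = lattice.adjacency()
    n = len(weights)

    def connected(us):
        us = set(us)
        if not us:
            return False
        stack = [next(iter(us))]
        seen = {stack[0]}
        while stack:
            u = stack.pop()
            for v in adj[u] & us:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == len(us)

    best = np.inf
    for mask in range(2 ** (n - 1)):
        s = {u for u in range(n - 1) if (mask >> u) & 1} | {n - 1}
        t = set(range(n)) - s
        if t and connected(s) and connected(t):
            labels = np.array([1 if u in s else 2 for u in range(n)])
            best = min(best, _rss(np.asarray(weights, float), labels, 2))
    return best


class TestConstrainedKmeans:
    def test_k1_single_connected_cluster(self, rng):
        model = make_model(rng.normal(size=(12, 2)), 3, 4)
        mc = constrained_kmeans(model, 1, trials=2, seed=0)
        assert mc.k == 1 and set(mc.labels) == {1}
        assert check_contiguity(mc, model.lattice.adjacency())

    def test_recovers_planted_blocks_and_matches_exhaustive_rss(self):
        rng = np.random.default_rng(11)
        blocks = np.array([0] * 8 + [1] * 8)  # rows 0-1 vs rows 2-3
        W = np.array([[0.0, 0.0], [4.0, 4.0]])[blocks] + rng.normal(0, 0.5, size=(16, 2))
        model = make_model(W, 4, 4)
        mc = constrained_kmeans(model, 2, trials=10, seed=1)
        best = exhaustive_best_contiguous_2partition(W, model.lattice)
        assert mc.rss == pytest.approx(best)
        # the two planted blocks are recovered exactly
        got = {frozenset(np.flatnonzero(mc.labels == lab)) for lab in (1, 2)}
        assert got == {frozenset(range(8)), frozenset(range(8, 16))}

    @pytest.mark.parametrize("seed", range(5))
    def test_every_metacluster_is_connected(self, seed):
        rng = np.random.default_rng(seed)
        model = make_model(rng.normal(size=(30, 4)), 5, 6)
        mc = constrained_kmeans(model, 5, trials=3, seed=seed)
        assert check_contiguity(mc, model.lattice.adjacency())
        assert sorted(set(mc.labels)) == [1, 2, 3, 4, 5]

    def test_selected_rss_not_worse_than_any_restart(self, rng):
        model = make_model(rng.normal(size=(20, 3)), 4, 5)
        mc = constrained_kmeans(model, 3, trials=8, seed=4)
        assert mc.rss <= min(mc.trial_rss) + 1e-12

    def test_k_out_of_range(self, rng):
        model = make_model(rng.normal(size=(4, 2)), 2, 2)
        with pytest.raises(ValueError):
            constrained_kmeans(model, 5)


class TestSelectK:
    def test_singleton_range(self, rng):
        model = make_model(rng.normal(size=(9, 2)), 3, 3)
        assert select_k(model, [1], trials=2).k == 1

    def test_unknown_criterion(self, rng):
        model = make_model(rng.normal(size=(9, 2)), 3, 3)
        with pytest.raises(ValueError):
            select_k(model, [1, 2], criterion="DIC")

    def test_recovers_planted_k_on_three_blocks(self):
        # separation 5x the within-block SD; both criteria should find k=3
        recovered = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            labels = np.repeat([0, 1, 2], 12)
            means = np.eye(3, 4) * 5.0
            W = means[labels] + rng.normal(0, 1.0, size=(36, 4))
            model = make_model(W, 6, 6)
            mc = select_k(model, range(1, 7), trials=5, seed=seed)
            recovered += abs(mc.k - 3) <= 1
        assert recovered >= 4

    def test_bic_recorded_alongside_aic(self, rng):
        model = make_model(rng.normal(size=(9, 2)), 3, 3)
        mc = select_k(model, [2, 3], criterion="BIC", trials=2)
        assert np.isfinite(mc.aic) and np.isfinite(mc.bic)
        assert mc.criterion == "BIC"


class TestProfilesAndAssignment:
    def test_single_unit_profile(self, rng):
        W = rng.normal(size=(4, 3))
        model = make_model(W, 2, 2)
        mc = constrained_kmeans(model, 4, trials=1, seed=0)
        prof = metacluster_profiles(model, mc)
        for lab in range(1, 5):
            unit = int(np.flatnonzero(mc.labels == lab)[0])
            assert np.allclose(prof.loc[lab], W[unit])

    def test_profile_mean_closed_form(self):
        W = np.array([[1.0, 3.0], [3.0, 1.0]])
        model = make_model(W, 1, 2)
        mc = constrained_kmeans(model, 1, trials=1)
        prof = metacluster_profiles(model, mc)
        assert np.allclose(prof.loc[1], [2.0, 2.0])

    def test_normalized_profile_max_one(self, rng):
        model = make_model(np.abs(rng.normal(size=(6, 3))) + 0.1, 2, 3)
        mc = constrained_kmeans(model, 2, trials=2)
        prof = metacluster_profiles(model, mc, normalize=True)
        assert np.allclose(prof.max(axis=1), 1.0)

    def test_item_composition_matches_brute_force(self, rng):
        model = make_model(rng.normal(size=(12, 2)), 3, 4)
        mc = constrained_kmeans(model, 3, trials=2, seed=1)
        units = pd.Series(rng.integers(0, 12, size=40), index=[f"g{i}" for i in range(40)])
        am = AssignmentMap(unit=units, distance=pd.Series(0.0, index=units.index))
        item_mc = assign_items_to_metaclusters(am, mc)
        for item, unit in units.items():
            assert item_mc[item] == mc.labels[unit]
        # conservation: member counts sum to total items
        assert item_mc.value_counts().sum() == 40

    def test_member_profiles_average_raw_matrix(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 10, size=(6, 2)),
                           index=list("abcdef"), columns=["x", "y"])
        item_mc = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        prof = member_profiles(mat, item_mc)
        assert np.allclose(prof.loc[1], mat.loc[list("abc")].mean())


class TestHypothesisTest:
    def _items(self, genes):
        return pd.Series(1, index=genes)

    def test_identical_columns_p_one(self):
        genes = [f"g{i}" for i in range(8)]
        mat = pd.DataFrame({"A": np.arange(8.0), "B": np.arange(8.0)}, index=genes)
        res = hypothesis_test(self._items(genes), mat, ("A", "B"))
        assert res.loc[1, "p"] == 1.0
        assert bool(res.loc[1, "degenerate"])

    def test_exact_p_matches_sign_flip_enumeration(self):
        # n=6 all-positive differences: two-sided exact p = 2/2^6
        genes = [f"g{i}" for i in range(6)]
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        mat = pd.DataFrame({"A": diffs, "B": np.zeros(6)}, index=genes)
        res = hypothesis_test(self._items(genes), mat, ("A", "B"))
        assert res.loc[1, "p"] == pytest.approx(2 / 2**6)
        # independent oracle: enumerate all sign assignments of the ranks
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks.sum()  # all positive
        total = 0
        extreme = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            total += 1
            wm = 6 * 7 / 2
            if min(w, wm - w) <= min(w_obs, wm - w_obs):
                extreme += 1
        assert res.loc[1, "p"] == pytest.approx(extreme / total)

    def test_bh_q_not_below_p(self, rng):
        genes = [f"g{i}" for i in range(40)]
        item_mc = pd.Series(rng.integers(1, 5, size=40), index=genes)
        mat = pd.DataFrame(
            {"A": rng.normal(size=40), "B": rng.normal(size=40)}, index=genes
        )
        res = hypothesis_test(item_mc, mat, ("A", "B"))
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(60)]
            item_mc = pd.Series([1] * 30 + [2] * 30, index=genes)
            base = rng.uniform(1, 5, size=60)
            shift = np.r_[np.full(30, 2.0), np.zeros(30)]
            mat = pd.DataFrame(
                {"A": base + shift + rng.normal(0, 0.3, 60), "B": base + rng.normal(0, 0.3, 60)},
                index=genes,
            )
            res = hypothesis_test(item_mc, mat, ("A", "B"))
            hits += bool(res.loc[1, "q"] < 0.05)
        assert hits >= 9


class TestFoldchange:
    def test_equal_columns_zero(self):
        genes = list("ab")
        mat = pd.DataFrame({"t": [3.0, 1.0], "r": [3.0, 1.0]}, index=genes)
        fc = metacluster_foldchange(pd.Series(1, index=genes), mat, "t", "r")
        assert fc[1] == 0.0

    def test_closed_form_cancellation(self):
        genes = list("ab")
        mat = pd.DataFrame({"t": [3.0, 1.0], "r": [1.0, 3.0]}, index=genes)
        fc = metacluster_foldchange(pd.Series(1, index=genes), mat, "t", "r")
        assert fc[1] == pytest.approx(0.0)  # mean of {+1, -1} with pseudocount 1

    def test_matches_per_gene_oracle(self, rng):
        genes = [f"g{i}" for i in range(10)]
        mat = pd.DataFrame(
            {"t": rng.uniform(0, 20, 10), "r": rng.uniform(0, 20, 10)}, index=genes
        )
        fc = metacluster_foldchange(pd.Series(1, index=genes), mat, "t", "r")
        expect = np.mean(np.log2((mat["t"] + 1) / (mat["r"] + 1)))
        assert fc[1] == pytest.approx(expect)


class TestExperimentHierarchy:
    def test_duplicate_columns_merge_first_at_zero(self, rng):
        prof = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        prof["d"] = prof["a"]
        Z, order = experiment_hierarchy(prof)
        first = Z[0]
        merged = {int(first[0]), int(first[1])}
        assert merged == {0, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_average_linkage(self, rng):
        prof = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("xyz"))
        corr = np.corrcoef(prof.to_numpy().T)
        d = 1 - corr
        # with 3 leaves: first merge = closest pair; check against scipy result
        Z, order = experiment_hierarchy(prof)
        i, j = np.unravel_index(np.argmin(d + np.eye(3) * 9), d.shape)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {i, j}
        assert sorted(order) == ["x", "y", "z"]

    def test_zero_variance_column_distance_one(self, rng):
        prof = pd.DataFrame({"a": rng.normal(size=6), "b": np.ones(6)})
        Z, order = experiment_hierarchy(prof)
        assert Z[0, 2] == pytest.approx(1.0)
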