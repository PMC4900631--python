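"""Monte-Carlo random encounters and the group-membership permutation test."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from fisofus.errors import ConfigurationError
from fisofus.null_models import (
    PermutationResult, association_persistence, classify_and_count,
    expected_nonrandom_by_chance, leave_one_out_rerun, monte_carlo_random_dai,
    permutation_test, _occurrence_matrix, _try_swap,
)
from fisofus.synthetic_data import SyntheticConfig, generate_scan_data

from conftest import make_table


class TestMonteCarlo:
    def test_far_apart_cores_give_exact_zero(self):
        a, b = box(0, 0, 100, 100), box(500, 0, 600, 100)
        r = monte_carlo_random_dai(a, b, z=10, trials=50, seed=0)
        assert r.random_dai == 0.0 and r.mean_cooccurrences == 0.0

    def test_tiny_coincident_squares_flagged_infinite(self):
        a = box(0, 0, 1, 1)
        r = monte_carlo_random_dai(a, a, z=10, trials=20, seed=0)
        assert r.mean_cooccurrences == 10.0
        assert r.infinite

    def test_multipart_region_sampling(self):
        # two-part core area: sampling must cover both parts
        from shapely.ops import unary_union
        a = unary_union([box(0, 0, 50, 50), box(200, 0, 250, 50)])
        b = box(0, 0, 250, 50)
        r = monte_carlo_random_dai(a, b, z=50, trials=100, seed=1)
        assert 0.0 < r.mean_cooccurrences < 50.0

    def test_estimator_consistency_doubling_trials(self):
        # standard error of the per-trial mean scales as 1/sqrt(trials)
        a, b = box(0, 0, 100, 100), box(60, 0, 160, 100)
        se = {}
        for trials in (100, 400):
            means = []
            for seed in range(20):
                r = monte_carlo_random_dai(a, b, z=20, trials=trials, seed=seed)
                means.append(r.mean_cooccurrences)
            se[trials] = np.std(means, ddof=1)
        ratio = se[100] / se[400]
        assert 1.0 < ratio < 4.0  # expected 2, generous sampling noise band

    def test_z_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            monte_carlo_random_dai(box(0, 0, 1, 1), box(0, 0, 1, 1), z=0)


def _random_binary_matrix(rng, nr=30, nc=8, p=0.4):
    M = (rng.uniform(size=(nr, nc)) < p).astype(np.int8)
    M[M.sum(axis=1) == 0, 0] = 1  # no empty subgroup rows
    return M


class TestSwaps:
    def test_swaps_preserve_margins(self, rng):
        M = _random_binary_matrix(rng)
        rows, cols = M.sum(axis=1).copy(), M.sum(axis=0).copy()
        done = 0
        while done < 500:
            if _try_swap(M, rng, None):
                done += 1
        assert np.array_equal(M.sum(axis=1), rows)
        assert np.array_equal(M.sum(axis=0), cols)

    def test_gregariousness_profile_preserved(self, rng):
        # each individual's distribution of subgroup sizes it sits in is a
        # function of (row sums, its column); after many swaps the per-
        # individual membership count and the subgroup-size multiset are intact
        M = _random_binary_matrix(rng)
        sizes_before = sorted(M.sum(axis=1))
        member_before = M.sum(axis=0).copy()
        for _ in range(2000):
            _try_swap(M, rng, None)
        assert sorted(M.sum(axis=1)) == sizes_before
        assert np.array_equal(M.sum(axis=0), member_before)


@pytest.fixture(scope="module")
def null_result():
    cfg = SyntheticConfig(n_individuals=7, seasons=("dry-2013",),
                          scans_per_day=8, days_per_season=25,
                          mean_subgroup_size=3.0, seed=42)
    t, _ = generate_scan_data(cfg)
    return permutation_test(t, t.roster, "dry-2013", n_permutations=200,
                            swaps_per_step=20, burn_in=300, seed=7)


class TestPermutationTest:
    def test_result_shape(self, null_result):
        r = null_result
        assert len(r.null_cvs) == 200
        assert 0.0 < r.global_p <= 1.0
        assert set(r.dyads["class"]) <= {"attractive", "repulsive", "neutral",
                                         "missing"}
        assert len(r.dyads) == 7 * 6 // 2

    def test_determinism(self, null_result):
        cfg = SyntheticConfig(n_individuals=7, seasons=("dry-2013",),
                              scans_per_day=8, days_per_season=25,
                              mean_subgroup_size=3.0, seed=42)
        t, _ = generate_scan_data(cfg)
        r2 = permutation_test(t, t.roster, "dry-2013", n_permutations=200,
                              swaps_per_step=20, burn_in=300, seed=7)
        assert np.array_equal(r2.null_cvs, null_result.null_cvs)
        assert r2.global_p == null_result.global_p

    def test_planted_attraction_detected(self):
        n = 8
        pref = np.zeros((n, n))
        pref[0, 1] = pref[1, 0] = 3.0
        cfg = SyntheticConfig(n_individuals=n, seasons=("dry-2013",),
                              scans_per_day=10, days_per_season=30,
                              mean_subgroup_size=3.0, preference_matrix=pref,
                              seed=5)
        t, _ = generate_scan_data(cfg)
        r = permutation_test(t, t.roster, "dry-2013", n_permutations=300,
                             swaps_per_step=20, burn_in=400, seed=11)
        row = r.dyads[(r.dyads.id_a == "ID01") & (r.dyads.id_b == "ID02")]
        assert row.iloc[0]["class"] == "attractive"

    def test_stratified_swaps_stay_within_days(self):
        cfg = SyntheticConfig(n_individuals=6, seasons=("dry-2013",),
                              scans_per_day=6, days_per_season=20,
                              mean_subgroup_size=2.5, seed=3)
        t, _ = generate_scan_data(cfg)
        r = permutation_test(t, t.roster, "dry-2013", n_permutations=50,
                             swaps_per_step=10, burn_in=100,
                             stratify_by_day=True, seed=1)
        assert len(r.null_cvs) == 50


class TestCountsAndPersistence:
    def _fake_result(self, season, flags):
        rows = [(a, b, 0.5, 0.1, 0.9, 0.5, cls) for (a, b, cls) in flags]
        dyads = pd.DataFrame(rows, columns=["id_a", "id_b", "observed_dai_g",
                                            "q_low", "q_high", "p_two", "class"])
        return PermutationResult([], season, 1.0, np.array([1.0]), 0.5, dyads,
                                 None, None, 1, 1, 0.05, 0)

    def test_classify_and_count(self):
        r = self._fake_result("dry-2013", [("A", "B", "attractive"),
                                           ("A", "C", "attractive"),
                                           ("B", "C", "repulsive"),
                                           ("C", "D", "neutral")])
        c = classify_and_count(r)
        assert (c["n_attractive"], c["n_repulsive"]) == (2, 1)
        assert c["n_attractive"] + c["n_repulsive"] <= len(r.dyads)

    def test_all_neutral(self):
        r = self._fake_result("dry-2013", [("A", "B", "neutral")])
        c = classify_and_count(r)
        assert (c["n_attractive"], c["n_repulsive"]) == (0, 0)

    def test_expected_by_chance(self):
        assert expected_nonrandom_by_chance(55, 0.05) == pytest.approx(2.75)
        assert expected_nonrandom_by_chance(100, 0.0) == 0.0
        assert expected_nonrandom_by_chance(100, 0.05) == pytest.approx(5.0)

    def test_persistence_consecutive_and_class_change(self):
        seasons = ["dry-2013", "wet-2013", "dry-2014", "wet-2014"]
        results = [
            self._fake_result(seasons[0], [("A", "B", "attractive"),
                                           ("C", "D", "attractive")]),
            self._fake_result(seasons[1], [("A", "B", "attractive")]),
            self._fake_result(seasons[2], [("C", "D", "repulsive")]),
            self._fake_result(seasons[3], []),
        ]
        table = association_persistence(results).table.set_index(["id_a", "id_b"])
        ab = table.loc[("A", "B")]
        assert ab["consecutive"] and not ab["non_consecutive"]
        assert not ab["class_change"]
        cd = table.loc[("C", "D")]
        assert cd["non_consecutive"] and not cd["consecutive"]
        assert cd["class_change"]  # attractive in one season, repulsive later


class TestLeaveOneOut:
    def test_excluding_unsighted_individual_changes_nothing(self):
        cfg = SyntheticConfig(n_individuals=6, seasons=("dry-2013",),
                              scans_per_day=6, days_per_season=20,
                              mean_subgroup_size=2.5, seed=9)
        t, _ = generate_scan_data(cfg)
        roster = list(t.roster) + ["GHOST"]
        t.roster["GHOST"] = "unknown"
        kw = dict(n_permutations=50, swaps_per_step=10, burn_in=100, seed=2)
        full = permutation_test(t, roster, "dry-2013", **kw)
        loo = leave_one_out_rerun(t, roster, "GHOST", "dry-2013", **kw)
        assert np.array_equal(full.null_cvs, loo.null_cvs)
        assert full.global_p == loo.global_p

    def test_excluded_dyads_absent(self):
        cfg = SyntheticConfig(n_individuals=6, seasons=("dry-2013",),
                              scans_per_day=6, days_per_season=20,
                              mean_subgroup_size=2.5, seed=9)
        t, _ = generate_scan_data(cfg)
        loo = leave_one_out_rerun(t, list(t.roster), "ID01", "dry-2013",
                                  n_permutations=50, swaps_per_step=10,
                                  burn_in=100, seed=2)
        assert "ID01" not in set(loo.dyads.id_a) | set(loo.dyads.id_b)

    def test_unknown_individual_rejected(self, toy_table):
        with pytest.raises(ConfigurationError):
            leave_one_out_rerun(toy_table, ["A", "B"], "NOPE")
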