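"""Pair similarity, outlier screening, drift scores, permutation nulls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from driftconn import (
    AnalysisError,
    ConnectivityMap,
    OutlierRule,
    PermutationConfig,
    drift_score,
    exclude_outliers,
    format_permutation_p,
    make_schedule,
    pairwise_similarity,
    permutation_test,
)
from driftconn.connectivity import FISHER_CLIP

Z_MAX = np.arctanh(1.0 - FISHER_CLIP)


def random_maps(schedule, n_targets=20, seed=0):
    rng = np.random.default_rng(seed)
    targets = np.arange(n_targets)
    return [
        ConnectivityMap(
            session_id=sid,
            seed="seed",
            target_ids=targets,
            z=rng.standard_normal(n_targets),
        )
        for sid in schedule.session_ids
    ]


def pair_frame(dt, z):
    return pd.DataFrame(
        {
            "session_i": [f"s{i}a" for i in range(len(dt))],
            "session_j": [f"s{i}b" for i in range(len(dt))],
            "delta_t_days": np.asarray(dt, float),
            "z_similarity": np.asarray(z, float),
            "included": True,
        }
    )


class TestPairwiseSimilarity:
    @pytest.mark.parametrize(
        "design,expected", [("female30", 435), ("male40", 780)]
    )
    def test_pair_counts_match_schedule(self, design, expected):
        sch = make_schedule(design)
        pairs = pairwise_similarity(random_maps(sch, seed=1), sch)
        assert len(pairs) == expected

    def test_identical_maps_hit_clipped_maximum(self):
        sch = make_schedule("custom", times=[0.0, 1.0, 2.0])
        base = random_maps(sch, seed=2)
        z = base[0].z
        maps = [
            ConnectivityMap(m.session_id, m.seed, m.target_ids, z.copy())
            for m in base
        ]
        pairs = pairwise_similarity(maps, sch)
        assert np.allclose(pairs["z_similarity"], Z_MAX)

    def test_uncorrelated_maps_give_zero(self):
        sch = make_schedule("custom", times=[0.0, 1.0, 2.0])
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # sample correlation 0 with a
        maps = [
            ConnectivityMap(sid, "seed", np.arange(4), z)
            for sid, z in zip(sch.session_ids, (a, b, a))
        ]
        pairs = pairwise_similarity(maps, sch).set_index(["session_i", "session_j"])
        assert pairs.loc[("ses-01", "ses-02"), "z_similarity"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_mismatched_targets_rejected(self):
        sch = make_schedule("custom", times=[0.0, 1.0, 2.0])
        maps = random_maps(sch, seed=3)
        maps[1] = ConnectivityMap(
            maps[1].session_id, "seed", np.arange(1, 21), maps[1].z
        )
        with pytest.raises(AnalysisError):
            pairwise_similarity(maps, sch)

    def test_drop_same_day_removes_fractional_pairs(self):
        sch = make_schedule("male40")
        maps = random_maps(sch, seed=4)
        pairs = pairwise_similarity(maps, sch, drop_same_day=True)
        assert (pairs["delta_t_days"] >= 1.0).all()
        # 10 morning/evening same-day pairs plus 9 evening-to-next-morning
        # pairs sit below one day
        assert len(pairs) == 780 - 19


class TestOutlierRule:
    def test_constant_similarities_not_excluded(self):
        pairs = pair_frame(np.arange(1, 6), np.full(5, 0.7))
        with pytest.warns(UserWarning, match="SD is zero"):
            out = exclude_outliers(pairs)
        assert out["included"].all()

    def test_single_gross_outlier_flagged(self):
        z = np.full(20, 0.5)
        z[:19] += np.linspace(-0.01, 0.01, 19)  # small spread
        sd0 = z.std(ddof=1)
        z[19] = 0.5 + 10 * sd0
        pairs = pair_frame(np.arange(1, 21), z)
        out = exclude_outliers(pairs, OutlierRule(k_sd=3.0))
        # verify against a hand-computed mean/SD screen
        mean, sd = z.mean(), z.std(ddof=1)
        expected = np.abs(z - mean) <= 3.0 * sd
        assert (~out["included"]).sum() == 1
        np.testing.assert_array_equal(out["included"].to_numpy(), expected)

    def test_single_pass_not_reiterated(self):
        # after removing the big outlier, the next-largest value would fail a
        # second-pass screen; a single-pass rule must keep it
        z = np.concatenate([np.zeros(17), [0.001, 0.002], [10.0]])
        pairs = pair_frame(np.arange(1, 21), z)
        out = exclude_outliers(pairs)
        assert (~out["included"]).sum() == 1


class TestDriftScore:
    def test_exact_linear_decay_gives_minus_one(self):
        dt = np.arange(1.0, 11.0)
        res = drift_score(pair_frame(dt, 1.0 - 0.01 * dt))
        assert res.r == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.integers(5, 40)
            dt = rng.uniform(0.5, 30, n)
            z = rng.standard_normal(n)
            res = drift_score(pair_frame(dt, z))
            num = np.mean(dt * z) - dt.mean() * z.mean()
            den = dt.std() * z.std()
            assert res.r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            drift_score(pair_frame([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_scale_of_time_units_immaterial(self):
        rng = np.random.default_rng(12)
        dt = rng.uniform(1, 30, 50)
        z = rng.standard_normal(50)
        days = drift_score(pair_frame(dt, z))
        hours = drift_score(pair_frame(dt * 24.0, z))
        assert days.r == pytest.approx(hours.r, abs=1e-12)


class TestPermutationTest:
    def test_observed_below_all_nulls_reports_add_one_floor(self):
        dt = np.arange(1.0, 31.0)
        pairs = pair_frame(dt, -0.01 * dt)  # r = -1 exactly
        res = permutation_test(
            pairs, PermutationConfig(n_shuffles=5000), rng=0
        )
        assert res.p_permutation == pytest.approx(1.0 / 5001.0)
        assert format_permutation_p(res.p_permutation, 5000) == "p < 0.001"

    def test_matches_full_enumeration_on_six_pairs(self):
        rng = np.random.default_rng(13)
        dt = np.array([1.0, 3.0, 6.0, 10.0, 15.0, 21.0])
        z = rng.standard_normal(6)
        pairs = pair_frame(dt, z)
        obs = drift_score(pairs).r

        def pearson(a, b):
            return np.corrcoef(a, b)[0, 1]

        null = [pearson(z, np.array(p)) for p in itertools.permutations(dt)]
        exact = np.mean(np.array(null) <= obs + 1e-12)
        res = permutation_test(pairs, PermutationConfig(n_shuffles=2000), rng=1)
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.p_permutation - exact) <= 1.96 * se + 1e-3

    def test_p_strictly_positive_and_bounded(self):
        rng = np.random.default_rng(14)
        pairs = pair_frame(rng.uniform(1, 30, 30), rng.standard_normal(30))
        res = permutation_test(pairs, PermutationConfig(n_shuffles=99), rng=2)
        assert 0.0 < res.p_permutation <= 1.0
        assert len(res.null) == 99

    def test_reproducible_given_rng(self):
        rng_pairs = np.random.default_rng(15)
        pairs = pair_frame(
            rng_pairs.uniform(1, 30, 40), rng_pairs.standard_normal(40)
        )
        a = permutation_test(pairs, PermutationConfig(n_shuffles=500), rng=7)
        b = permutation_test(pairs, PermutationConfig(n_shuffles=500), rng=7)
        assert a.p_permutation == b.p_permutation
        np.testing.assert_array_equal(a.null, b.null)

    def test_excluded_pairs_stay_out_of_null(self):
        dt = np.arange(1.0, 22.0)
        z = np.concatenate([np.linspace(1, 0.9, 20), [50.0]])
        pairs = exclude_outliers(pair_frame(dt, z))
        assert not pairs["included"].iloc[-1]
        res = permutation_test(pairs, PermutationConfig(n_shuffles=100), rng=3)
        assert res.n_pairs == 20
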