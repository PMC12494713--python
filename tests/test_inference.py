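"""Emotion PCA, covariate deltas, pair regression, dependent-correlation
comparison, network drift, FDR, and Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftconn import (
    ConfigurationError,
    DomainError,
    GeneratorParams,
    NumericalError,
    PermutationConfig,
    SeedSpec,
    bh_fdr,
    compare_dependent_correlations,
    compare_seed_drifts,
    drift_regression,
    drift_score,
    emotion_pca,
    kruskal_h,
    kruskal_wallis_perm,
    make_schedule,
    network_drift,
    pair_covariate_deltas,
    simulate_sessions,
)
from driftconn.connectivity import session_maps
from driftconn.drift import exclude_outliers, pairwise_similarity

from test_drift import pair_frame


class TestEmotionPCA:
    def test_single_variable_is_its_own_component(self):
        x = pd.DataFrame({"pss": [1.0, 4.0, 2.0, 6.0, 3.0]})
        res = emotion_pca(x)
        z = (x["pss"] - x["pss"].mean()) / x["pss"].std(ddof=1)
        np.testing.assert_allclose(res.scores, z, atol=1e-10)
        assert res.lambda_pct["pss"] == pytest.approx(100.0)

    def test_perfectly_correlated_pair_fully_explained(self):
        a = np.array([0.0, 1.0, 2.0, 5.0])
        x = pd.DataFrame({"q1": a, "q2": 3 * a + 1})
        res = emotion_pca(x)
        np.testing.assert_allclose(res.lambda_pct, 100.0, atol=1e-8)
        assert res.loadings["q1"] == pytest.approx(res.loadings["q2"], abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        latent = rng.standard_normal(40)
        x = pd.DataFrame(
            {
                f"q{i}": l * latent + np.sqrt(1 - l**2) * rng.standard_normal(40)
                for i, l in enumerate((0.9, 0.8, 0.85, 0.7))
            }
        )
        res = emotion_pca(x)
        # independent oracle: correlation-matrix eigendecomposition
        z = (x - x.mean()) / x.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        v1 = evecs[:, np.argmax(evals)]
        lam = 100.0 * evals.max() * v1**2
        np.testing.assert_allclose(res.lambda_pct.to_numpy(), lam, atol=1e-10)
        assert res.eigenvalues[0] >= res.eigenvalues[1:].max()
        assert res.loadings.iloc[0] > 0
        assert abs(res.scores.mean()) < 1e-10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            emotion_pca(pd.DataFrame({"q1": [1.0, 1.0, 1.0], "q2": [0, 1, 2.0]}))
        with pytest.raises(ConfigurationError):
            emotion_pca(pd.DataFrame({"q1": [1.0, np.nan], "q2": [0.0, 1.0]}))


class TestCovariateDeltas:
    def _pairs(self):
        return pd.DataFrame(
            {
                "session_i": ["s1", "s1"],
                "session_j": ["s2", "s3"],
                "delta_t_days": [1.0, 2.0],
                "z_similarity": [0.5, 0.4],
                "included": True,
            }
        )

    def test_absolute_difference_symmetric(self):
        cov = pd.DataFrame({"session_id": ["s1", "s2", "s3"], "h": [3.0, 7.0, 3.0]})
        out = pair_covariate_deltas(self._pairs(), cov, ["h"])
        assert out["d_h"].tolist() == [4.0, 0.0]
        flipped = cov.assign(h=[7.0, 3.0, 7.0])
        out2 = pair_covariate_deltas(self._pairs(), flipped, ["h"])
        assert out2["d_h"].tolist() == [4.0, 0.0]

    def test_missing_session_rejected(self):
        cov = pd.DataFrame({"session_id": ["s1", "s2"], "h": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            pair_covariate_deltas(self._pairs(), cov, ["h"])


class TestDriftRegression:
    def test_exact_linear_relation_recovered(self):
        dt = np.arange(1.0, 21.0)
        pairs = pair_frame(dt, 2.0 - 0.01 * dt)
        table = drift_regression(pairs)
        assert table.loc["delta_t_days", "B"] == pytest.approx(-0.01, abs=1e-12)
        assert table.loc["delta_t_days", "SE"] < 1e-10

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        dt = rng.uniform(1, 20, 8)
        h = rng.standard_normal(8)
        z = rng.standard_normal(8)
        pairs = pair_frame(dt, z)
        pairs["d_h"] = h
        table = drift_regression(pairs, ["d_h"])
        design = np.column_stack([np.ones(8), dt, h])
        beta = np.linalg.solve(design.T @ design, design.T @ z)
        np.testing.assert_allclose(
            table["B"].to_numpy(), beta, atol=1e-10
        )
        resid = z - design @ beta
        sigma2 = (resid**2).sum() / (8 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        np.testing.assert_allclose(table["SE"].to_numpy(), se, atol=1e-10)

    def test_slope_relates_to_drift_score_algebraically(self):
        rng = np.random.default_rng(9)
        dt = rng.uniform(1, 30, 60)
        z = rng.standard_normal(60)
        pairs = pair_frame(dt, z)
        r = drift_score(pairs).r
        b = drift_regression(pairs).loc["delta_t_days", "B"]
        assert b == pytest.approx(r * z.std() / dt.std(), abs=1e-10)

    def test_collinear_design_rejected(self):
        dt = np.arange(1.0, 11.0)
        pairs = pair_frame(dt, np.random.default_rng(0).standard_normal(10))
        pairs["d_h"] = 2 * dt
        with pytest.raises(NumericalError):
            drift_regression(pairs, ["d_h"])


def meng_oracle(r_jk, r_jh, r_kh, n):
    """Meng, Rosenthal & Rubin (1992) overlapping dependent-correlation z,
    coded independently of the library implementation."""
    import math

    z1 = math.atanh(r_jk)
    z2 = math.atanh(r_jh)
    r2bar = (r_jk**2 + r_jh**2) / 2
    f = (1 - r_kh) / (2 * (1 - r2bar))
    if f > 1:
        f = 1.0
    h = (1 - f * r2bar) / (1 - r2bar)
    return (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_kh) * h))


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(-0.2, -0.2, 0.4, 100)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_matches_published_formula_oracle(self):
        z, _ = compare_dependent_correlations(-0.30, -0.10, 0.50, 200)
        assert z == pytest.approx(meng_oracle(-0.30, -0.10, 0.50, 200), abs=1e-8)

    @pytest.mark.parametrize(
        "r_jk,r_jh,r_kh,n",
        [(-0.25, -0.05, 0.3, 60), (0.4, 0.1, 0.6, 35), (-0.1, -0.4, 0.2, 435)],
    )
    def test_antisymmetric_in_seed_order(self, r_jk, r_jh, r_kh, n):
        z1, _ = compare_dependent_correlations(r_jk, r_jh, r_kh, n)
        z2, _ = compare_dependent_correlations(r_jh, r_jk, r_kh, n)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            compare_dependent_correlations(0.2, 0.1, 0.5, 3)
        with pytest.raises(DomainError):
            compare_dependent_correlations(1.0, 0.1, 0.5, 30)

    def test_faster_drifting_seed_detected_on_phantom(
        self, phantom, layout, female_schedule
    ):
        images = phantom["images"]
        targets = layout.target_ids

        def pairs_for(label):
            maps = session_maps(images, SeedSpec.roi(label, label), targets)
            return exclude_outliers(pairwise_similarity(maps, female_schedule))

        z, p = compare_seed_drifts(pairs_for("ec_al"), pairs_for("ec_pm"))
        assert np.isfinite(z) and 0.0 < p <= 1.0


class TestBhFdr:
    def test_reference_adjustments(self):
        assert bh_fdr([0.02])[0] == pytest.approx(0.02)
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_step_up_oracle_on_random_vectors(self):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        rng = np.random.default_rng(17)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            np.testing.assert_allclose(bh_fdr(p), oracle(p), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.1, 1.2])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        assert kruskal_h([[1.0, 1.0], [1.0, 1.0], [1.0]]) == 0.0

    def test_matches_scipy_with_ties(self):
        groups = [[1.2, 3.4, 3.4], [2.2, 5.1], [0.5, 3.4, 7.7, 2.2]]
        expected = stats.kruskal(*groups).statistic
        assert kruskal_h(groups) == pytest.approx(expected, abs=1e-10)

    def test_permutation_wrapper_degenerate_case(self):
        tables = [
            {
                "delta_t": np.arange(1.0, 7.0),
                "z_by_network": pd.DataFrame(
                    {"netA": np.arange(6.0), "netB": np.arange(6.0)}
                ),
            }
        ]
        h, p = kruskal_wallis_perm(tables, n_perm=50, rng=0)
        assert h == 0.0
        assert p == 1.0

    def test_permutation_reproducible_and_detects_heterogeneity(self):
        rng = np.random.default_rng(21)
        dt = rng.uniform(1, 30, 60)
        strong = -0.08 * dt + 0.2 * rng.standard_normal(60)
        flat = 0.2 * rng.standard_normal(60)
        tables = []
        for _ in range(2):  # two subjects
            tables.append(
                {
                    "delta_t": dt,
                    "z_by_network": pd.DataFrame(
                        {"drifting": strong, "quiet": flat, "quiet2": flat[::-1]}
                    ),
                }
            )
        h1, p1 = kruskal_wallis_perm(tables, n_perm=300, rng=5)
        h2, p2 = kruskal_wallis_perm(tables, n_perm=300, rng=5)
        assert (h1, p1) == (h2, p2)
        assert h1 > 0
        assert p1 < 0.05


class TestNetworkDrift:
    def test_single_network_equals_whole_brain(self, phantom, layout, female_schedule):
        images = phantom["images"]
        targets = layout.target_ids
        maps = session_maps(images, SeedSpec.roi("ec_al", "ec_al"), targets)
        whole = pd.Series("all", index=targets)
        table = network_drift(
            maps,
            whole,
            female_schedule,
            permutation=PermutationConfig(n_shuffles=50),
            rng=3,
        )
        pairs = exclude_outliers(pairwise_similarity(maps, female_schedule))
        direct = drift_score(pairs)
        assert table.loc["all", "drift_r"] == pytest.approx(direct.r, abs=1e-12)

    def test_only_drifting_network_scores_negative(self, layout, female_schedule):
        params = GeneratorParams(
            n_timepoints=120, drift_step=0.05, drift_networks=("net01",)
        )
        scores = {"net01": [], "others": []}
        for rep in range(5):
            images, _ = simulate_sessions(
                female_schedule, layout, params, None, 700 + rep
            )
            maps = session_maps(
                images, SeedSpec.roi("ec_al", "ec_al"), layout.target_ids
            )
            table = network_drift(
                maps,
                layout.network_members(),
                female_schedule,
                permutation=PermutationConfig(n_shuffles=20),
                rng=rep,
            )
            scores["net01"].append(table.loc["net01", "drift_r"])
            scores["others"].append(
                table.drop(index="net01")["drift_r"].mean()
            )
        assert np.mean(scores["net01"]) < -0.1
        assert abs(np.mean(scores["others"])) < 0.05

    def test_tiny_network_rejected(self, phantom, layout, female_schedule):
        images = phantom["images"][:3]
        targets = layout.target_ids
        maps = session_maps(images, SeedSpec.roi("ec_al", "ec_al"), targets)
        networks = pd.Series("big", index=targets)
        networks.iloc[:3] = "tiny"
        sch = make_schedule("custom", times=[0.0, 1.0, 2.0])
        with pytest.raises(ConfigurationError, match="tiny"):
            network_drift(maps[:3], networks, sch, rng=0)

    def test_fdr_column_monotone_against_raw(self, phantom, layout, female_schedule):
        images = phantom["images"]
        maps = session_maps(
            images, SeedSpec.roi("ec_al", "ec_al"), layout.target_ids
        )
        table = network_drift(
            maps,
            layout.network_members(),
            female_schedule,
            permutation=PermutationConfig(n_shuffles=200),
            rng=11,
        )
        assert (table["p_fdr"] >= table["p_permutation"] - 1e-12).all()
        assert (table["p_fdr"] <= 1.0).all()
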