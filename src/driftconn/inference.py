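"""Confound control and comparative inference for drift scores.

Covers the remaining statistics of the analysis: aggregation of mood
questionnaires into one emotion score by PCA, per-pair covariate deltas,
the covariate-controlled multiple regression of pair similarity on elapsed
time, the Meng-Rosenthal-Rubin test for differences between two seeds'
(dependent, overlapping) drift scores, network-restricted drift with
Benjamini-Hochberg FDR across networks, and a Kruskal-Wallis test of
drift-score heterogeneity across networks with a pipeline-coupled
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMap
from .drift import (
    OutlierRule,
    PermutationConfig,
    exclude_outliers,
    pairwise_similarity,
    permutation_test,
)
from .exceptions import (
    AnalysisError,
    ConfigurationError,
    DomainError,
    NumericalError,
)
from .synthetic import SessionSchedule

__all__ = [
    "EmotionPCAResult",
    "emotion_pca",
    "pair_covariate_deltas",
    "drift_regression",
    "compare_dependent_correlations",
    "compare_seed_drifts",
    "network_drift",
    "bh_fdr",
    "kruskal_h",
    "kruskal_wallis_perm",
]


# ---------------------------------------------------------------------------
# Emotion PCA
# ---------------------------------------------------------------------------

@dataclass
class EmotionPCAResult:
    """First principal component of the standardized questionnaire battery.

    ``scores`` are mean-zero per-session PC1 scores; ``lambda_pct[q]`` is
    the percentage of questionnaire ``q``'s (standardized) variance
    captured by PC1, i.e. the squared correlation of the variable with the
    component.
    """

    scores: np.ndarray
    loadings: pd.Series
    lambda_pct: pd.Series
    eigenvalues: np.ndarray = field(repr=False, default=None)


def emotion_pca(questionnaires: pd.DataFrame) -> EmotionPCAResult:
    """PCA (correlation-matrix scaling) of the mood questionnaires.

    Variables are standardized to mean 0 / SD 1, the correlation matrix is
    eigendecomposed, and PC1 provides the per-session emotion score.  The
    sign is fixed so the first questionnaire loads positively.
    """
    if questionnaires.isna().any().any():
        raise ConfigurationError("questionnaire table contains missing scores")
    if len(questionnaires) < 2:
        raise AnalysisError("PCA needs >= 2 sessions")
    x = questionnaires.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = list(questionnaires.columns[sd == 0])
        raise ConfigurationError(f"zero-variance questionnaire(s): {flat}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pc1 = evecs[:, 0]
    if pc1[0] < 0:
        pc1 = -pc1
    scores = z @ pc1
    scores = scores - scores.mean()
    # correlation of each standardized variable with PC1 = sqrt(lambda1)*a_j
    var_corr = np.sqrt(max(evals[0], 0.0)) * pc1
    lam = 100.0 * var_corr**2
    cols = list(questionnaires.columns)
    return EmotionPCAResult(
        scores=scores,
        loadings=pd.Series(pc1, index=cols, name="loading"),
        lambda_pct=pd.Series(lam, index=cols, name="lambda_pct"),
        eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# Pairwise covariate deltas and regression
# ---------------------------------------------------------------------------

def pair_covariate_deltas(
    pairs: pd.DataFrame,
    covariates: pd.DataFrame,
    columns: Sequence[str],
) -> pd.DataFrame:
    """Attach absolute between-session covariate differences to each pair.

    Adds one ``d_<col>`` column per requested covariate: the absolute
    difference of that covariate between the pair's two sessions.
    """
    cov = covariates.set_index("session_id")
    for col in columns:
        if col not in cov.columns:
            raise ConfigurationError(f"covariate column {col!r} not found")
    missing = set(pairs["session_i"]).union(pairs["session_j"]) - set(cov.index)
    if missing:
        raise ConfigurationError(
            f"covariates missing for sessions: {sorted(missing)[:5]}"
        )
    out = pairs.copy()
    for col in columns:
        vi = cov.loc[out["session_i"], col].to_numpy()
        vj = cov.loc[out["session_j"], col].to_numpy()
        out[f"d_{col}"] = np.abs(vj - vi)
    return out


def drift_regression(
    pairs: pd.DataFrame,
    delta_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of pair similarity on elapsed time plus covariate deltas.

    Returns one row per predictor (``delta_t`` and each requested delta
    column) with coefficient ``B``, classical ``SE``, ``t`` and two-tailed
    ``p`` (``n - p - 1`` residual degrees of freedom).  The fit size is
    stored in ``DataFrame.attrs['n']``.
    """
    inc = pairs[pairs["included"]] if "included" in pairs.columns else pairs
    predictors = ["delta_t_days", *delta_columns]
    for col in predictors:
        if col not in inc.columns:
            raise ConfigurationError(f"predictor column {col!r} not found")
    n, p = len(inc), len(predictors)
    if n < p + 2:
        raise AnalysisError(f"need >= {p + 2} included pairs, got {n}")
    x = inc[predictors].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise NumericalError(
            f"collinear regression design over columns {['const', *predictors]}"
        )
    fit = sm.OLS(inc["z_similarity"].to_numpy(dtype=float), design).fit()
    table = pd.DataFrame(
        {
            "B": fit.params,
            "SE": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
    )
    table.index = ["const", *predictors]
    table.attrs["n"] = n
    return table


# ---------------------------------------------------------------------------
# Dependent (overlapping) correlation comparison
# ---------------------------------------------------------------------------

def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z test for two correlations sharing a variable.

    ``r_jk`` and ``r_jh`` are the two seeds' drift scores (each a
    correlation of similarity with the shared elapsed-time variable) and
    ``r_kh`` is the correlation between the two seeds' similarity vectors
    over the common pair set of size ``n``.  Returns ``(z, p)`` with a
    one-tailed p in the hypothesized direction (seed A more negative:
    ``p = Phi(z)``).
    """
    if n < 4:
        raise DomainError(f"need n >= 4 pairs, got {n}")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1.0:
            raise DomainError("correlations must lie strictly inside (-1, 1)")
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    r_sq_bar = (r_jk**2 + r_jh**2) / 2.0
    f = min((1.0 - r_kh) / (2.0 * (1.0 - r_sq_bar)), 1.0)
    h = (1.0 - f * r_sq_bar) / (1.0 - r_sq_bar)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r_kh) * h))
    p = float(stats.norm.cdf(z))
    return float(z), p


def compare_seed_drifts(
    pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
) -> tuple[float, float]:
    """Compare two seeds' drift scores over their common included pairs.

    Both pair tables must index the same session pairs; drift scores and
    the between-seed similarity correlation are recomputed on the
    intersection of the two seeds' included pairs before applying
    :func:`compare_dependent_correlations`.
    """
    key = ["session_i", "session_j"]
    merged = pairs_a.merge(pairs_b, on=key, suffixes=("_a", "_b"))
    both = merged[merged["included_a"] & merged["included_b"]]
    if len(both) < 4:
        raise AnalysisError("fewer than 4 common included pairs")
    dt = both["delta_t_days_a"].to_numpy()
    za = both["z_similarity_a"].to_numpy()
    zb = both["z_similarity_b"].to_numpy()
    r_jk = float(stats.pearsonr(za, dt).statistic)
    r_jh = float(stats.pearsonr(zb, dt).statistic)
    r_kh = float(stats.pearsonr(za, zb).statistic)
    return compare_dependent_correlations(r_jk, r_jh, r_kh, len(both))


# ---------------------------------------------------------------------------
# Network-level drift and multiplicity
# ---------------------------------------------------------------------------

def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def network_drift(
    maps: Sequence[ConnectivityMap],
    networks: pd.Series,
    schedule: SessionSchedule,
    *,
    rule: OutlierRule = OutlierRule(),
    permutation: PermutationConfig | None = None,
    rng: int | np.random.Generator | None = None,
    min_voxels: int = 10,
    drop_same_day: bool = False,
) -> pd.DataFrame:
    """Drift score per network, with permutation p and BH-FDR across networks.

    ``maps`` are whole-brain connectivity maps for one seed; ``networks``
    maps target voxel_id -> network label.  Similarity for each network is
    computed over that network's voxels only, then the standard exclusion,
    drift score, and permutation test are applied; p-values are BH-adjusted
    across networks.
    """
    if permutation is None:
        permutation = PermutationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ref_targets = maps[0].target_ids
    labels = networks.loc[ref_targets].to_numpy()
    rows = []
    for name in pd.unique(labels):
        mask = labels == name
        if mask.sum() < min_voxels:
            raise ConfigurationError(
                f"network {name!r} has only {int(mask.sum())} target voxels "
                f"(minimum {min_voxels})"
            )
        sub = [
            ConnectivityMap(
                session_id=m.session_id,
                seed=f"{m.seed}~{name}",
                target_ids=ref_targets[mask],
                z=m.z[mask],
            )
            for m in maps
        ]
        pairs = pairwise_similarity(sub, schedule, drop_same_day=drop_same_day)
        pairs = exclude_outliers(pairs, rule)
        result = permutation_test(
            pairs, permutation, seed_name=f"{maps[0].seed}~{name}", rng=rng
        )
        rows.append(
            {
                "network": name,
                "drift_r": result.r,
                "p_parametric": result.p_parametric,
                "p_permutation": result.p_permutation,
                "n_pairs": result.n_pairs,
            }
        )
    table = pd.DataFrame(rows).set_index("network")
    table["p_fdr"] = bh_fdr(table["p_permutation"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Kruskal-Wallis across networks
# ---------------------------------------------------------------------------

def kruskal_h(groups: Sequence[Sequence[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of groups."""
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis needs >= 2 groups")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = values.size
    if n < 2:
        raise AnalysisError("Kruskal-Wallis needs >= 2 observations")
    ranks = stats.rankdata(values)
    if np.ptp(values) == 0:
        return 0.0
    start = 0
    h = 0.0
    for g in groups:
        size = len(g)
        if size:
            h += ranks[start : start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return float(h / tie)


def _network_scores(
    delta_t: np.ndarray, z_by_network: pd.DataFrame
) -> np.ndarray:
    """Drift score per network column, ignoring NaN (excluded) pairs."""
    scores = np.empty(z_by_network.shape[1])
    for idx, col in enumerate(z_by_network.columns):
        z = z_by_network[col].to_numpy(dtype=float)
        ok = ~np.isnan(z)
        scores[idx] = stats.pearsonr(z[ok], delta_t[ok]).statistic
    return scores


def kruskal_wallis_perm(
    subject_tables: Sequence[Mapping[str, object]],
    n_perm: int = 5000,
    rng: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Heterogeneity of drift scores across networks, permutation-calibrated.

    Each element of ``subject_tables`` describes one subject:
    ``{"delta_t": 1-D array over pairs, "z_by_network": DataFrame of pair
    similarities (one column per network; NaN marks excluded pairs)}``.
    Observations are per-subject-per-network drift scores; groups are the
    networks.  Each permutation shuffles a subject's elapsed-time labels
    once (shared across that subject's networks), regenerates every drift
    score, and recomputes H; ``p = (1 + #{null H >= H}) / (1 + n_perm)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    columns = list(subject_tables[0]["z_by_network"].columns)
    for tab in subject_tables[1:]:
        if list(tab["z_by_network"].columns) != columns:
            raise ConfigurationError("subjects must share the same network columns")

    def h_for(dts: list[np.ndarray]) -> float:
        per_subject = [
            _network_scores(dt, tab["z_by_network"])
            for dt, tab in zip(dts, subject_tables)
        ]
        stacked = np.stack(per_subject)  # subjects x networks
        groups = [stacked[:, k] for k in range(stacked.shape[1])]
        return kruskal_h(groups)

    observed_dts = [
        np.asarray(tab["delta_t"], dtype=float) for tab in subject_tables
    ]
    h_obs = h_for(observed_dts)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = h_for([rng.permutation(dt) for dt in observed_dts])
    p = (1.0 + np.count_nonzero(null >= h_obs)) / (1.0 + n_perm)
    return float(h_obs), float(p)
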