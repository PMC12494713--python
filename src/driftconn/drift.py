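"""Temporal drift score: pair similarity, outlier exclusion, permutation null.

The temporal drift score of a seed is the Pearson correlation, across
unordered session pairs, between the Fisher-Z pattern similarity of the two
sessions' connectivity maps and the elapsed time between them.  Pairs whose
similarity deviates more than ``k_sd`` standard deviations from the mean
over all pairs are excluded once, before any inference.  Significance comes
from a two-tailed parametric test on r and from a one-tailed (lower-tail)
permutation null built by shuffling the elapsed-time labels across included
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMap, fisher_z
from .exceptions import AnalysisError, ConfigurationError
from .synthetic import SessionSchedule

__all__ = [
    "OutlierRule",
    "PermutationConfig",
    "DriftResult",
    "pairwise_similarity",
    "exclude_outliers",
    "drift_score",
    "permutation_test",
    "format_permutation_p",
]

PAIR_COLUMNS = ["session_i", "session_j", "delta_t_days", "z_similarity", "included"]


@dataclass(frozen=True)
class OutlierRule:
    """Exclude pairs more than ``k_sd`` SDs from the mean similarity."""

    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ConfigurationError("k_sd must be positive")


@dataclass(frozen=True)
class PermutationConfig:
    """Label-shuffle settings for the drift-score null distribution."""

    n_shuffles: int = 5000
    seed: int | None = None
    tail: str = "lower"

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")
        if self.tail != "lower":
            raise ConfigurationError("only the lower tail is supported")


@dataclass
class DriftResult:
    """A seed's temporal drift score with parametric and permutation p-values."""

    seed: str
    r: float
    p_parametric: float
    n_pairs: int
    p_permutation: float | None = None
    null: np.ndarray | None = field(default=None, repr=False)
    n_shuffles: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise AnalysisError(f"drift score {self.r} outside [-1, 1]")

    def summary(self) -> str:
        parts = [f"{self.seed}: r = {self.r:.3f} (n = {self.n_pairs} pairs)"]
        if self.p_permutation is not None:
            parts.append(
                "permutation "
                + format_permutation_p(self.p_permutation, self.n_shuffles or 0)
            )
        return ", ".join(parts)


def format_permutation_p(p: float, n_shuffles: int) -> str:
    """Report a permutation p-value at the resolution the shuffle count supports."""
    if p < 0.001:
        return "p < 0.001"
    return f"p = {p:.3f}"


def pairwise_similarity(
    maps: Sequence[ConnectivityMap],
    schedule: SessionSchedule,
    *,
    drop_same_day: bool = False,
) -> pd.DataFrame:
    """One record per unordered session pair: elapsed time and Z similarity.

    ``z_similarity`` is the Fisher-Z of the Pearson correlation between the
    two sessions' connectivity maps over target voxels.  Elapsed time comes
    from the schedule in (possibly fractional) days.  ``drop_same_day``
    removes pairs less than a day apart (the morning/evening pairs of the
    two-sessions-per-day schedule).
    """
    if len(maps) < 3:
        raise AnalysisError("need >= 3 sessions for pairwise similarity")
    if len(maps) != schedule.n_sessions:
        raise AnalysisError(
            f"{len(maps)} maps but schedule has {schedule.n_sessions} sessions"
        )
    ref = maps[0].target_ids
    for m in maps[1:]:
        if m.target_ids.shape != ref.shape or np.any(m.target_ids != ref):
            raise AnalysisError(
                f"target set of session {m.session_id} differs from "
                f"{maps[0].session_id}"
            )
    z_mat = np.stack([m.z for m in maps])
    centered = z_mat - z_mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        raise AnalysisError("a session's connectivity map has zero variance")
    unit = centered / norms[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)

    i_idx, j_idx = np.triu_indices(len(maps), k=1)
    dt = schedule.t_days[j_idx] - schedule.t_days[i_idx]
    if np.any(dt <= 0):
        raise AnalysisError("same-timestamp session pairs are disallowed")
    pairs = pd.DataFrame(
        {
            "session_i": np.array(schedule.session_ids)[i_idx],
            "session_j": np.array(schedule.session_ids)[j_idx],
            "delta_t_days": dt,
            "z_similarity": fisher_z(corr[i_idx, j_idx]),
            "included": True,
        }
    )
    if drop_same_day:
        pairs = pairs[pairs["delta_t_days"] >= 1.0].reset_index(drop=True)
    return pairs


def exclude_outliers(
    pairs: pd.DataFrame, rule: OutlierRule | float = OutlierRule()
) -> pd.DataFrame:
    """Flag pairs whose similarity deviates > k SDs from the mean (single pass).

    Mean and SD are computed once over all pairs; the rule is not
    re-iterated after exclusion.  A zero SD produces no exclusions and a
    warning.
    """
    if isinstance(rule, (int, float)):
        rule = OutlierRule(k_sd=float(rule))
    if len(pairs) < 3:
        raise AnalysisError("need >= 3 pairs for outlier screening")
    out = pairs.copy()
    z = out["z_similarity"].to_numpy()
    sd = z.std(ddof=1)
    if sd == 0:
        warnings.warn("similarity SD is zero; no outliers excluded", stacklevel=2)
        out["included"] = True
        return out
    out["included"] = np.abs(z - z.mean()) <= rule.k_sd * sd
    return out


def _included(pairs: pd.DataFrame) -> pd.DataFrame:
    if "included" in pairs.columns:
        return pairs[pairs["included"]]
    return pairs


def drift_score(pairs: pd.DataFrame, seed_name: str = "seed") -> DriftResult:
    """Pearson correlation of similarity with elapsed time over included pairs.

    The parametric p-value is the standard two-tailed t transform of r with
    ``n_pairs - 2`` degrees of freedom.
    """
    inc = _included(pairs)
    if len(inc) < 3:
        raise AnalysisError("need >= 3 included pairs for a drift score")
    dt = inc["delta_t_days"].to_numpy()
    z = inc["z_similarity"].to_numpy()
    if np.ptp(dt) == 0 or np.ptp(z) == 0:
        raise AnalysisError("zero variance in elapsed time or similarity")
    res = stats.pearsonr(z, dt)
    return DriftResult(
        seed=seed_name,
        r=float(res.statistic),
        p_parametric=float(res.pvalue),
        n_pairs=len(inc),
    )


def permutation_test(
    pairs: pd.DataFrame,
    config: PermutationConfig | None = None,
    *,
    seed_name: str = "seed",
    rng: int | np.random.Generator | None = None,
) -> DriftResult:
    """Drift score with a lower-tail permutation p-value and null distribution.

    Each shuffle permutes the elapsed-time labels across included pairs
    (similarities fixed) and recomputes the correlation.  The p-value uses
    the add-one rule ``(1 + #{null r <= observed r}) / (1 + n_shuffles)``,
    so it is never exactly zero.
    """
    if config is None:
        config = PermutationConfig()
    observed = drift_score(pairs, seed_name=seed_name)
    inc = _included(pairs)
    dt = inc["delta_t_days"].to_numpy()
    z = inc["z_similarity"].to_numpy()
    n = len(inc)

    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    z_std = (z - z.mean()) / z.std()
    dt_std = (dt - dt.mean()) / dt.std()
    perms = rng.permuted(
        np.broadcast_to(dt_std, (config.n_shuffles, n)).copy(), axis=1
    )
    null = perms @ z_std / n
    # ties with the observed score count as at-least-as-extreme; the small
    # tolerance keeps that convention stable under floating-point jitter
    p_perm = (1.0 + np.count_nonzero(null <= observed.r + 1e-12)) / (
        1.0 + config.n_shuffles
    )
    observed.p_permutation = float(p_perm)
    observed.null = null
    observed.n_shuffles = config.n_shuffles
    return observed
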