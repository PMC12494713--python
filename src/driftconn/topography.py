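"""Voxel-wise drift maps, the hippocampal longitudinal-gradient test, and
subregion averaging.

Single voxels (rather than ROI means) serve as seeds; each voxel gets its
own temporal drift score through the standard pipeline (connectivity map ->
pairwise similarity -> 3-SD outlier screen -> drift score, with the outlier
rule applied per voxel-seed).  The gradient test then asks whether voxel
drift scores vary linearly with the anterior-posterior (y, anterior-
positive) coordinate: faster anterior drift shows up as a negative
correlation between drift score and y, and significance comes from a
directional permutation null built by shuffling the y coordinates across
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMap, fisher_z
from .drift import OutlierRule, drift_score, exclude_outliers, pairwise_similarity
from .exceptions import AnalysisError, ConfigurationError
from .preprocess import SessionImage
from .synthetic import SessionSchedule

__all__ = [
    "GradientResult",
    "multi_voxel_maps",
    "voxelwise_drift",
    "gradient_test",
    "subregion_mean",
]


@dataclass
class GradientResult:
    """Correlation of voxel drift scores with y, and its permutation null."""

    r_gradient: float
    p_permutation: float
    n_perm: int
    n_voxels: int
    null: np.ndarray = field(repr=False, default=None)


def multi_voxel_maps(
    images: Sequence[SessionImage],
    voxel_ids: Sequence[int],
    target_ids: Sequence[int] | np.ndarray,
) -> dict[int, list[ConnectivityMap]]:
    """Connectivity maps for many single-voxel seeds in one pass per session.

    Equivalent to calling :func:`~driftconn.connectivity.connectivity_map`
    per voxel, but standardizes the target block once per session.
    """
    voxel_ids = np.asarray(voxel_ids)
    target_ids = np.asarray(target_ids)
    out: dict[int, list[ConnectivityMap]] = {int(v): [] for v in voxel_ids}
    for image in images:
        index = image.voxels.set_index("voxel_id").index
        seed_pos = index.get_indexer(voxel_ids)
        tgt_pos = index.get_indexer(target_ids)
        if np.any(seed_pos < 0) or np.any(tgt_pos < 0):
            raise ConfigurationError("requested voxels absent from session")
        seeds = image.signal[seed_pos]
        targets = image.signal[tgt_pos]
        s_c = seeds - seeds.mean(axis=1, keepdims=True)
        t_c = targets - targets.mean(axis=1, keepdims=True)
        s_n = np.linalg.norm(s_c, axis=1)
        t_n = np.linalg.norm(t_c, axis=1)
        if np.any(s_n == 0):
            bad = voxel_ids[s_n == 0][0]
            raise AnalysisError(
                f"voxel seed {bad} has zero variance in session {image.session_id}"
            )
        t_n = np.where(t_n > 0, t_n, 1.0)
        r = np.clip((s_c / s_n[:, None]) @ (t_c / t_n[:, None]).T, -1.0, 1.0)
        z = fisher_z(r)
        for row, vid in enumerate(voxel_ids):
            out[int(vid)].append(
                ConnectivityMap(
                    session_id=image.session_id,
                    seed=f"voxel_{vid}",
                    target_ids=target_ids,
                    z=z[row],
                )
            )
    return out


def voxelwise_drift(
    images: Sequence[SessionImage],
    voxel_table: pd.DataFrame,
    target_ids: Sequence[int] | np.ndarray,
    schedule: SessionSchedule,
    *,
    rule: OutlierRule = OutlierRule(),
    drop_same_day: bool = False,
) -> pd.DataFrame:
    """Temporal drift score per voxel seed.

    ``voxel_table`` needs columns ``voxel_id`` and ``y_mm`` (a ``subregion``
    column, if present, is carried through).  Errors raised by any pipeline
    stage are re-raised annotated with the offending voxel id.
    """
    required = {"voxel_id", "y_mm"}
    if not required <= set(voxel_table.columns):
        raise ConfigurationError(f"voxel table must have columns {sorted(required)}")
    maps = multi_voxel_maps(images, voxel_table["voxel_id"].to_numpy(), target_ids)
    records = []
    for _, row in voxel_table.iterrows():
        vid = int(row["voxel_id"])
        try:
            pairs = pairwise_similarity(
                maps[vid], schedule, drop_same_day=drop_same_day
            )
            pairs = exclude_outliers(pairs, rule)
            result = drift_score(pairs, seed_name=f"voxel_{vid}")
        except AnalysisError as err:
            raise AnalysisError(f"voxel {vid}: {err}") from err
        rec = {
            "voxel_id": vid,
            "y_mm": float(row["y_mm"]),
            "drift_r": result.r,
            "p_parametric": result.p_parametric,
            "n_pairs": result.n_pairs,
        }
        if "subregion" in voxel_table.columns:
            rec["subregion"] = row["subregion"]
        records.append(rec)
    return pd.DataFrame(records)


def gradient_test(
    voxel_map: pd.DataFrame,
    n_perm: int = 5000,
    rng: int | np.random.Generator | None = None,
    tail: str = "lower",
) -> GradientResult:
    """Correlate voxel drift scores with y and test against a coordinate-
    shuffle null.

    The permutation p-value is one-tailed with a fixed direction: the a
    priori hypothesis is faster anterior drift, i.e. drift scores more
    negative at larger (anterior-positive) y, so the null count is taken
    in the lower tail of the correlation (``tail="upper"`` tests the
    opposite direction).
    """
    if tail not in ("lower", "upper"):
        raise ConfigurationError(f"unknown tail {tail!r}")
    if len(voxel_map) < 10:
        raise AnalysisError("gradient test needs >= 10 voxels")
    y = voxel_map["y_mm"].to_numpy(dtype=float)
    r_vox = voxel_map["drift_r"].to_numpy(dtype=float)
    if len(np.unique(y)) < 5:
        raise AnalysisError("gradient test needs >= 5 distinct y_mm values")
    if np.ptp(y) == 0:
        raise AnalysisError("constant y_mm coordinates")
    observed = float(stats.pearsonr(r_vox, y).statistic)

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y_std = (y - y.mean()) / y.std()
    r_std = (r_vox - r_vox.mean()) / r_vox.std()
    perms = rng.permuted(np.broadcast_to(y_std, (n_perm, len(y))).copy(), axis=1)
    null = perms @ r_std / len(y)
    if tail == "lower":  # ties count as extreme, stable to float jitter
        count = np.count_nonzero(null <= observed + 1e-12)
    else:
        count = np.count_nonzero(null >= observed - 1e-12)
    p = (1.0 + count) / (1.0 + n_perm)
    return GradientResult(
        r_gradient=observed,
        p_permutation=float(p),
        n_perm=n_perm,
        n_voxels=len(voxel_map),
        null=null,
    )


def subregion_mean(
    voxel_map: pd.DataFrame, labels: Sequence[str] | None = None
) -> pd.Series:
    """Unweighted mean drift score per subregion label.

    ``labels`` restricts (and orders) the output; a requested label with no
    voxels is a configuration error.
    """
    if "subregion" not in voxel_map.columns:
        raise ConfigurationError("voxel map has no 'subregion' column")
    means = voxel_map.groupby("subregion")["drift_r"].mean()
    if labels is not None:
        missing = [lab for lab in labels if lab not in means.index]
        if missing:
            raise ConfigurationError(f"empty subregion label(s): {missing}")
        means = means.loc[list(labels)]
    return means
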