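"""Per-session seed-based connectivity patterns.

A seed is either an ROI (the unweighted mean time series over all voxels
carrying one or more labels) or a single voxel.  The connectivity pattern of
a session is the Pearson correlation of the seed series with every target
voxel's series, Fisher-Z transformed.  The target set is held fixed across
sessions so patterns can be compared pairwise downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, DomainError
from .preprocess import SessionImage

__all__ = [
    "SeedSpec",
    "ConnectivityMap",
    "seed_series",
    "fisher_z",
    "connectivity_map",
    "session_maps",
    "FISHER_CLIP",
]

#: Correlations are clipped to +/- (1 - FISHER_CLIP) before arctanh so that
#: perfectly correlated patterns map to a large finite Z (~8.4).
FISHER_CLIP = 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """Seed definition: an ROI label set averaged, or one voxel.

    ``mode`` is ``"roi-mean"`` with ``labels`` set, or ``"single-voxel"``
    with ``voxel_id`` set.
    """

    name: str
    mode: str = "roi-mean"
    labels: tuple[str, ...] | None = None
    voxel_id: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "roi-mean":
            if not self.labels:
                raise ConfigurationError("roi-mean seed requires labels")
        elif self.mode == "single-voxel":
            if self.voxel_id is None:
                raise ConfigurationError("single-voxel seed requires voxel_id")
        else:
            raise ConfigurationError(f"unknown seed mode {self.mode!r}")

    @classmethod
    def roi(cls, name: str, labels: str | Sequence[str]) -> "SeedSpec":
        if isinstance(labels, str):
            labels = (labels,)
        return cls(name=name, mode="roi-mean", labels=tuple(labels))

    @classmethod
    def voxel(cls, voxel_id: int, name: str | None = None) -> "SeedSpec":
        return cls(
            name=name or f"voxel_{voxel_id}", mode="single-voxel", voxel_id=int(voxel_id)
        )


@dataclass(frozen=True)
class ConnectivityMap:
    """One seed's Fisher-Z connectivity value per target voxel, one session."""

    session_id: str
    seed: str
    target_ids: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        tid = np.asarray(self.target_ids)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "target_ids", tid)
        if z.shape != tid.shape:
            raise ConfigurationError("target_ids and z shapes differ")
        if not np.all(np.isfinite(z)):
            raise AnalysisError("connectivity map contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.target_ids, "z": self.z})


def seed_series(image: SessionImage, seed: SeedSpec) -> np.ndarray:
    """Extract the seed time series (unweighted ROI mean or single voxel)."""
    if seed.mode == "single-voxel":
        rows = image.voxels.index[image.voxels["voxel_id"] == seed.voxel_id]
        if len(rows) == 0:
            raise ConfigurationError(
                f"seed voxel {seed.voxel_id} not present in session "
                f"{image.session_id}"
            )
        return image.signal[rows[0]].copy()
    mask = image.voxels["label"].isin(seed.labels).to_numpy()
    if not mask.any():
        raise ConfigurationError(
            f"seed {seed.name!r}: no voxels carry labels {seed.labels}"
        )
    return image.signal[mask].mean(axis=0)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher-Z (arctanh) transform with clipping at ``1 - 1e-7``.

    Odd and strictly increasing on [-1, 1]; values outside the closed
    interval (beyond a 1e-12 numerical slack) raise :class:`DomainError`.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise DomainError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -(1.0 - FISHER_CLIP), 1.0 - FISHER_CLIP))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit norm; returns (standardized, sd)."""
    centered = x - x.mean(axis=-1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=-1, keepdims=True))
    safe = np.where(sd > 0, sd, 1.0)
    return centered / safe, sd.squeeze(-1)


def connectivity_map(
    image: SessionImage,
    seed: SeedSpec,
    target_ids: Sequence[int] | np.ndarray,
) -> ConnectivityMap:
    """Correlate the seed series with every target voxel, Fisher-Z transform.

    Zero-variance target series map to z = 0 (with a warning) so the target
    dimension stays constant across sessions; a zero-variance seed series is
    an analysis error.
    """
    if image.n_timepoints < 3:
        raise AnalysisError("need >= 3 timepoints for a correlation map")
    target_ids = np.asarray(target_ids)
    pos = image.voxels.set_index("voxel_id").index.get_indexer(target_ids)
    if np.any(pos < 0):
        missing = target_ids[pos < 0][:5]
        raise ConfigurationError(f"target voxels absent from session: {missing}")
    series = seed_series(image, seed)
    if np.ptp(series) == 0:
        raise AnalysisError(
            f"seed {seed.name!r} has zero variance in session {image.session_id}"
        )
    seed_std, _ = _standardize_rows(series[None, :])
    targets = image.signal[pos]
    tgt_std, tgt_sd = _standardize_rows(targets)
    r = (tgt_std @ seed_std[0])
    flat = tgt_sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance target voxels mapped to z = 0 "
            f"in session {image.session_id}",
            stacklevel=2,
        )
        r[flat] = 0.0
    r = np.clip(r, -1.0, 1.0)  # guard rounding
    return ConnectivityMap(
        session_id=image.session_id,
        seed=seed.name,
        target_ids=target_ids,
        z=fisher_z(r),
    )


def session_maps(
    images: Iterable[SessionImage],
    seed: SeedSpec,
    target_ids: Sequence[int] | np.ndarray,
) -> list[ConnectivityMap]:
    """Connectivity maps for one seed across a list of sessions."""
    return [connectivity_map(img, seed, target_ids) for img in images]
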