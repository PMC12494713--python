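"""Multi-session phantom fMRI generator with known ground truth.

The phantom emulates the statistical structure a seed-based temporal-drift
analysis assumes: a dense-sampling schedule (30 daily sessions, or 40
sessions over 30 days with morning/evening pairs on the middle ten days), a
coordinate table of seed ROIs (anterolateral / posteromedial entorhinal
cortex, a strip of hippocampal voxels spanning the longitudinal y axis, and
two control regions) plus gray-matter target voxels partitioned into
networks, and per-session latent seed-to-target connectivity weights that
drift across sessions as a random walk.

Model
-----
Each drifting *entity* (a seed ROI or a single hippocampal voxel) carries a
latent weight vector ``w_s`` over target voxels.  Between sessions the
weights take a random-walk step ``w_s = w_{s-1} + delta * sqrt(dt) * eta``
with a fresh unit-norm direction ``eta``, so expected squared displacement
grows linearly in elapsed time and pattern similarity decays monotonically
with the interval between any two sessions.  Covariates (a cyclic
hormone-like series, head motion, a latent emotion factor) can additionally
displace the weights along a Brownian path indexed by the covariate's
value at couplings ``beta_*``: expected squared displacement between two
sessions is then proportional to the absolute covariate difference, the
linear-in-|delta| structure the pairwise covariate regression models.
Within a session each entity emits a band-limited latent signal ``u(t)``;
target voxel ``v`` records ``sum_e w_e(v) u_e(t) + sigma * noise`` and seed
voxels record their entity's ``u(t)`` plus noise, so empirical seed-target
correlation maps approximate ``w_s`` up to scale.  Observation noise is by
default constructed so that null pattern-similarity fluctuations carry no
session-level components and are exchangeable across session pairs; see
:func:`_observation_noise` and the methods note for why this matters to
permutation-test calibration.

Per-hippocampal-voxel drift rates follow a linear profile along the
longitudinal (y) axis: ``delta(v) = delta_hpc * (1 + gradient_slope *
(y_v - mean_y))``.  A positive slope makes anterior voxels (larger y) drift
faster, which downstream yields voxel drift scores that correlate
negatively with y — the anterior-to-posterior gradient the analysis tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .preprocess import SessionImage, bandpass_matrix, write_labels, write_session

__all__ = [
    "SessionSchedule",
    "PhantomLayout",
    "GeneratorParams",
    "GroundTruth",
    "make_schedule",
    "make_layout",
    "simulate_covariates",
    "simulate_weights",
    "simulate_sessions",
    "write_dataset",
    "DEFAULT_DRIFT_STEP",
    "DEFAULT_BETA_HORMONE",
]

#: Default per-day random-walk step in connectivity-weight space.  Calibrated
#: once with the pooled-pair Monte-Carlo oracle (>= 10,000 session pairs
#: across full generative replicates) so that the population temporal drift
#: score on the 30-daily-session schedule is about -0.2, the magnitude
#: reported for entorhinal seeds in month-long dense-sampling data.
DEFAULT_DRIFT_STEP = 0.009

#: Default hormone->weight coupling used when the hormone confound channel is
#: switched on (weight displacement per unit of the hormone series).
DEFAULT_BETA_HORMONE = 0.035

#: Morning-to-evening spacing for the male schedule, in days (7 am -> 8 pm).
SAME_DAY_SPACING_DAYS = 13.0 / 24.0

_FEMALE_HORMONES = {
    # name -> (period_days, phase_rad)
    "estradiol": (28.0, 0.0),
    "progesterone": (28.0, np.pi),
    "lh": (28.0, np.pi / 2),
    "fsh": (28.0, 3 * np.pi / 2),
}
_MALE_HORMONES = {
    "estradiol": (7.0, 0.0),
    "testosterone": (1.0, 0.0),
    "cortisol": (1.0, np.pi / 2),
}

QUESTIONNAIRES = ("pss", "stai", "pom_tension", "pom_depression")


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSchedule:
    """Session identifiers and elapsed time in days since the first session."""

    session_ids: tuple[str, ...]
    t_days: np.ndarray
    design_label: str

    def __post_init__(self) -> None:
        t = np.asarray(self.t_days, dtype=float)
        object.__setattr__(self, "t_days", t)
        if len(self.session_ids) != len(t):
            raise ConfigurationError("session_ids and t_days lengths differ")
        if len(t) == 0:
            raise ConfigurationError("schedule must contain at least one session")
        if t[0] != 0.0:
            raise ConfigurationError("first session must be at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("session times must be strictly increasing")

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)


def make_schedule(
    design: str, times: Sequence[float] | None = None
) -> SessionSchedule:
    """Build a sampling schedule.

    ``"female30"`` is one session per day for 30 consecutive days
    (t = 0..29).  ``"male40"`` is 40 sessions over 30 days: morning sessions
    on days 0-9, morning and evening sessions on days 10-19, evening
    sessions on days 20-29, with morning and evening 13 h apart.  A
    ``"custom"`` design echoes the supplied times verbatim.
    """
    if design == "female30":
        t = np.arange(30.0)
    elif design == "male40":
        t_list: list[float] = []
        for d in range(30):
            if d < 10:
                t_list.append(float(d))
            elif d < 20:
                t_list.append(float(d))
                t_list.append(d + SAME_DAY_SPACING_DAYS)
            else:
                t_list.append(d + SAME_DAY_SPACING_DAYS)
        t = np.array(t_list) - t_list[0]
    elif design == "custom":
        if times is None:
            raise ConfigurationError("custom design requires explicit times")
        t = np.asarray(list(times), dtype=float)
    else:
        raise ConfigurationError(f"unknown schedule design {design!r}")
    ids = tuple(f"ses-{i + 1:02d}" for i in range(len(t)))
    return SessionSchedule(session_ids=ids, t_days=t, design_label=design)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomLayout:
    """Voxel coordinate table for the phantom.

    ``voxels`` has columns ``voxel_id, i, j, k, x_mm, y_mm, z_mm, label,
    subregion``.  Seed labels (``ec_al, ec_pm, hpc, control_m1,
    control_prc``) are disjoint; every remaining (target) voxel belongs to
    exactly one network label.  Hippocampal voxels carry ``ahpc``/``phpc``
    subregion tags split at the midpoint of their y range.
    """

    voxels: pd.DataFrame
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    seed_labels: tuple[str, ...]
    network_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        hpc_y = self.voxels.loc[self.voxels["label"] == "hpc", "y_mm"]
        if hpc_y.nunique() < 10:
            raise ConfigurationError(
                "hippocampal voxels must span >= 10 distinct y_mm values"
            )

    @property
    def target_ids(self) -> np.ndarray:
        mask = self.voxels["label"].isin(self.network_labels)
        return self.voxels.loc[mask, "voxel_id"].to_numpy()

    def label_ids(self, *labels: str) -> np.ndarray:
        return self.voxels.loc[
            self.voxels["label"].isin(labels), "voxel_id"
        ].to_numpy()

    def network_members(self) -> pd.Series:
        """Map target voxel_id -> network label."""
        mask = self.voxels["label"].isin(self.network_labels)
        sub = self.voxels.loc[mask]
        return pd.Series(sub["label"].to_numpy(), index=sub["voxel_id"].to_numpy())

    def hpc_table(self) -> pd.DataFrame:
        return self.voxels[self.voxels["label"] == "hpc"].reset_index(drop=True)


def make_layout(
    n_networks: int = 17,
    voxels_per_network: int = 18,
    n_hpc_voxels: int = 20,
    n_roi_voxels: int = 6,
    spacing_mm: float = 2.0,
) -> PhantomLayout:
    """Build the default phantom layout on a regular 2-mm grid.

    Hippocampal voxels form a strip along the j (y) axis; y is
    anterior-positive, so larger y = more anterior.  Targets occupy a
    separate grid plane, one row of the plane per network.
    """
    if n_hpc_voxels < 10:
        raise ConfigurationError("need >= 10 hippocampal voxels")
    nj = max(n_hpc_voxels, voxels_per_network, 2 * n_roi_voxels + 4)
    ni = max(n_networks, 8)
    grid_shape = (ni, nj, 4)
    # RAS-positive affine; origin places the hpc strip at posterior y values,
    # as for a left hippocampus in standard space.
    affine = np.array(
        [
            [spacing_mm, 0, 0, -spacing_mm * ni / 2],
            [0, spacing_mm, 0, -spacing_mm * (nj + 2)],
            [0, 0, spacing_mm, 0.0],
            [0, 0, 0, 1.0],
        ]
    )

    rows: list[tuple] = []

    def add(i: int, j: int, k: int, label: str, subregion: str = "") -> None:
        x = affine[0, 0] * i + affine[0, 3]
        y = affine[1, 1] * j + affine[1, 3]
        z = affine[2, 2] * k + affine[2, 3]
        rows.append((len(rows), i, j, k, x, y, z, label, subregion))

    for j in range(n_hpc_voxels):
        sub = "ahpc" if j >= n_hpc_voxels // 2 else "phpc"
        add(3, j, 1, "hpc", sub)
    for j in range(n_roi_voxels):
        add(5, nj - n_roi_voxels + j, 1, "ec_al", "ec_al")
    for j in range(n_roi_voxels):
        add(5, j, 1, "ec_pm", "ec_pm")
    for j in range(n_roi_voxels):
        add(7, j, 3, "control_m1")
    for j in range(n_roi_voxels):
        add(7, nj - n_roi_voxels + j, 3, "control_prc")
    networks = tuple(f"net{n + 1:02d}" for n in range(n_networks))
    for n, name in enumerate(networks):
        for j in range(voxels_per_network):
            add(n, j, 2, name)

    voxels = pd.DataFrame(
        rows,
        columns=["voxel_id", "i", "j", "k", "x_mm", "y_mm", "z_mm", "label", "subregion"],
    )
    return PhantomLayout(
        voxels=voxels,
        affine=affine,
        grid_shape=grid_shape,
        seed_labels=("ec_al", "ec_pm", "hpc", "control_m1", "control_prc"),
        network_labels=networks,
    )


# ---------------------------------------------------------------------------
# Generator parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the phantom generator.

    ``drift_step`` is the per-sqrt(day) random-walk step size in weight
    space for the entorhinal-anterolateral seed and the hippocampal strip;
    the posteromedial seed defaults to half of it and the control seeds to
    zero.  ``gradient_slope`` is the relative change of the hippocampal
    per-voxel step per mm of y.  ``beta_*`` couple session covariates to
    weight displacements.  ``sigma`` is the observation-noise SD in units
    of the (unit-variance) latent signals, and ``seed_error_scale``
    multiplies the seed-series measurement error; its default puts the
    phantom's between-session pattern similarity near Fisher z = 1, the
    level typical of seed-map test-retest reliability.
    """

    n_timepoints: int = 200
    tr_s: float = 0.72
    f_lo: float = 0.01
    f_hi: float = 0.1
    drift_step: float = DEFAULT_DRIFT_STEP
    drift_step_pm: float | None = None
    drift_step_controls: float = 0.0
    gradient_slope: float = 0.05
    drift_mode: str = "walk"
    drift_networks: tuple[str, ...] | None = None
    w_scale: float = 3.0
    sigma: float = 0.5
    seed_error_scale: float = 1.0
    roi_texture_scale: float = 0.3
    beta_hormone: float = 0.0
    beta_motion: float = 0.0
    beta_emotion: float = 0.0
    hormone_amplitude: float = 1.0
    hormone_noise_sd: float = 0.2
    hormone_period_days: float = 28.0
    emotion_scale: float = 1.0
    emotion_ar: float = 0.5
    questionnaire_loadings: tuple[float, float, float, float] = (0.9, 0.9, 0.9, 0.9)
    fd_base: float = 0.12
    fd_scale: float = 1.0
    noise_mode: str = "exchangeable"

    def __post_init__(self) -> None:
        if self.noise_mode not in ("exchangeable", "white"):
            raise ConfigurationError(f"unknown noise_mode {self.noise_mode!r}")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.seed_error_scale <= 0:
            raise ConfigurationError("seed_error_scale must be positive")
        if self.roi_texture_scale < 0:
            raise ConfigurationError("roi_texture_scale must be non-negative")
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")
        if self.drift_step < 0 or self.drift_step_controls < 0:
            raise ConfigurationError("drift steps must be non-negative")
        if self.drift_step_pm is not None and self.drift_step_pm < 0:
            raise ConfigurationError("drift_step_pm must be non-negative")
        if self.drift_mode not in ("walk", "linear"):
            raise ConfigurationError(f"unknown drift_mode {self.drift_mode!r}")
        if self.n_timepoints < 8:
            raise ConfigurationError("n_timepoints too small for band-limited signals")

    def entity_deltas(self, layout: PhantomLayout) -> dict[str, float]:
        """Resolve the per-entity drift step, applying the hpc y gradient.

        Raises
        ------
        ConfigurationError
            If the gradient profile drives any per-voxel step negative.
        """
        pm = self.drift_step / 2.0 if self.drift_step_pm is None else self.drift_step_pm
        deltas = {
            "ec_al": self.drift_step,
            "ec_pm": pm,
            "control_m1": self.drift_step_controls,
            "control_prc": self.drift_step_controls,
        }
        hpc = layout.hpc_table()
        y_centered = hpc["y_mm"].to_numpy() - hpc["y_mm"].mean()
        for vid, yc in zip(hpc["voxel_id"], y_centered):
            d = self.drift_step * (1.0 + self.gradient_slope * yc)
            if d < 0:
                raise ConfigurationError(
                    f"gradient profile gives negative drift step ({d:.4g}) at "
                    f"hippocampal voxel {vid}; reduce gradient_slope"
                )
            deltas[f"hpc_{vid}"] = d
        return deltas


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    schedule: SessionSchedule,
    params: GeneratorParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Per-session covariate table: hormones, motion, questionnaires.

    Hormone series are smooth cyclic functions of elapsed time plus noise
    (cycle lengths chosen per schedule design: 28-day menstrual-like cycles
    for ``female30``, shorter/circadian cycles for ``male40``).  The four
    questionnaire scores load on one latent emotion factor; the latent
    factor itself is included as the ``emotion_latent`` column — it is
    ground truth, not an observable, and downstream emotion aggregation
    must use the questionnaire columns only.
    """
    rng = _as_rng(seed)
    t = schedule.t_days
    n = schedule.n_sessions
    if schedule.design_label == "female30":
        hormones = _FEMALE_HORMONES
    elif schedule.design_label == "male40":
        hormones = _MALE_HORMONES
    else:
        hormones = {"hormone": (params.hormone_period_days, 0.0)}

    table: dict[str, np.ndarray] = {
        "session_id": np.array(schedule.session_ids),
        "t_days": t,
    }
    # The study start falls at an arbitrary point of the endocrine cycle, so
    # all hormones share one random phase offset (relative phases fixed).
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    for name, (period, phase) in hormones.items():
        clean = params.hormone_amplitude * np.sin(
            2 * np.pi * t / period + phase + phase0
        )
        table[name] = clean + params.hormone_noise_sd * rng.standard_normal(n)

    table["mean_fd"] = params.fd_base + params.fd_scale * rng.gamma(3.0, 0.02, size=n)

    # AR(1) latent emotion factor, stationary unit variance before scaling.
    eps = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = eps[0]
    phi = params.emotion_ar
    for s in range(1, n):
        e[s] = phi * e[s - 1] + np.sqrt(1 - phi**2) * eps[s]
    e *= params.emotion_scale
    table["emotion_latent"] = e
    for name, loading in zip(QUESTIONNAIRES, params.questionnaire_loadings):
        noise_sd = np.sqrt(max(1.0 - loading**2, 0.0)) * params.emotion_scale
        table[name] = loading * e + noise_sd * rng.standard_normal(n)

    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Latent weights and sessions
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """The generator's latent state, for recovery tests.

    ``weights`` maps each drifting entity to its ``(n_sessions, n_targets)``
    latent weight trajectory (covariate displacements included);
    ``deltas`` holds the per-entity drift step actually applied;
    ``couplings[channel]`` is that covariate channel's per-session weight
    displacement trajectory, shared by all entities (covariate effects on
    connectivity are systematic, not seed-specific).
    """

    weights: dict[str, np.ndarray]
    deltas: dict[str, float]
    couplings: dict[str, np.ndarray]
    target_ids: np.ndarray
    covariates: pd.DataFrame | None = None

    def to_json(
        self, path: str | Path, include_weights: bool = False
    ) -> None:
        payload: dict = {
            "deltas": {k: float(v) for k, v in self.deltas.items()},
            "target_ids": self.target_ids.tolist(),
            "couplings": {
                name: disp.tolist() for name, disp in self.couplings.items()
            },
        }
        if include_weights:
            payload["weights"] = {k: w.tolist() for k, w in self.weights.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)


def drift_entities(layout: PhantomLayout) -> dict[str, np.ndarray]:
    """Map each drifting entity name to the seed voxel ids it occupies."""
    entities: dict[str, np.ndarray] = {
        "ec_al": layout.label_ids("ec_al"),
        "ec_pm": layout.label_ids("ec_pm"),
        "control_m1": layout.label_ids("control_m1"),
        "control_prc": layout.label_ids("control_prc"),
    }
    for vid in layout.hpc_table()["voxel_id"]:
        entities[f"hpc_{vid}"] = np.array([vid])
    return entities


def simulate_weights(
    schedule: SessionSchedule,
    layout: PhantomLayout,
    params: GeneratorParams,
    seed: int | np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> GroundTruth:
    """Simulate the latent weight trajectories for every drifting entity."""
    rng = _as_rng(seed)
    targets = layout.target_ids
    n_tg = len(targets)
    deltas = params.entity_deltas(layout)
    entities = drift_entities(layout)

    if params.drift_networks is not None:
        unknown = set(params.drift_networks) - set(layout.network_labels)
        if unknown:
            raise ConfigurationError(f"unknown drift networks: {sorted(unknown)}")
        net = layout.network_members().loc[targets].to_numpy()
        step_mask = np.isin(net, list(params.drift_networks))
        if not step_mask.any():
            raise ConfigurationError("drift_networks selects no target voxels")
    else:
        step_mask = np.ones(n_tg, dtype=bool)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    couplings_on = [
        ("hormone", params.beta_hormone),
        ("motion", params.beta_motion),
        ("emotion", params.beta_emotion),
    ]
    if any(beta != 0 for _, beta in couplings_on) and covariates is None:
        raise ConfigurationError(
            "covariate couplings are non-zero but no covariate table was given"
        )
    cov_series: dict[str, np.ndarray] = {}
    if covariates is not None:
        hormone_cols = [
            c
            for c in covariates.columns
            if c
            not in ("session_id", "t_days", "mean_fd", "emotion_latent")
            + QUESTIONNAIRES
        ]
        cov_series["hormone"] = covariates[hormone_cols[0]].to_numpy()
        cov_series["motion"] = covariates["mean_fd"].to_numpy()
        cov_series["emotion"] = covariates["emotion_latent"].to_numpy()

    t = schedule.t_days
    # One displacement trajectory per covariate channel, shared by all
    # entities: covariate effects on connectivity are systematic.
    couplings: dict[str, np.ndarray] = {}
    for cov_name, beta in couplings_on:
        if beta != 0.0:
            couplings[cov_name] = _covariate_walk(
                cov_series[cov_name], beta, step_mask, rng
            )
    weights: dict[str, np.ndarray] = {}
    for name in entities:
        delta = deltas[name]
        w0 = params.w_scale * unit(rng.standard_normal(n_tg))
        traj = np.empty((schedule.n_sessions, n_tg))
        if params.drift_mode == "linear":
            direction = np.where(step_mask, rng.standard_normal(n_tg), 0.0)
            direction = unit(direction)
            for s in range(schedule.n_sessions):
                traj[s] = w0 + delta * t[s] * direction
        else:
            w = w0.copy()
            traj[0] = w
            for s in range(1, schedule.n_sessions):
                eta = np.where(step_mask, rng.standard_normal(n_tg), 0.0)
                w = w + delta * np.sqrt(t[s] - t[s - 1]) * unit(eta)
                traj[s] = w
        for disp in couplings.values():
            traj += disp
        weights[name] = traj

    return GroundTruth(
        weights=weights,
        deltas=deltas,
        couplings=couplings,
        target_ids=targets,
        covariates=covariates,
    )


def _covariate_walk(
    values: np.ndarray,
    beta: float,
    step_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Equal-norm weight displacements with Brownian covariate geometry.

    Sessions are embedded isometrically on a sphere in weight space so that
    ``<D_i, D_j> = c - beta**2 * |h_i - h_j| / 2`` exactly (``c`` the
    smallest constant keeping the Gram matrix positive semidefinite), i.e.
    squared displacement between two sessions is ``beta**2 * |h_i - h_j|``
    — the linear-in-|delta| geometry of a Brownian path — while every
    session sits at the same distance from the origin.  The constant norm
    keeps the covariate channel free of session-level similarity shifts
    that would masquerade as other predictors in the pairwise regression.
    The embedding is rotated into the target space by a random orthonormal
    frame (restricted to ``step_mask`` voxels).
    """
    n, n_tg = len(values), step_mask.size
    dist = np.abs(values[:, None] - values[None, :])
    c0 = beta**2 * dist.max() / 2.0
    gram = c0 - beta**2 * dist / 2.0
    evals, evecs = np.linalg.eigh(gram)
    coords = evecs * np.sqrt(np.clip(evals, 0.0, None))  # n x n
    g = np.where(step_mask[:, None], rng.standard_normal((n_tg, n)), 0.0)
    frame, r = np.linalg.qr(g)
    frame = frame * np.sign(np.diag(r))
    return coords @ frame.T


def _observation_noise(
    target_rows: np.ndarray,
    entity_rows: list[np.ndarray],
    u: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
    avoid: np.ndarray | None = None,
) -> np.ndarray:
    """Observation noise for one session's voxel x time matrix.

    ``"white"`` mode is plain i.i.d. Gaussian noise.  In ``"exchangeable"``
    mode (default) the noise is constructed so that a session's
    connectivity-map error carries no session-level energy fluctuations,
    which makes null pattern-similarity fluctuations exchangeable across
    session pairs — the condition under which the pair-label permutation
    null is exact (see the methods note):

    * target-voxel noise is a scaled Haar-random frame with orthonormal
      columns supported on the orthogonal complement of the latent-signal
      subspace, so the energy it projects onto any temporal direction is a
      constant and its sample cross-products with every latent signal
      vanish exactly;
    * each seed entity's measurement error is a fixed-norm random
      direction in the same complement (norm ``sigma * sqrt(n_t / n_roi)``,
      emulating ROI-averaged voxel noise), shared by the entity's voxels,
      plus per-voxel jitter that is mean-centered within the entity and so
      never reaches the entity's measured series.

    ``avoid`` is an optional orthonormal basis in target-voxel space; the
    target noise frame is built orthogonal to it.  It carries the span of
    the covariate weight displacements, so covariate channels contribute
    their deterministic similarity structure without extra pair noise.
    """
    n_vox = len(target_rows)
    n_t = params.n_timepoints
    if params.noise_mode == "white":
        return params.sigma * rng.standard_normal((n_vox, n_t))
    n_tg = int(target_rows.sum())
    n_comp = n_t - u.shape[0]
    if n_comp < 2 or n_tg < n_comp:
        raise ConfigurationError(
            "exchangeable noise needs n_targets >= n_timepoints - n_entities "
            ">= 2; use noise_mode='white'"
        )
    # Orthonormal basis of the complement of the latent rows of u.
    q_full = np.linalg.qr(u.T, mode="complete")[0]
    basis = q_full[:, u.shape[0]:]  # n_t x n_comp

    if avoid is not None and n_tg < n_comp + avoid.shape[1]:
        raise ConfigurationError(
            "exchangeable noise cannot avoid the covariate subspace: too few "
            "target voxels; use noise_mode='white'"
        )

    def _frame(g: np.ndarray) -> np.ndarray:
        if avoid is not None:
            g = g - avoid @ (avoid.T @ g)
        q, r = np.linalg.qr(g)
        return q * np.sign(np.diag(r))

    noise = np.zeros((n_vox, n_t))
    q = _frame(rng.standard_normal((n_tg, n_comp)))
    # Balance row norms (keeping columns orthonormal) so per-voxel noise
    # energies are near-constant and do not jitter the per-voxel
    # correlation denominators session by session.
    for _ in range(2):
        q = _frame(q / np.linalg.norm(q, axis=1, keepdims=True))
    scale = params.sigma * np.sqrt(n_tg * n_t / n_comp)
    noise[target_rows] = (scale * q) @ basis.T

    for rows in entity_rows:
        direction = rng.standard_normal(n_comp)
        direction /= np.linalg.norm(direction)
        xi = (
            params.seed_error_scale
            * params.sigma
            * np.sqrt(n_t / len(rows))
            * (basis @ direction)
        )
        noise[rows] += xi
        if len(rows) > 1:
            # within-entity voxel texture, also in the latent complement and
            # mean-centered so it never reaches the entity's measured series
            raw = rng.standard_normal((len(rows), n_comp)) @ basis.T
            jitter = params.roi_texture_scale * params.sigma * raw
            noise[rows] += jitter - jitter.mean(axis=0)
    return noise


def _latent_signals(
    n_entities: int, params: GeneratorParams, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited, mutually orthogonal unit-variance latent signals.

    Orthogonality is imposed in-sample (QR within the band-limited subspace)
    so each seed's empirical connectivity map isolates that seed's own
    weight vector; see the package methods note for why.
    """
    raw = rng.standard_normal((n_entities, params.n_timepoints))
    banded = bandpass_matrix(raw, params.tr_s, params.f_lo, params.f_hi)
    q, r = np.linalg.qr(banded.T)  # columns orthonormal
    q = q * np.sign(np.diag(r))  # sign-fix for reproducibility
    return q.T * np.sqrt(params.n_timepoints)


def simulate_sessions(
    schedule: SessionSchedule,
    layout: PhantomLayout,
    params: GeneratorParams,
    covariates: pd.DataFrame | None,
    seed: int | np.random.Generator,
) -> tuple[list[SessionImage], GroundTruth]:
    """Generate one phantom session image per scheduled session.

    Returns the session images (voxel order follows ``layout.voxels``) and
    the ground truth needed for recovery tests.
    """
    rng = _as_rng(seed)
    truth = simulate_weights(schedule, layout, params, rng, covariates)
    entities = drift_entities(layout)
    entity_names = list(entities)
    targets = truth.target_ids
    n_vox = len(layout.voxels)
    target_rows = layout.voxels["voxel_id"].isin(targets).to_numpy()
    vid_to_row = pd.Series(np.arange(n_vox), index=layout.voxels["voxel_id"])
    entity_rows = [vid_to_row.loc[entities[e]].to_numpy() for e in entity_names]

    avoid = None
    if truth.couplings and params.noise_mode == "exchangeable":
        disp = np.concatenate(list(truth.couplings.values()), axis=0).T
        q, r = np.linalg.qr(disp)
        rank = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
        avoid = q[:, rank]

    images: list[SessionImage] = []
    for s, sid in enumerate(schedule.session_ids):
        u = _latent_signals(len(entity_names), params, rng)
        signal = _observation_noise(
            target_rows, entity_rows, u, params, rng, avoid
        )
        w_mat = np.stack([truth.weights[e][s] for e in entity_names])
        signal[target_rows] += w_mat.T @ u
        for e_idx, name in enumerate(entity_names):
            signal[entity_rows[e_idx]] += u[e_idx]
        images.append(
            SessionImage(
                session_id=sid,
                signal=signal,
                voxels=layout.voxels,
                tr_s=params.tr_s,
                affine=layout.affine,
                grid_shape=layout.grid_shape,
            )
        )
    return images, truth


# ---------------------------------------------------------------------------
# Dataset serialization
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    images: Sequence[SessionImage],
    layout: PhantomLayout,
    schedule: SessionSchedule,
    covariates: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
    include_weights: bool = False,
) -> Path:
    """Write a phantom dataset: per-session 4-D NIfTIs, a label mask NIfTI,
    a sessions TSV sidecar, and (optionally) a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels(
        layout.voxels, layout.affine, layout.grid_shape,
        out / "labels.nii.gz", out / "labels.json",
    )
    for image in images:
        write_session(image, out / f"{image.session_id}_bold.nii.gz")
    covariates.to_csv(out / "sessions.tsv", sep="\t", index=False)
    meta = {
        "design_label": schedule.design_label,
        "tr_s": float(images[0].tr_s) if images else None,
        "session_ids": list(schedule.session_ids),
        "t_days": schedule.t_days.tolist(),
    }
    with open(out / "dataset.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    if ground_truth is not None:
        ground_truth.to_json(out / "ground_truth.json", include_weights)
    return out
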