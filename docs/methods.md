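# Methods

## The statistic

`driftconn` quantifies whether a brain region's whole-brain resting-state
functional-connectivity pattern drifts with elapsed time across a
dense-sampling study (tens of sessions over about a month).  For a seed
region *s* and session *i*, the connectivity pattern is the vector of
Pearson correlations between the seed's (ROI-averaged or single-voxel) time
series and every gray-matter target voxel's series, Fisher-Z transformed.
For every unordered session pair *(i, j)* the **pattern similarity**
`Z_ij = arctanh(corr(map_i, map_j))` is computed over target voxels, and
pairs whose similarity deviates more than 3 SD from the mean over all pairs
(per seed) are excluded once, before any inference.  The **temporal drift
score** is

    r_drift = Pearson(Z_ij, Δt_ij)   over included pairs,

with `Δt_ij` the elapsed time in days (fractional for same-day
morning/evening pairs, 13/24 day apart).  Negative scores mean patterns
grow more dissimilar with time.  Inference uses (a) the two-tailed
parametric *t* transform of *r* with `n_pairs − 2` degrees of freedom and
(b) a one-tailed (lower-tail) permutation null built by shuffling the
`Δt` labels across included pairs (default 5000 shuffles) with the add-one
rule `p = (1 + #{r_null ≤ r_obs}) / (1 + n_shuffles)`; ties with the
observed score count as at-least-as-extreme.  Pair non-independence (pairs
share sessions) is deliberately not corrected beyond this label-shuffle
scheme; that is the published procedure, and its behavior under
session-level noise is discussed below.

Downstream statistics reuse the same pair machinery:

- **Voxel-wise drift and the longitudinal gradient.**  Single hippocampal
  voxels serve as seeds (the 3-SD screen is applied per voxel-seed); the
  gradient test correlates voxel drift scores with the anterior-positive
  y coordinate and builds its null by shuffling the y coordinates across
  voxels (one-tailed, fixed lower tail — the a-priori hypothesis is faster
  anterior drift, hence a negative correlation).  Entorhinal voxel scores
  are averaged per subregion (anterolateral vs posteromedial).
- **Seed comparisons.**  Two seeds' drift scores share the `Δt` variable,
  so they are compared with the Meng–Rosenthal–Rubin overlapping
  dependent-correlation z test, using the correlation between the two
  seeds' similarity vectors over the intersection of their included pairs.
- **Covariate control.**  Per-pair absolute covariate differences
  (hormones, mean framewise displacement, emotion score) enter an OLS
  regression of `Z_ij` on `[1, Δt, |Δh|, |ΔFD|, |Δemotion|]` with
  classical standard errors.  The emotion score is the first principal
  component of the standardized mood questionnaires (correlation-matrix
  PCA; sign fixed so the first questionnaire loads positively; the
  variance-explained figures are squared variable–component correlations).
- **Network decomposition.**  Similarity restricted to one network's
  target voxels yields per-network drift scores; permutation p-values are
  Benjamini–Hochberg adjusted across the networks.  Heterogeneity across
  networks is tested with a tie-corrected Kruskal–Wallis H over
  per-subject-per-network drift scores, calibrated by re-shuffling each
  subject's `Δt` labels (one shared shuffle per subject per iteration) and
  recomputing every score and H.

Preprocessing reduces to its statistical content: OLS nuisance regression
(six motion parameters plus CSF/WM mean signals; a constant and linear
trend are always included — the filter needs detrended input and the
published description is silent on this) followed by an ideal FFT band-pass
(0.01 < f < 0.1 Hz, strict inequalities, mean removed).  The ideal mask
documents the exact passband and keeps its tests analytic; no IIR variant
is offered.

## The phantom generator

Real month-long dense-sampling datasets cannot be re-analyzed at desk
scale, so every statistical claim is validated on a phantom whose ground
truth is known.  The phantom is a coordinate table, not a brain: seed ROIs
(anterolateral/posteromedial entorhinal cortex, a 20-voxel hippocampal
strip spanning 38 mm of the longitudinal axis, motor-cortex and perirhinal
control sites) plus 306 target voxels partitioned into 17 networks, on a
2-mm grid with an RAS-positive affine (rendering to 4-D NIfTI is a thin
serialization layer).

Each drifting *entity* (a seed ROI, or each hippocampal voxel separately)
carries a latent weight vector `w_s` over targets (base norm `w_scale = 3`).
Between sessions the weights take a random-walk step
`w_s = w_{s−1} + δ·√Δt·η` with a fresh unit direction `η`, so expected
squared displacement grows linearly in elapsed time and pattern similarity
decays monotonically with the interval for every pair (a linear-in-time
drift mode is available as an option).  Within a session each entity emits
a band-limited (0.01–0.1 Hz) unit-variance latent signal; target voxels
record the weighted sum of latent signals plus observation noise
(`sigma = 0.5`), seed voxels their entity's signal plus measurement error.
The per-voxel hippocampal step follows a linear profile
`δ(v) = δ_hpc·(1 + slope·(y_v − ȳ))`; a positive slope makes anterior
voxels drift faster, which yields voxel drift scores that correlate
negatively with y — the direction reported for the human hippocampus.
A configuration whose profile would drive any step negative is rejected.

Covariates are generated per session: smooth cyclic hormone series
(28-day cycles for the daily female-style schedule, shorter/circadian
cycles for the morning/evening male-style schedule; one shared random
phase per dataset, since the study start falls at an arbitrary cycle
point), a gamma-distributed mean framewise displacement, and four
questionnaire scores loading 0.9 on one AR(1) latent emotion factor.  A
covariate channel with coupling `β` displaces the weights of every entity
along a common trajectory constructed as a spherical isometric embedding
of the sessions: `⟨D_i, D_j⟩ = c − β²|h_i − h_j|/2` exactly, with constant
norms.  Squared weight displacement between two sessions is then exactly
proportional to the absolute covariate difference — the linear-in-|Δ|
geometry the pairwise regression models — with no session-position terms
that could masquerade as other predictors.

### Why the observation noise is constrained

The pair-label permutation null treats the included pairs' similarities as
exchangeable.  With unconstrained white observation noise they are not:
each session's map-noise energy fluctuates (chi-square), and every pair
containing that session inherits the fluctuation.  These session-level
("row") components make the label-shuffle test anti-conservative — with
plain white noise at this phantom scale we measure a rejection rate of
about 0.15 at nominal 0.05, and an abstract row/pair variance-share model
reproduces that figure.  Real resting-state data contain such session-level
components (global SNR differences, residual motion), so this
anti-conservativeness is a genuine caveat for the published test; it is
*not* something the analysis code can fix without changing the published
procedure.

The phantom's job, however, is to provide data that satisfy the
assumptions the analysis makes, so the default `noise_mode="exchangeable"`
removes the session-level components by construction:

- target-voxel noise is a scaled Haar-random frame with orthonormal
  columns supported on the orthogonal complement of the latent-signal
  subspace — the noise energy projected onto *any* temporal direction is a
  constant, and sample cross-products with every latent signal vanish
  exactly; row norms are balanced so per-voxel correlation denominators do
  not jitter across sessions;
- each entity's seed measurement error is a fixed-norm random direction in
  the same complement, with norm `seed_error_scale·σ·√(T/n_roi)`
  (emulating ROI-averaged voxel noise); within-ROI texture
  (`roi_texture_scale = 0.3`) is mean-centered inside the entity so it
  never reaches the measured seed series;
- when covariate couplings are active, the target-noise frame is also
  built orthogonal to the covariate displacement span, so confound
  channels contribute their deterministic similarity structure without
  extra structured pair noise.

`noise_mode="white"` retains plain i.i.d. noise for studying the
uncorrected behavior.

### Calibrated defaults

Where the design targets a stated operating point, the corresponding
default was calibrated once against that target and frozen:

- `drift_step = 0.009` per √day: the *population* drift score of the full
  generative process on the 30-daily-session schedule — defined as the
  pooled Pearson correlation over ≥10,000 (Δt, similarity) pairs drawn
  across independent replicates — is ≈ −0.2, the magnitude reported for
  entorhinal seeds in month-long human data.  The drift score is invariant
  to rescaling of the similarities, so this population value is set by the
  ratio of drift-induced decay to observation-level similarity noise, not
  by δ alone; the Monte-Carlo definition therefore includes the
  observation stage.
- `drift_step_pm = drift_step/2`: the posteromedial entorhinal seed drifts
  at half the anterolateral rate, giving a recoverable subregion ordering.
- `gradient_slope = 0.05` per mm: the anterior-most hippocampal voxel
  drifts ≈ 2×, the posterior-most ≈ 0.05× the base rate, an unambiguous
  linear contrast that the y-shuffle test detects reliably at this phantom
  scale.  Control seeds default to zero drift.
- `beta_hormone = 0.035` (when the hormone channel is switched on): large
  enough that the pairwise regression flags the hormone delta essentially
  always, small enough that the similarity response stays in the linear
  regime of the Fisher transform.
- `n_timepoints = 200`, `TR = 0.72 s`, 306 targets: the phantom scale used
  throughout the simulation studies.

## What passing tests do and do not show

The phantom reproduces the *statistical skeleton* of a dense-sampling
drift analysis: monotone similarity decay from a weight-space random walk,
a linear drift-rate gradient along an anatomical axis, covariate channels
with known couplings, exchangeable null similarity noise.  It deliberately
omits realistic hemodynamics, spatial autocorrelation, physiological noise
and motion artifacts, and its between-session similarity level (Fisher
z ≈ 3 under the default noise) is higher than real seed-map test-retest
values (z ≈ 1); the drift statistics are functions of similarity
*differences*, not levels, so this does not affect the operating
characteristics being tested, but absolute similarity values from the
phantom should not be compared with real data.  Passing the calibration
and recovery suites shows the pipeline is correct and well calibrated
*under its own assumptions*; on real data, session-level noise components
can make the pair-label permutation null anti-conservative (see above),
and the pair-regression t statistics inherit the same caveat.

## Numerical choices

- Correlations are clipped to |r| ≤ 1 − 1e−7 before `arctanh`; inputs
  beyond |r| > 1 + 1e−12 are domain errors.
- Zero-variance target voxels map to z = 0 (with a warning) so the target
  dimension is constant across sessions; zero-variance seeds are errors.
- The 3-SD outlier screen uses the sample SD (ddof = 1), a single pass,
  no re-iteration; zero SD excludes nothing and warns.
- Permutation p-values use the add-one rule and count ties (within 1e−12)
  as at-least-as-extreme; they are never exactly zero.
- OLS uses classical (homoscedastic) standard errors throughout, matching
  the published analysis; rank-deficient designs are rejected with the
  collinear columns named (QR with column pivoting).
- The Meng dependent-correlation test caps the `f` factor at 1, per the
  published formula.
- All randomness flows from `numpy.random.Generator`; identical seeds give
  bit-identical phantoms, and simulation studies spawn child generators
  from a single `SeedSequence`.

## Problem sizes used in the simulation studies

Null calibration: 200 replicates × 500 shuffles.  Drift recovery: 100
replicates, population reference from ≈30,000 pooled Monte-Carlo pairs.
Gradient: 100 replicates (power) and 200 (null).  Confound separation:
100 replicates.  Each replicate simulates 30 sessions × 350 voxels × 200
timepoints and runs the full pipeline; the complete battery takes a few
minutes on one CPU.

## Known limitations

- Exchangeable-noise mode requires at least as many target voxels as
  `n_timepoints − n_entities` (and room for the covariate subspace);
  smaller phantoms must fall back to white noise.
- The male-style schedule's same-day pairs are included with Δt = 13/24
  day by default; `drop_same_day` removes all sub-day pairs instead.  The
  published description does not state which was done.
- Network-restricted similarity uses the whole-brain map restricted to the
  network's voxels, which equals computing the map against the network
  mask directly.
- The Kruskal–Wallis permutation couples networks within a subject through
  one shared label shuffle per iteration; the published description does
  not specify the coupling, and the choice is configurable by providing
  different subject tables.
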