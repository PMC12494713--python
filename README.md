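# driftconn

Temporal drift of seed-based whole-brain resting-state functional
connectivity patterns.

Dense-sampling fMRI studies scan the same person every day for a month.
Over such timescales, the whole-brain connectivity pattern of medial
temporal seeds — entorhinal cortex and hippocampus — slowly reorganizes:
pattern similarity between two sessions falls off with the time elapsed
between them, even at rest.  `driftconn` implements the statistics used to
detect and characterize that drift, and a phantom generator with known
ground truth so every stage can be validated without any data download.

## The statistic

For seed *s* and session *i*, the connectivity pattern is the Fisher-Z
transformed Pearson correlation of the seed time series with every
gray-matter voxel.  For each unordered session pair,

    Z_ij = arctanh( corr(map_i, map_j) )        pattern similarity
    r_drift = Pearson( Z_ij , Δt_ij )           temporal drift score

over pairs surviving a 3-SD outlier screen.  A negative `r_drift` means
patterns grow more dissimilar with elapsed time.  Significance comes from
the two-tailed parametric test on *r* and from a one-tailed permutation
null (elapsed-time labels shuffled across pairs, add-one p-value).  On top
of this core, the package provides voxel-wise drift maps with a
hippocampal longitudinal-axis gradient test (y-coordinate shuffle null),
Meng–Rosenthal–Rubin comparisons of two seeds' dependent drift scores,
covariate-controlled regression of pair similarity on elapsed time plus
hormone/motion/emotion deltas (with a questionnaire PCA emotion score),
and network-restricted drift with Benjamini–Hochberg FDR and a
permutation-calibrated Kruskal–Wallis heterogeneity test.

Preprocessing is included as its statistical core: OLS nuisance regression
(6 motion parameters + CSF/WM means, constant and trend) and an ideal FFT
band-pass (0.01–0.1 Hz), in that order.  Sessions are read from and
written to 4-D NIfTI with integer-coded label masks and a TSV sidecar.

## Worked example

Simulate a 30-daily-session phantom at the default settings (calibrated so
the population drift score of the generative process is about −0.2) and
score the anterolateral entorhinal seed:

```python
import numpy as np
from driftconn import (GeneratorParams, SeedSpec, make_layout, make_schedule,
                       simulate_covariates, simulate_sessions)
from driftconn.studies import run_seed_pipeline

schedule = make_schedule("female30")          # 30 sessions, t = 0..29 days
layout = make_layout()                        # seeds + 17x18 target voxels
params = GeneratorParams()
rng = np.random.default_rng(7)
covariates = simulate_covariates(schedule, params, rng)
images, truth = simulate_sessions(schedule, layout, params, covariates, rng)

result = run_seed_pipeline(
    images, schedule, SeedSpec.roi("ec_al", "ec_al"), layout.target_ids,
    n_shuffles=5000, rng=1,
)
print(result.summary())
print(f"parametric p = {result.p_parametric:.2e}")
```

```
ec_al: r = -0.292 (n = 435 pairs), permutation p < 0.001
parametric p = 5.54e-10
```

All 435 session pairs survived the outlier screen; similarity declines
with elapsed time (r = −0.29), and no shuffle of the elapsed-time labels
produced a drift score that negative.  The hippocampal gradient on the
same phantom:

```python
from driftconn import gradient_test, voxelwise_drift

vmap = voxelwise_drift(images, layout.hpc_table(), layout.target_ids, schedule)
res = gradient_test(vmap, n_perm=5000, rng=1)
print(f"gradient r = {res.r_gradient:.3f}, permutation p = {res.p_permutation:.4f}")
print(vmap.groupby("subregion")["drift_r"].mean().round(3))
```

```
gradient r = -0.825, permutation p = 0.0002
subregion
ahpc   -0.088
phpc    0.020
```

Voxel drift scores grow more negative toward anterior (larger y) voxels —
the generator's drift-rate gradient is recovered with the expected sign.

A `driftconn` command-line interface wraps the same pipeline over NIfTI
datasets on disk: `driftconn simulate --design female30 --out phantom/`,
then `driftconn drift --data phantom/ --seed-roi ec_al --n-perm 5000`,
plus `gradient`, `networks`, and `regress` subcommands.

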