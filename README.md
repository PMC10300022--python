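# dynstates

Dynamic functional-connectivity brain states for resting-state fMRI, built
around a Gaussian hidden Markov model (HMM) fitted to independent-component
(IC) time courses.

Resting-state FC is usually treated as stationary, but the brain moves
through recurring connectivity regimes on the scale of seconds. This package
implements the full analysis chain used to characterise those regimes in a
two-group (patients vs healthy controls) design — for example, cohorts with
high-grade gliomas — where the clinical questions are: do functional dynamics
survive the pathology, how do pathological states differ in connectivity,
and does a patient's occupancy of a pathological state relate to lesion
features or cognitive scores?

Because clinical rs-fMRI cohorts are rarely shareable, the package ships a
first-class synthetic-cohort generator with known ground truth (hidden state
paths, state covariances, planted group differences, planted cognitive
predictors), so every stage is testable end-to-end and the statistical power
of the group contrasts can be measured rather than assumed.

## The model

Each subject contributes a T x M matrix of z-scored IC time courses
(M components grouped into resting-state networks). The cohort is temporally
concatenated and modelled by a K-state HMM with multivariate-Gaussian
observations:

- hidden chain: initial distribution pi, transition matrix A (row-stochastic),
  shared across subjects; the forward recursion restarts at each subject's
  first volume;
- observation model: x_t | s_t = k  ~  N(mu_k, Sigma_k) with a full M x M
  covariance per state.

Estimation is maximum-likelihood EM (Baum-Welch) with scaled forward-backward
recursions, k-means initialisation and random restarts; model order K is
scanned (default 2..15) and compared by BIC, average log-likelihood per frame
(avLL) and the cross-restart coefficient of variation of occupancy estimates.
From the fitted model the package derives, per subject, the Viterbi state
path, fractional occupancy FO_k (fraction of volumes in state k), switching
rate SR (state changes per second), and empirical transition matrices; per
state, the correlation matrix R_k = D^-1/2 Sigma_k D^-1/2, its proportional
sparsification (strongest 20% of edges by |r|), Laplacian-eigenmap
connectivity gradients with Procrustes alignment, weighted graph metrics
(degree, betweenness, clustering, local/global efficiency) and signed Louvain
consensus modularity. Patient occupancy of a pathological state is finally
regressed on a cognitive battery via collinearity-aware feature clustering
and stepwise OLS.

## Worked example

```python
import numpy as np
from dynstates import (SimConfig, simulate_cohort, zscore_and_concat,
                       GaussianHMM, cohort_dynamics, compare_groups)

cfg = SimConfig(K=4, M=15, n_blocks=5, n_controls=12, n_patients=12,
                T=300, n_pathological=2, seed=7)
subjects, truth = simulate_cohort(cfg)
concat = zscore_and_concat(subjects)
res = GaussianHMM.from_concat(concat, k_states=4).fit(n_restarts=3, seed=7)
print(res.summary())

paths = res.viterbi_paths()
mets = cohort_dynamics(paths, 4, cfg.TR, subject_ids=concat.subject_ids,
                       groups=concat.groups)
table = compare_groups(mets, alpha=0.01)
print(table[["metric", "median_control", "median_patient", "p_fdr", "reject"]]
      .to_string(index=False))
```

Output:

```
Gaussian HMM results
====================
states (K):        4
components (M):    15
observations (N):  7200
subjects:          24
log-likelihood:    -138957.93
avLL per frame:    -19.2997
BIC:               282845.28
EM converged:      True (33 iterations, 3 restarts)

pooled fractional occupancy (posterior):
  S1:0.219  S2:0.281  S3:0.240  S4:0.259

transition matrix:
   0.875  0.124  0.000  0.000
   0.099  0.901  0.000  0.000
   0.000  0.000  0.897  0.103
   0.000  0.000  0.094  0.906

metric  median_control  median_patient    p_fdr  reject
 FO_S1        0.000000        0.450000 0.000013    True
 FO_S2        0.000000        0.550000 0.000013    True
 FO_S3        0.503333        0.000000 0.000013    True
 FO_S4        0.496667        0.000000 0.000013    True
    SR        0.075649        0.066359 0.191792   False
```

Reading it: the fit recovers two sticky state pairs (the block structure of
the transition matrix mirrors the two group-specific chains of the
generator); every state's fractional occupancy separates the groups at
FDR-corrected p < 1e-4 (here the fitted S1/S2 are the patient-dominated
states — HMM state labels are arbitrary until matched, see
`dynstates.match_states`), while the switching rate does not (both groups
switch roughly every 13-15 s), i.e. dynamics are slowed, not destroyed.

The same pipeline runs from the shell:

```bash
dynstates run --config config.yaml --seed 7 --out runs/demo
```

which executes simulate -> prep -> (scan) -> fit -> metrics -> states ->
gradients -> graphs -> predict and writes every stage's tables plus a
provenance manifest (SHA-256 of each output, config, seed) into the run
directory. Individual stages are exposed as subcommands
(`dynstates fit --out runs/demo ...`).

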