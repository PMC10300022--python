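# Methods

This note documents the models and procedures implemented in `dynstates`,
the design of the synthetic cohorts the tests run on, and the reasoning
behind every default that was a genuine choice.

## Observation model and estimation

The core object is a K-state hidden Markov model over temporally
concatenated, per-subject z-scored IC time courses (T_s x M per subject).
States share one set of parameters across the cohort: initial distribution
`pi`, transition matrix `A`, and per-state Gaussian observation parameters
(`mu_k`, full covariance `Sigma_k`). Subject boundaries break the chain —
the forward recursion is re-initialised at every subject's first volume —
so subjects are independent realisations of one group-level hidden process.

Estimation is maximum-likelihood EM:

- E step: scaled (normalised-alpha) forward-backward recursions, batched
  across subjects of equal length; per-frame emission log-densities are
  shifted by their row maximum before exponentiation, so no underflow occurs
  at any T.
- M step: closed-form updates; covariances get a ridge `reg * I`
  (default 1e-6) to stay positive definite.
- Initialisation: k-means on (a <=20k subsample of) the frames for `mu`,
  within-cluster covariances for `Sigma`, sticky `A` (diagonal 0.8), uniform
  `pi`. `n_restarts` seeded restarts (default 5); the best final
  log-likelihood wins.
- Convergence: the per-frame log-likelihood gain dropping below `tol`
  (default 1e-5 per observation). EM monotonicity is asserted in the tests.

Decoding uses the Viterbi algorithm in log space, ties broken toward the
lower state index. Model order is scanned (default K = 2..15) and the scan
reports, per K: the best log-likelihood, avLL (log-likelihood per frame),
BIC with parameter count (K-1) + K(K-1) + KM + KM(M+1)/2, and the
coefficient of variation across restarts of the rank-sorted pooled occupancy
vector (a stability index). The recommended K minimises BIC, but all three
indices are reported because fit quality and estimate stability need not
agree; the final choice stays with the user.

Free energy from variational inference is deliberately not implemented; the
maximum-likelihood fit with BIC gives the same model-comparison role with
fully specifiable, oracle-testable semantics (forward-backward and Viterbi
are checked against exhaustive path enumeration at K <= 3, T <= 7, and
against an independent HMM library's likelihood under fixed parameters).

State labels are arbitrary; `match_states` aligns a fit to a reference by
Hungarian assignment on the Frobenius distance between state correlation
matrices plus the Euclidean distance between state means (the mean term
decides ties when correlation structures coincide).

## Temporal metrics and group tests

Per subject, from the Viterbi path: fractional occupancy
FO_k = #{t: s_t = k}/T; switching rate SR = #{t: s_t != s_{t-1}} /
((T-1) * TR) in Hz; the row-normalised empirical transition matrix
(never-visited states keep an all-zero row and a flag, so group averages can
mask them — group-level transition matrices pool counts by default);
and the maximum-occupancy state (ties to the lower index, logged).

Group comparisons use the unpaired Mann-Whitney rank-sum test (exact
enumeration for pooled n <= 12 without ties, otherwise the tie- and
continuity-corrected normal approximation) — the two groups are independent
samples, so the unpaired test is the correct one even where paired wording
appears in parts of the literature this pipeline follows. One test per state
for FO plus one for SR form a single Benjamini-Hochberg family
(default alpha 0.01 for FO/graph families, 0.05 for edge and univariate
screens).

## State connectivity, gradients, graphs

Each state's correlation matrix R_k = D^-1/2 Sigma_k D^-1/2 is sparsified
proportionally: the strongest 20% of the M(M-1)/2 edges by |r| are retained
with their signs (ties at the cutoff resolved lexicographically and logged).
Magnitude ranking is used rather than signed ranking so that strong
anticorrelations survive a strength comparison. Edge-strength differences
between states are rank-sum tests on the retained upper-triangular values,
BH-corrected across state pairs.

Gradients: per row of R the top (1 - row_sparsify) fraction of entries is
kept, a Gaussian-kernel affinity is built on Euclidean distances between
the processed rows (sigma = median off-diagonal distance unless given), and
the eigenvectors of the g smallest nonzero eigenvalues of the
symmetric-normalised Laplacian are returned (orthonormal columns; these are
the random-walk eigenvectors up to the D^-1/2 scaling; the constant
eigenvector is dropped at eigenvalue 1e-10; signs fixed so each column's
largest-magnitude entry is positive). Sets are aligned by orthogonal
Procrustes (rotation/reflection only) to the gradients of the element-wise
mean FC, and similarity is the cosine of aligned first gradients.
`row_sparsify` defaults to 0.5: the 90% convention of vertex-level gradient
toolboxes, applied to a 45-node IC-level matrix, keeps only ~5 entries per
row — essentially the node's own network — which erases the cross-network
geometry and makes the leading gradient unstable; keeping the top half of
each row preserves the connectivity hierarchy. Both 0.9 and the kernel width
remain exposed parameters.

Graph metrics run on |W| rescaled to a maximum weight of 1, with lengths
1/w: binary degree, strength, weighted shortest-path betweenness (raw pair
counts), Onnela geometric-mean weighted clustering, local efficiency (the
weighted global efficiency of each node's neighbourhood subgraph) and global
efficiency (mean inverse shortest-path length over ordered pairs; isolated
nodes score 0 and are flagged). Betweenness and global efficiency are
verified against an all-simple-paths enumeration oracle on graphs of <= 7
nodes. Between-state comparisons of nodal metrics are paired per node
(Wilcoxon signed-rank) because the node set is identical in every state,
BH-corrected over the metric x state-pair family.

Community structure uses Louvain on the signed quality
Q = Q+/v+ - Q-/(v+ + v-) (positive weights rewarded fully, negative weights
penalised with the smaller normalisation), with randomized node orders,
consensus clustering of the co-assignment matrix thresholded at tau = 0.5,
and re-clustering until all runs agree (error after 50 rounds). The reported
modularity is the mean Q across the randomized runs; the consensus
partition's own Q is also emitted. The two-clique optimum is verified
against exhaustive partition search on 8 nodes. Partition similarity is the
Jaccard overlap of co-assigned node pairs (all-singleton pairs define 0,
with a warning).

## Lesions and cognition

Lesion masks are 3-D binary arrays on a common grid; extension is the voxel
count and the hemisphere label comes from the mask centroid against the
first-axis midpoint (the convention is written into the sidecar metadata).
Frequency maps are voxelwise means of binary masks — the "weighting" of
summed masks is the identity, so division by the subgroup size yields a
frequency in [0, 1]. Occupancy-lesion association is a Pearson correlation
with the t-distribution p-value (n - 2 df).

Cognitive scores are z-scored against normative means/SDs. Between patient
subgroups (assigned by maximum occupancy among pathological states) each
test is screened by a rank-sum test at alpha 0.05 with raw p-values — this
is a screening step, deliberately uncorrected. For prediction, tests are
clustered on the distance 1 - |Pearson r| with average linkage (single,
complete and ward are selectable), the tree is cut at the k in
2..n_tests - 1 maximising the mean silhouette, and each cluster contributes
its member most correlated with the target occupancy (ties alphabetical;
constant columns are set aside). The reduced set enters forward-backward
stepwise OLS with partial-F thresholds p_enter = 0.05 / p_remove = 0.10
(classic defaults), standardised predictors, cycle detection, and aliased
columns dropped. R^2 is the squared Pearson correlation between fitted
values and the response — numerically identical to 1 - SSE/SST for models
with an intercept (asserted in the tests). When a patient's occupancies of
two complementary states sum to ~1, the two models' coefficient vectors are
mirror images; the tests assert this anti-symmetry on synthetic data where
it holds exactly.

## The synthetic cohort

The generator defines the study conditions for every test. Defaults mirror
the targeted study design: 33 controls + 33 patients, M = 45 components in
10 blocks (resting-state-network analogues), T = 730 volumes at
TR = 1.26 s, K = 6 states of which the last two are "pathological".

Hidden chains: controls move among the healthy states (stay probability
0.9, 1% leak); patients drain into the pathological pair with forward/back
rates 0.124/0.062, chosen so that the per-frame switch probability matches
the empirically observed resting-state switching scale (~0.07-0.08 Hz at
TR 1.26 s) and the stationary split between the two pathological states is
~1:2. A configurable patient fraction (default 0.25) has the rates swapped,
producing the bimodal stratification — a minority subgroup dominated by the
first pathological state — that the univariate and stepwise stages need.

Emissions: correlation-structured covariances built from (i) per-block
within coupling drawn once from U(0.40, 0.60), sorted so the spared blocks
carry the strongest coupling, modulated per state by +-0.05; (ii)
cross-block coupling decaying along a 1-D block axis within (0.05, 0.25) —
this axis gives the connectome one dominant slow mode, which is what makes
a "first gradient" well-defined and comparable across states (with
near-degenerate leading eigenvalues, the first-gradient identity swaps
between states — a property of blocky toy matrices, not of the method);
(iii) attenuation 0.5 in pathological states applied to every edge except
those inside the spared blocks. The sparing is essential: graph metrics
rescale each matrix to unit maximum weight, so a uniform attenuation cancels
exactly and produces no segregation deficit; attenuation that spares the
primary-network coupling is both the realistic pattern and the one that
reproduces the expected fingerprint (lower clustering, local and global
efficiency; unchanged degree and betweenness). Matrices are repaired to
positive definiteness by eps*I doubling until the smallest eigenvalue
clears 1e-8. State means are N(0, 0.55^2) per channel: on z-scored channels
the means carry most of the state identifiability, leaving the correlation
structure free to encode the planted connectivity contrasts. The mean scale
and the +-0.05 modulation are pilot calibrations: smaller values let EM
merge the two pathological states in a sizeable fraction of fits, larger
modulation destroys cross-state gradient similarity.

Cognitive batteries contain 24 tests: planted columns are
weight * FO + N(0, noise_sd) (defaults: weights +1/-1 on two tests, noise
0.05), the rest are noisy copies of 7 shared latent factors so that the
feature clustering has real redundancy to collapse. Lesions are random
ellipsoids on a common grid, unrelated to occupancy by construction.

What the generator does not emulate: haemodynamic autocorrelation and
spectral content of BOLD (emissions are conditionally i.i.d. given the
state), physiological noise, ICA mixing artefacts, scanner/site effects,
spatial lesion-network topography, and missing data. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
pipeline under the declared generative model — not robustness to violations
of it.

## Preprocessing

The denoising chain is order-fixed: despike -> nuisance regression ->
high-pass -> resample -> z-score(+concatenate). The despiker is an
AFNI-style running-median (window 15) + tanh-squash rule on the
MAD-scaled residual (SD fallback at zero MAD); the despike-before-z-score
order is a documented choice. High-pass is projection on an SPM-style
discrete-cosine basis containing all components below 1/128 Hz (exact
projection semantics, zero-mean output). Temporal harmonisation is
cubic-spline interpolation onto the target TR grid without extrapolation;
the interior interpolation error scales as (TR * 2*pi*f)^4/384, i.e. ~2e-3
at 0.1 Hz for TR 1.4 s, which is what the tests assert. Framewise
displacement follows the rigid-body convention: summed absolute differences
of translations plus 50 mm times those of rotations. WM/CSF signals enter
as generic confound columns; the package does not compute them from images.

## Evaluation problem sizes

The packaged evaluations (tests and `scripts/acceptance.py`) use these
scales, chosen as the package's own study conditions: parameter recovery on
K = 4, M = 15, 20+20 subjects, T = 500 with 5 restarts; discrimination
power on 50 replicates of K = 4, M = 45, 15+15 subjects, T = 450 with a
full 2-restart fit per replicate, scoring each planted comparison's
rejection rate; the study-scale run at the full 33+33 x 730 x 45 default
with 2 restarts. The recovery transition check compares the EM-fitted
matrix (after state matching) row-wise with the chain of the group that
occupies each state; transition matrices re-counted from decoded paths are
not used for this, since every frame error creates two spurious
transitions.

## Known limitations

- One shared transition matrix is estimated for the whole cohort; with
  group-specific true chains the fitted rows are effectively owned by the
  group that visits each state, which is exploited, not hidden, by the
  evaluation.
- Small or briefly-visited states inherit noisy covariance estimates, and
  edge-level comparisons involving them lose power; the power evaluation
  quantifies this instead of assuming it away.
- The stepwise procedure inherits the usual caveats of stepwise selection
  (no post-selection inference correction); R^2 is in-sample by design.
- Adding new subjects requires re-running the whole fit; there is no online
  updating.
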