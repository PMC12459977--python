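# Methods

This note documents the models, estimators, and design choices behind
`dynstates`, and what the synthetic validation does and does not establish.

## Overview

The package implements a dynamic functional-connectivity (dFC) analysis of a
cortical language network extended with subcortical parcels: framewise
time-varying correlation networks are estimated from ROI time series with a
GARCH-standardized EWMA/DCC estimator, decomposed into temporally
reoccurring connectivity states by L1 (k-medians) clustering, characterized
topologically as weighted graphs, and compared between groups with
permutation-corrected network statistics. A synthetic cohort generator with
full ground truth (latent state paths, planted group effects, behavior
coupling) stands in for clinical data, so every stage can be validated
end-to-end.

## Synthetic cohort generator

The generator emulates the acquisition and population structure the
analysis targets:

* **Parcellation** — 68 cortical nodes (34 per hemisphere, symmetric names)
  plus 36 subcortical nodes (4 amygdala, 4 hippocampus, 12 basal ganglia,
  16 thalamus subregions), 104 in total. Coordinates are a deterministic
  schematic layout, not anatomy.
* **Sampling** — per subject, 6 runs of 118 retained frames at TR = 2 s
  (128 acquired volumes minus 10 discarded at run start is the assumption
  behind 118; the true post-scrubbing frame count per subject is unknown).
* **Latent states** — a semi-Markov chain over k = 4 correlation templates
  with geometric dwell, mean 20 frames (40 s), uniform moves between
  distinct states. Dwell structure is a modeling choice; nothing in the
  analysis assumes it.
* **Templates** — each of the three non-weak states has one strongly
  positive module (within-correlation +0.55) and a moderate negative
  coupling (−0.12) between that module and one other module, over a +0.05
  background; the fourth state is uniformly weak (all off-diagonal +0.05).
  This mirrors empirical state patterns: one dominant domain-specific
  module per state, antagonism with another domain, and an overall-weak
  baseline state. A correlation matrix cannot carry sizeable negative
  correlation between two *weakly* coherent modules and remain positive
  definite, which is why the negative coupling attaches to the strong
  module. All templates are verified positive definite at construction;
  invalid plans are rejected, never silently repaired.
* **Signals** — given the state at frame t, node signals are correlated
  Gaussians scaled by per-node GARCH(1,1) conditional standard deviations
  (shared parameters ω = 0.1, α = 0.1, β = 0.8; unconditional variance 1),
  giving realistic volatility clustering. No hemodynamic model, motion, or
  physiological artifact is simulated — validation therefore speaks to the
  estimators under regime-switching correlation with conditional
  heteroscedasticity, not to artifact robustness on real fMRI.
* **Group effects** — patients' templates differ from controls' at planted
  edges: a 10-edge *path* with −0.2 (hypo-connectivity, on state 0's strong
  module) and a 10-edge path with +0.2 (hyper-connectivity, on background
  edges of state 1). Paths rather than stars: a star of 10 edges at
  |δ| ≥ 0.2 shifts the template's minimum eigenvalue by ≈ −δ√10 and breaks
  positive definiteness, while a path shifts it by at most −2δ. Effects are
  population-level (applied to templates), so edgewise tests have a
  well-defined truth.
* **Behavior** — each subject's latent language-performance score is
  `intercept + 8·(mean realized hypo-edge correlation) − 8·(mean realized
  hyper-edge correlation) + N(0, 0.2)`, where "realized" is the subject's
  empirical within-state correlation at the planted edges. Separate hypo
  and hyper slopes are needed to emulate the dual effect (hypo-connectivity
  correlating positively, hyper-connectivity negatively, with performance);
  the slopes and noise give a strong but noisy coupling (population partial
  correlation magnitudes ≈ 0.4–0.7). Nine subtest columns load linearly on
  the latent score. Covariates (age, sex, lesion type, race, education) are
  drawn independently of the score, so partial correlation should equal the
  marginal correlation by construction.
* **Seeding** — all randomness flows from one root seed; subject i's stream
  is `default_rng(SeedSequence((root_seed, i)))` (behavior/covariates use
  offset 10000 + i). Fixed seeds reproduce series bit-identically.

## Signal preprocessing

Optional, for already-extracted ROI series, in the fixed order linear
detrend → nuisance regression → band-pass (0.01–0.1 Hz). The band-pass is a
4th-order Butterworth applied forward-backward (zero phase). Runs are
processed independently to avoid boundary artifacts; confound regressors
are not themselves filtered. Rank-deficient confound designs drop dependent
columns with a warning.

## Framewise time-varying correlation

**Stage 1 (variance).** Each node's run-demeaned, concatenated series gets
a univariate GARCH(1,1) fit by Gaussian quasi-maximum likelihood:
σ²_t = ω + α·x²_{t−1} + β·σ²_{t−1}, σ²₁ initialized at the sample variance,
stationarity (α + β < 1 − 10⁻⁶) enforced by reparameterization, σ² floored
at 10⁻¹⁰. The optimizer screens a fixed 3×3 (α, β) start grid plus the
constant-variance point and polishes the best two starts with Nelder–Mead;
the returned optimum is the likelihood argmax over all candidates, so it is
deterministic and dominates the reference points by construction.
Standardized residuals are z_t = x_t/σ_t.

**Stage 2 (correlation).** The DCC recursion on standardized residuals is

    q_t = (1 − θ₁ − θ₂)·s̄ + θ₁·z_{t−1} z'_{t−1} + θ₂·q_{t−1},
    R_t = normalize(q_t),   q₁ = s̄ (sample correlation of z).

Three modes are provided:

* `ewma` (default): the boundary form θ₁ = 1 − λ, θ₂ = λ with fixed
  λ = 0.7 — an exponentially weighted moving average of the residual outer
  products. The emitted path averages a forward and a time-reversed pass
  (zero-phase, same rationale as forward-backward filtering): a causal EWMA
  lags regime changes by roughly its window (~5 frames), which on
  synthetic regime-switching data capped frame-label accuracy near 0.82;
  centering the window raised pooled-cohort label recovery from ARI ≈ 0.55
  to ≈ 0.71 and halves the estimation variance. λ was calibrated once on
  synthetic ground truth (recovery is flat for λ ∈ 0.6–0.75).
* `pairwise`: per-edge bivariate (θ₁, θ₂) by quasi-maximum likelihood
  (deterministic grid screen + shrinking pattern search per edge) — the
  ROI-pair formulation standard in functional-connectivity DCC.
* `joint`: one shared (θ₁, θ₂) from the full N-dimensional
  quasi-likelihood.

Why EWMA is the default for *state* analysis: QML-estimated θ optimize
one-step prediction, which shrinks the tracked correlation toward the
static mean by the factor θ₁/(1 − θ₂). On data where only a minority of
edges actually switch regimes, the joint likelihood collapses to θ₁ ≈ 0
(static correlation) — the shared-parameter noise penalty on static edges
dominates, a known large-N failure of full DCC likelihoods — and even
per-edge QML estimates track at ~10% amplitude. Both QML modes remain
available and are validated (constant-correlation and step-change
recovery); they are the right tool when the goal is volatility-adjusted
correlation rather than regime segmentation.

Because stage 2 operates per edge (ewma/pairwise), the assembled R_t is
exactly symmetric with unit diagonal and entries in [−1, 1] but **not
guaranteed positive semidefinite**; `DynamicConnectome.validate` checks
PSD only on request. The recursions run straight through run boundaries;
frame provenance is kept so the first 5 frames of each run (burn-in,
configurable) are dropped before clustering. The static complement is the
Pearson correlation over all (per-run demeaned) frames.

## Connectivity states

Framewise matrices are vectorized (upper triangle, i < j, row-major),
pooled over subjects, and clustered with Lloyd-style k-medians: L1
assignment, element-wise median centroid update (the centroid that
minimizes the L1 objective), empty clusters re-seeded at the farthest
point. The objective is asserted non-increasing every iteration; best of
n_init random-row initializations is kept. Distances are computed in
float32 (the step is memory-bandwidth bound at 5356 edge dimensions);
centroids and objectives are reported in float64. Frames enter as raw
correlations (no Fisher transform).

**Choosing k.** For each k in 2..8 the within/between dispersion ratio
r(k) (mean point-to-own-centroid distance over mean pairwise centroid
distance) is reported as the elbow curve. Selection uses the slope ratio
d(k)/d(k+1) of the within-cluster objective W(k), with W also fit at k = 1
(the global median): k* is where one more cluster stops paying, ties to
smaller k. On high-dimensional framewise data the r(k) curve sits close to
its noise floor (within-cluster distance is dominated by per-edge
estimation noise) and curvature rules on r(k) itself are unstable at
noise level; the slope-ratio rule recovers the generating k on
well-separated data with a ~5× margin and also returns the boundary value
k = 2 correctly for two-cloud data.

Subject-by-state matrices are element-wise medians of the subject's frames
in the state; states with no frames for a subject are absent, never
zero-filled. Cross-solution state correspondence is the optimal one-to-one
assignment maximizing summed centroid Pearson correlation (Hungarian
algorithm); spatial similarity between matrices is the Pearson correlation
of vectorized upper triangles. Group-level clustering defaults to
per-cohort solutions matched afterwards; a pooled mode exists.

## Weighted graph topology

State matrices are thresholded at r > 0.2 (strict inequality; negatives
always removed) and kept weighted. Path lengths use L = 1/W. Global
efficiency is the mean inverse shortest-path length over ordered pairs
(1/∞ = 0); nodal local efficiency is the global efficiency of the
neighbor-induced subgraph with original weights (0 for degree < 2);
betweenness counts fractional shortest-path contributions, normalized by
(n−1)(n−2)/2. Shortest paths are Dijkstra (scipy); betweenness is
networkx. The test suite checks all metrics against an independent
Floyd–Warshall + path-enumeration oracle to 10⁻⁹ on random graphs, plus
closed forms and scaling/monotonicity laws.

## Hubs and strength distributions

The complementary cumulative distribution P(S ≥ x) of nodal strengths is
fit by ordinary least squares on log p against three forms: power law
(c + (α−1)·log x), exponential (c − x/x_c), and exponentially truncated
power law (c + (α−1)·log x − x/x_c); R² on log p decides the best family
(the truncated form nests the other two, so with observed data it wins
whenever the tail genuinely bends). Maximum-likelihood tail fitting is out
of scope. Hubs are the 20 strongest nodes (ties to smaller node id).
Functional relevance is the Dice coefficient 2|A∩B|/(|A|+|B|) between the
hub mask and precomputed binary meta-analytic node masks, optionally
restricted to the left hemisphere; preparing such masks from volumetric
meta-analysis maps is upstream of this package.

## Group statistics

Edgewise contrasts are Welch two-sample t tests on upper-triangle edges.
Family-wise error over edges is controlled by the network-based statistic
(NBS): edges with p below the primary threshold form a suprathreshold
graph; connected components are computed separately among positive-t and
negative-t edges (hyper- vs hypo-connectivity); the component statistic is
compared with the permutation null of the maximal component statistic over
both signs (group labels permuted; p = (1 + #{null ≥ obs})/(n_perm + 1)).

The component statistic defaults to **intensity** (sum of |t| over the
component), with extent (edge count) available. At the conventional
primary threshold of 0.05, the ~2.5% chance suprathreshold edges per sign
exceed the percolation threshold of a 68+-node graph, so the null maximal
*extent* is itself a giant component (median ≈ 57 edges on 68 nodes) that
a compact effect can never outgrow regardless of strength; intensity still
accumulates evidence from strong true edges. For the same reason, analyses
that target compact planted effects use a stricter primary threshold
(0.001) — standard NBS practice: the threshold is an analysis parameter,
and FWER control holds by permutation at any choice. The pipeline default
remains edge p < 0.05, appropriate for spatially extended effects.

Nodal/global topology contrasts are Welch t tests with Benjamini–Hochberg
correction across nodes within each (state, metric) family. The behavioral
composite z-scores subtests to a baseline (acute) sample, runs PCA on the
correlation matrix, retains components with eigenvalue > 1 and explained
variance > 10%, rotates retained components obliquely (direct oblimin,
γ = 0), scores subjects by Thurstone regression, and reduces multiple
component scores to one by a final PCA, sign-oriented so higher = better.
Partial correlation residualizes both variables on [1, covariates]
(categoricals one-hot encoded, first level dropped; dependent columns
dropped with a warning) and tests the residual Pearson r on n − q − 2
degrees of freedom. Longitudinal dependence between post-stroke timepoints
is ignored by these two-sample contrasts (per-timepoint comparisons); a
mixed-effects treatment is out of scope.

## Validation studies and their problem sizes

`dynstates.validation` (used by `scripts/acceptance.py`, the analysis
drivers, and the acceptance tests) measures, at sizes chosen to run in
minutes on one CPU:

* **State recovery** — 10 subjects × 6 runs × 118 frames × 104 nodes;
  elbow over k = 2..8 (3 restarts); ARI of recovered frame labels at k = 4
  against the latent path. Expected behavior: k* = 4 robustly; ARI ≈ 0.7
  with matched accuracy ≈ 0.89. The residual disagreement is concentrated
  in frames within ±2 frames of a latent switch (measured accuracy 38–77%
  there vs 97–98% in steady state): with geometric dwell of mean 20,
  ~13% of frames sit in that window, which caps any finite-window
  estimator's frame accuracy near 0.9. Frame-perfect recovery would
  require dwells several times longer.
* **Estimator recovery** — GARCH(1,1) QML at the generator's parameters
  (T = 4000, 20 replicates; mean absolute errors ≪ 0.1) and pairwise DCC
  time-mean correlation on constant-ρ data (T = 2000, error < 0.05).
* **Family selection** — 50 samples (n = 200) from a truncated power law
  (α = 1.5, x_c = 10); selection rate of the generating family, plus exact
  (R² = 1) recovery on noise-free curves.
* **NBS calibration/power** — 200 null cohorts (20 vs 20, 68 nodes,
  1000 permutations): family-wise error within the binomial 95% interval
  of 0.05; one large-effect power run (10-edge path, δ = 0.3): ≥ 8/10
  planted edges inside the significant component.
* **Dual-effect recovery** — 20 replicates of the default 40-subject
  cohort; within-state matrices are built from the *latent* state labels
  (re-running the full DCC + clustering chain per replicate would cost
  hours and its label recovery is already measured separately); NBS per
  affected state at edge p < 0.001 plus covariate-adjusted partial
  correlations of the behavioral score with planted-edge strength.

## Known limitations

* Framewise matrices from edge-wise recursions are not guaranteed PSD.
* The zero-phase (bidirectional) EWMA is non-causal; it is an offline
  analysis choice and unsuitable for real-time tracking.
* The elbow rule, like all such heuristics, is meaningless under a null of
  unstructured data (it still returns some interior k; the curve should be
  inspected, and k can be fixed via configuration).
* The generator does not model hemodynamics, motion, scanner drift, or
  spatially correlated noise; passing validation here demonstrates
  correctness of the estimators and statistics under the stated generative
  model, not robustness to real fMRI artifacts.
* Behavioral component scoring after oblique rotation follows the
  z-score-to-baseline + rotated-loading convention; other scoring
  conventions differ by an affine map and would not change correlations'
  signs.
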