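# Methods

This note documents the models, procedures, and design choices behind
`latgen`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic data
do and do not establish.

## Task model

The experiment is an acquired-equivalence design. Nine scene contexts are
partitioned into three latent states (A, B, C), three contexts per state;
all contexts of a state share one category→value mapping in every phase.
`build_design(seed)` draws, independently: the context partition, the
preferred old category per state (a permutation, so states are mutually
distinguishable during initial training), the low-value new category per
state (independent per state — new-category values are randomized with
respect to the initial training), and which context set (by introduction
order) is used for new-category training.

Sequence generators reproduce the trial layout exactly:

| phase | layout |
|---|---|
| initial training | 6 blocks × 54 trials; blocks 1–2/3–4/5–6 use the first/second/third context of each state; 9 conditions × 6-trial mini-blocks per block, mini-blocks nested by context with randomized orders |
| reminder | 216 trials: 9 contexts × 3 categories × 8-trial mini-blocks |
| new-category training | 90 trials: 3 trained contexts × 3 new categories × 10-trial mini-blocks |
| blocked generalization | 180 trials: 18 held-out conditions × 10-trial mini-blocks, nested by context, no feedback |
| randomized generalization | 6 runs × 180 trials (10 per condition), pseudo-random order |

Rewarded conditions pay with probability 0.9 and punish with 0.1 (reversed
for low-value conditions); payoffs are ±50/−25 gold in initial training,
+50/−100 in new-category training, and doubled (+100/−200) in
generalization, where no feedback is shown. Passing changes nothing but
still reveals the counterfactual sell outcome during training.

Pseudo-randomization of scanner runs is done by rejection sampling of
condition-balanced permutations until the same-state and same-context
transition rates lie within ±5 percentage points of chance (6/18 and
3/18). The original experiment optimized sequences for fMRI design
efficiency; at desk scale only the transition statistics matter, so
rejection sampling replaces the efficiency optimizer. Training-phase ITIs
are lognormal with log-scale σ = 0.5, clipped to [0.5, 4] s, with the
location solved numerically so the *clipped* mean is 1 s; scanner ITIs are
uniform on [1, 9] s (only the range is specified by the task).

The task's blurb that blind selling has zero expected value is
inconsistent with these probabilities and payoffs (the marginal EV of
selling is +2.5 gold in initial training and −5 in new-category training);
the probabilities and payoffs are authoritative here.

## Spreading-activation RT models

All four models share the same dynamics. Each node's activation starts at
0 and, on every trial, moves toward the asymptote 1 by a Rescorla–Wagner
step `a ← a + r·(1 − a)` with a node-specific rate `r`. Rates are
monomials in three parameters, each bounded in [0, 1]: α₁ (direct
retrieval), α₂ (mediated retrieval), α₃ (incidental retrieval); each step
along a retrieval path multiplies in another factor, giving the power-law
falloff with path length. The models differ only in their node inventory
and in which rate class each node falls into given the probed condition
(implemented as a precompiled per-condition exponent table; see the module
docstring of `activation_models` for the full class lists).

Predicted raw RT is the asymptotic ceiling minus the summed activation of
the probed read-out nodes — context + context-category for HLS, state +
state-category for LS, context + category-value for IAR — evaluated on the
**pre-update** state: retrieval difficulty reflects memory at probe time,
which is also what makes the very first generalization trial maximally
slow. CAR has no separate context/category nodes, so its read-out is
`1 − a(probed conjunction)`; because predictions are z-scored before
entering the likelihood, any affine read-out choice is equivalent (a
property the tests verify). Within a trial, all updates are computed
simultaneously from the pre-trial state, and where several textual
retrieval pathways reach one node the single enumerated class rate is
used. Networks are built fresh at generalization onset; training phases
are not simulated.

Degenerate parameter points whose raw predictions are constant (SD below
1e−10) are flagged and returned as zero vectors; the fitter assigns them a
large penalty.

## Likelihood and fitting

The fit of a model is the negative log-likelihood of a Gaussian linear
regression of observed z-scored RTs on the model's z-scored predictions.
Slope, intercept, and residual variance are profiled analytically (OLS and
σ² = RSS/n, floored at 1e−6 so perfect fits have bounded likelihood),
leaving the three α's to a bounded L-BFGS-B search from uniform random
starting points (30 restarts by default). Only correct-response
generalization trials enter, and observed RTs are z-scored on the included
trials in raw seconds (the log transform is reserved for the behavioral
switch-cost analysis, which mirrors how the RT analyses are usually
reported; affine rescalings do not change the likelihood ordering).

**Recovery.** `parameter_recovery` and `cross_model_recovery` simulate
z-domain RTs (prediction + i.i.d. Gaussian noise, re-z-scored) and refit.
Defaults: 540-trial sequences, noise SD 0.5 z-units, 20 replicates — sized
for minutes-scale runs on one CPU while keeping parameter errors well
under ±0.15. Recovery sequences are three concatenated pseudo-randomized
runs traversed by one continuous network: randomized orders decorrelate
condition identity from network state, which is what separates the models
(on purely mini-blocked orders the models' best-fit predictions correlate
above 0.999 and no finite experiment could tell them apart). Cross-model
recovery uses 10 restarts per fit as a runtime compromise; the canonical
generator parameters (0.9, 0.5, 0.1) encode the empirically observed
α₁ > α₂ > α₃ ordering. A second entry point,
`cross_model_recovery_from_reference`, reproduces the original study's
procedure instead: per replicate, all four models are first fit to
reference HLS-agent data and each model then generates from its own
best-fit parameters.

**RMSD taxonomy.** For mini-blocked sequences every trial is labeled as a
first trial of a context (indexed by state presentation order 1–3 and
context order 1–2), a category switch (first trial of a later mini-block
of the same context), or a within-mini-block trial; RMSD between observed
and predicted z-RTs is reported per label. On HLS-generated data the
associative models miss category-switch trials hardest, because they reach
the newly trained category-values only through mediated retrieval.

## Behavioral analyses

Learning curves are summarized by least-squares fits of `y = a·t^x` over
within-mini-block positions t = 1..6 (best of 10 fits started from
standard-normal draws; the implementation uses a trust-region least-squares
solver with tight tolerances, so noiseless in-class curves are recovered to
better than 1e−4). Accuracy curves average the correct indicator
position-wise across mini-blocks (first nine by default when emulating the
phase comparison); RT curves average log RTs position-wise and fit the
geometric-mean curve, restricted to the first mini-blocks of the first
three contexts when emulating the speed-up comparison. Position-wise means
are taken within subject before any group statistics.

Switch costs use correct pseudo-randomized trials only: RTs are
log-transformed, z-scored within session, and each trial with a defined
predecessor in the same run is assigned to latent-state-switch /
context-switch cells (run-initial trials are excluded; a context stay
implies a state stay). The latent-state contrast is evaluated only among
context-switch trials so state and context changes are not conflated, and
is tested with a one-sample t-test on the per-subject differences.
LS-repetition curves take the first mini-block of each context in the
blocked phase, organized by state presentation order (1–3) × context order
within state (1–2).

## RSA

Empirical RDMs over the 18 generalization conditions use the crossnobis
estimator: condition-pair pattern differences are whitened with a noise
covariance estimated from residuals and multiplied across independent run
pairs, averaged over all ordered pairs and divided by the channel count.
Cross-validation makes the estimator unbiased — null distances are zero in
expectation and may legitimately be negative. The noise covariance uses
diagonal-target shrinkage (Schäfer–Strimmer analytic intensity on the
off-diagonal), keeping the estimate well-conditioned when channels
outnumber residual samples.

Hypothesis RDMs use ordinal distances: 1/2 for same/different latent
state, context, and value (the specific integers are irrelevant because
predictors are z-scored), and graded animacy distances for category —
within 1, faces–animals 2, animals–objects 3, faces–objects 4 (the
animals–objects cell is fixed only by the ordering constraint that objects
are more similar to animals than to faces; 3 is the natural integer
choice). The visual-similarity RDM takes Euclidean distances between the
contexts' 2-D placement coordinates. Interactions are elementwise products
of z-scored lower triangles. The regression z-scores all predictors, adds
an intercept, leaves the empirical vector on its native scale, and lets
main effects and interactions compete for variance simultaneously;
rank-deficient designs are flagged and solved by pseudo-inverse.
Group-level inference is a one-sample t-test per predictor across
subjects, with an optional sign-flip permutation p-value. Searchlight
traversal and cluster-level correction are out of scope; the machinery
operates at dataset/ROI level.

## Synthetic data

Behavioral agents generate choices and RTs with known ground truth.
Training accuracy follows a saturating curve from chance (0.5) toward a
lapse-limited ceiling with per-position rate 0.4; training RTs follow a
noisy power decay. Generalization choices are correct with probability
1 − lapse (default lapse 0.04 → ~96% accuracy); generalization RTs come
from the agent's generative activation model with Gaussian noise on the
standardized scale (default 0.5 z) mapped affinely to seconds,
`rt = s·(z + ε) + o` with floor 0.2 s and defaults (s, o) = (0.33 s,
1.1 s), calibrated so later generalization trials average ≈1.1 s and the
first trial ≈4 s — the regime of well-trained participants. Retrieval
dynamics restart at each generalization segment (the blocked phase and
each scanner run): with a single persistent network the activations would
saturate during the blocked phase and the scanner runs would carry no
retrieval structure at all, contradicting the persistent switch costs the
cohort emulates. Cohorts redraw the design per subject, as in the
experiment.

Pattern datasets plant factor codes in condition means: every level of
every requested factor (latent state, context, category, value) gets a
code vector, all drawn jointly orthonormal across channels, scaled by the
factor's amplitude. Noise is Gaussian with a compound-symmetric channel
covariance (default SD 1, channel correlation 0.2), shared between the
per-run estimates and the residual array used for covariance estimation.
Orthonormal codes make planted effects exactly separable, so recovery
tests are interpretable; real multivoxel data offer no such guarantee, and
passing these tests shows the estimator and regression are correct, not
that real effects of this size would be detected. Because crossnobis
distances are quadratic in pattern differences, regression betas grow
quadratically (not linearly) with the planted amplitude. Visual-similarity
coordinates are drawn independently of the state assignment; note that the
raw visual RDM still correlates positively with the latent-state RDM
through shared same-context pairs, so the meaningful independence property
is conditional on a context change.

## Numerical and scale choices

* Problem sizes (540-trial recovery sequences, 20 replicates, 16-subject
  cohorts, 30–40 channel pattern sets, 200 null simulations) are chosen so
  the full test suite and the reproduction script each run in minutes on a
  single CPU.
* The inner activation loop is JIT-compiled with numba when available; a
  pure-Python fallback keeps results identical (and ~30× slower).
* Seeds thread through `numpy.random.Generator` everywhere; all generators
  are pure functions of their seeds.

## Known limitations

* The models predict only correct-trial RTs; choices, errors, and training
  dynamics are outside their scope.
* The agents' per-segment network restarts are a modeling convenience for
  scanner-run structure, not a claim about memory consolidation between
  runs.
* The Gaussian linear likelihood treats RT noise as homoscedastic on the
  z scale; heavy-tailed RT distributions are not modeled.
* The crossnobis fold scheme (all run pairs) and shrinkage target are one
  reasonable choice among several used in the literature; absolute beta
  magnitudes depend on them even though unbiasedness does not.
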