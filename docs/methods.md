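# Methods

## Scope and philosophy

`contextval` implements the complete analysis chain of a context-dependent
value-decoding experiment against synthetic data.  The package's claims are
therefore about the *procedures*: that the design generator satisfies its
combinatorial contract exactly, that every statistical test is calibrated
under a null generative model, and that planted effects of the studied kind
are recovered with the correct signs.  Nothing here estimates parameters of
real brains; what passing tests show is that the chain would detect such
effects if they were present with the planted structure, and would not
invent them otherwise.

## Design generation

Each block holds 36 1D trials (3 EV × 2 contexts × 6 repetitions, target
side balanced 3/3) and 72 2D trials (3 EV × 2 contexts × 12 ordered
irrelevant pairings).  For every (EV, context) cell the two ordered
versions of each unordered irrelevant pair share a target side — one
congruent, one incongruent — and sides are split 3/3 across the six
unordered pairs.  This makes EV, EV_back and Congruency *exactly*
orthogonal and balances side 6/6 within every cell; EV_back levels 30/50/70
occur 4/8/12 times per block, the "design frequency" used by the RDM
models.

Sequencing: a (context, dimensionality) slot plan is drawn first — context
run lengths 4–7, at most 3 consecutive same-dimensionality trials within a
context and 5 overall — using a feasibility-guarded sequential sampler;
trials are then assigned greedily under the remaining constraints (target
side ≤ 4 consecutive; congruency runs ≤ 3, broken by 1D trials; no repeated
target feature, i.e. (context, EV), on consecutive trials).  Dead ends
restart the block; a bounded retry budget turns pathological parameter
choices into an explicit `DesignGenerationError` naming the stage.
Candidate designs whose adjacent-trial EV-repeat fraction exceeds 10% —
overall or counted over adjacent pairs lying within the congruent,
incongruent or 1D subsets — are rejected, and one survivor of the candidate
pool is selected by seed.  Subset repeats are counted over *adjacent* pairs
of the full sequence (both members in the subset): counting within
subsequences would make the 1D criterion unsatisfiable, since non-adjacent
1D trials are unconstrained (~1/3 expected repeat rate).

Inter-event gaps are truncated exponentials (cue→stimulus mean 0.6 s on
[0.5, 2.5]; stimulus→outcome 3.4 s on [1.5, 9]; outcome→cue 1.25 s on
[0.7, 6]); the rate is solved numerically so the truncated mean matches,
and sampling inverts the restricted CDF.  The estimability check builds
boxcar regressors (one per stimulus, cues split by context, outcomes by
EV), convolves them with the canonical double-gamma HRF (nilearn's Glover
kernel) at 0.05 s resolution, samples at TR = 1.25 s, and reports variance
inflation factors from the inverse correlation matrix; empty columns (an
event type that never occurs in a toy design) are reported as missing
rather than poisoning the inversion.  Generated designs sit near max VIF
≈ 1.2–1.6, far below the conservative bound of 5.

## Staircase

The observer model is the package's own construct: RT = a + b/θ + ε with
feature-specific offsets a, Gaussian ε, and fixed accuracy probability; RT
is strictly decreasing in θ with equilibrium θ\* = b/(RT⁰ − a).  Block 1
(72 trials) anchors on the last 48 accurate trials and applies one α = 1
step per feature; block 2 re-anchors on 24 motion-cued trials (the motion
anchor serves both contexts) and adjusts a feature after every third
correct answer, α stepping 0.6 → 0.1, at most six steps.  Only accurate
trials enter feature means.  Motion θ is clamped to (10⁻⁴, 1], color θ to
[10⁻⁴, ∞).  With heterogeneous offsets the between-feature variance of
expected RT falls in ≈100% of seeded replicates — the procedure's purpose.

## Behavioral models

Simulation and fitting share one regressor builder: EV, EV_back, trial
index and switch distance are z-scored; side, context and congruency
(incongruent = +1, congruent = −1, 1D = 0) are effects-coded.  The RT
ladder fits Gaussian mixed models with a subject random intercept by ML
(statsmodels `MixedLM`) and reports likelihood-ratio tests between adjacent
nested models.  The accuracy ladder uses a binomial GLM with *fixed*
per-subject intercepts: the Python ecosystem has no `glmer` equivalent
with likelihood-ratio support, and conditioning on subject intercepts
leaves the slope LR tests calibrated (verified by the calibration suite).
A degenerate all-correct sample is flagged and refitted with ridge
penalization.  Contrasts (incongruent vs 1D vs congruent) are paired
t-tests on per-subject mean log RT, Benjamini–Hochberg adjusted; identical
condition means short-circuit to t = 0, p = 1.

## Pattern simulation

Codes are built from an orthonormal voxel basis mixed through the Cholesky
factor of the target correlation matrix ρ^(|v−v′|/20), so realized
inner products are exact.  The background codebook shares the relevant
codebook with overlap ω (default 0.9); context codes are orthogonal to all
value codes.  Trial patterns mix g_ctx·c(context) + g_EV·u_rel(EV) +
g_back·u_back(EV_back) + heteroscedastic Gaussian noise (per-voxel SDs
log-normal); matched zero-mean residual matrices make noise normalization
non-trivial.  Gains: g_ctx is log-normal (median a_ctx); g_back grows
linearly with EV_back level and carries a log-normal trial jitter
(`back_gain_sd`) — without trial-wise background fluctuation the
probability-correlation analysis has no asymmetry to detect, since the
EV_back level alone is nearly constant within the filtered trial sets; and
g_EV = max(0, a_EV − λ·exp(−m·g_ctx)·g_back): competition λ, moderation m.

`NeuralParams.paper_like` plants the full mechanism.  Its effect sizes
were fixed by a power analysis of the sign checklist conducted before the
acceptance suite was frozen: a_EV = 1.6 keeps the competition mostly off
the g_EV = 0 floor (flooring destroys the interaction information);
a_ctx = 2 with m = 0.6 puts m·g_ctx in a range where exp(−m·g_ctx) varies
severalfold while P_context remains a usable proxy of g_ctx; a_back = 1.2
and back_gain_sd = 0.9 give the background channel enough trial variance
for the correlation asymmetry.  Ground-truth gains are exported per trial,
so every planted quantity is recomputable without re-simulation.

## RSA

Accurate 2D trials are averaged into nine (EV, EV_back) condition patterns
per run; voxels are scaled by their residual SD (default) or whitened by a
Ledoit-Wolf shrinkage residual covariance; the across-condition mean
pattern is subtracted per run.  Distances are Euclidean between condition
patterns of *different* runs only, averaged over ordered run pairs — the
diagonal holds same-condition cross-run distances and is retained in the
models (45 unique cells).  Dissimilarities are modeled with gamma GLMs
(log link by default; the paper-style inverse link is available but
unstable with free fixed intercepts on small samples).  Frequency control:
condition means over f trials carry noise variance ∝ 1/f, and the mean
subtraction mixes (1/81) of every condition's variance into each pattern,
so under pure noise the expected distance of cell (i, j) scales as the
run-pair mean of √((7/9)(1/fᵢʳ + 1/fⱼˢ) + (Sᵣ + Sₛ)/81), with Sᵣ the
run's sum of 1/f over conditions and realized accurate-trial counts in
place of design frequencies; the log of this noise floor enters the
models with a free slope (the null suite showed that simpler covariates —
categorical pairs, design-count inverse sums — leave an EV_back-aligned
bias, since frequency is a function of EV_back).  Categorical
frequency-pair intercepts
cannot be used with fixed effects: EV_back level determines design
frequency, making them perfectly collinear with the EV_back similarity
terms (only shrinkage/random-effect engines separate them).  Inference is
two-stage: the pooled scaled-deviance LR is reported descriptively, but
p-values come from t-tests of per-subject gamma-GLM coefficients —
cross-run distances of overlapping condition pairs are dependent within
subject, which deflates pooled LR statistics, while the summary-statistics
route is calibrated under arbitrary within-subject dependence (the
standard two-level approach in neuroimaging).

## Decoding

Scikit-learn multinomial logistic regression (lbfgs, L2, C = 1).  Training
sets are accurate 1D trials of the three retained runs (EV and context
targets; balancing keys EV × context × chosen side) or accurate 2D trials
(EV_back one-vs-rest; keys EV × context × EV_back, with sample weights
equating total positive and negative weight).  Up-sampling duplicates
existing cell members, preferring under-represented blocks; test sets are
never up-sampled.  Each trial is predicted exactly once, by the fold
holding out its run.  One-vs-rest probabilities are renormalized to sum to
one, then clipped; clipped vectors are not renormalized again, so sums may
deviate from 1 by ≤ 6×10⁻⁵.  Balanced accuracy averages correctness
within (subject, fold, label) first; argmax ties count as incorrect.  The
TR-selection step of real-BOLD pipelines is represented by an identity
selector (patterns are trial-level); the onset → volume convention
floor(round(onset + 5)/TR) is documented here for users who connect the
design to volume-resolved data.

## Linking

Beta-family regressions (logit link, statsmodels `BetaModel`) with subject
fixed intercepts model the clipped probabilities; the engine is recorded
in every effect table.  As in the RSA module, inference is two-stage:
decoded probabilities are dependent within subject — each fold's
predictions share one trained weight vector, and a trial's class
probabilities are coupled by the sum-to-one constraint — which the null
suite showed makes pooled LR tests miscalibrated in both directions.  The
pooled fits provide estimates and AICs; p-values are t-tests of
per-subject slopes.  P_other requires EV ≠ EV_back and the third
value's feature on screen (any of the four displayed features).  In the
nested moderation model, per-(subject, EV_back level) intercepts absorb
the EV_back main effect exactly — with fixed effects the paper-style
main-effect-plus-nested-intercepts decomposition is only identifiable
through shrinkage — so the ladder tests the remaining slope terms.
Subject-level slopes come from per-subject OLS fits (the no-random-slope
fallback); between-subject coupling uses Pearson r with Spearman p.

## Calibration and recovery suites

`validation.py` runs the end-to-end checks at reduced sizes chosen so the
whole suite completes comfortably on one CPU: behavior calibration on a
one-block design with 12 subjects; RDM calibration on two-block null
patterns with 10 subjects and 60 voxels; linking calibration on two-block
null patterns with 3 subjects and 40 voxels (null behavior runs
near-ceiling accuracy so two-fold training cells stay populated — under
calibration the accuracy level is irrelevant to the statistics, and a draw
that still hits an empty cell is redrawn); recovery with 12 subjects and
150 voxels over 50 replicates.  One fixed design is shared across
replicates within a suite — the design is a deterministic study condition,
not a random quantity under test.

## Known limitations

* No BOLD temporal structure: patterns are trial-level responses, so HRF
  mis-modeling, autocorrelation and physiological noise are out of scope
  (the VIF check covers estimability only).
* Fixed-effects engines replace the paper-style random-effect GLMMs for
  binomial/beta/gamma families; where that changes identifiability (RDM
  frequency control, EV_back nesting) the reparametrization is documented
  above.
* The observer and gain models are intentionally minimal; recovery results
  certify the analysis chain, not the realism of any particular parameter
  value.
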