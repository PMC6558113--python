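# Methods

`cdmscreen` implements a diagnostic-classification workflow for depression
screening: estimate, from dichotomous questionnaire responses, which of the
ten ICD-10 depressive symptom criteria a respondent satisfies, and convert
the resulting posterior over symptom profiles into probabilities of a
none/mild/moderate/severe depressive episode. This note records the model,
the numerical choices, and what the simulation-based validation does and
does not establish.

## Model

Respondent latent state is a binary profile alpha in {0,1}^K over K symptom
criteria (K = 10: C1–C3 "typical" — depressed mood, loss of interest,
fatigability; C4–C10 "common"). A Q-matrix marks which criteria drive each
item. Conditional on alpha, responses are independent Bernoulli; item j with
K* required criteria has one endorsement probability per reduced sub-profile.
The saturated G-DINA parameterization on the identity link is

    P(alpha) = phi_0 + sum_k phi_k alpha_k + sum_{k<k'} phi_kk' alpha_k alpha_k' + ...

Reduced models are linear-restriction submodels: DINA (only the all-present
cell differs), DINO (only the none-present cell differs), and additive models
without interactions on the identity (A-CDM), logit (LLM) and log (RRUM)
links. Link assignment follows the standard definitions of each family
member. The structural distribution pi over all 2^K profiles is saturated.

Identity-link probabilities are the primary item parameterization; monotone
(non-decreasing in attributes) constraints are *not* imposed during
estimation by default (`monotone` flag available) — enforcing them changes
estimates and the estimator should report, not assume, monotonicity.

## Estimation

Marginal maximum likelihood via EM over the 2^K profile classes:

- E-step: posterior profile weights per respondent, entirely in log space
  with log-sum-exp normalization (missing responses contribute likelihood 1).
- M-step: pi is the mean posterior plus a 1e-6 per-class floor (no class
  ever dies). Saturated, DINA and DINO items have closed-form weighted-mean
  updates with a 1e-3 pseudo-count toward 0.5 and hard cell bounds
  [1e-4, 1 - 1e-4] (degenerate all-endorsed items drift to the bound instead
  of crashing). Additive items take a warm-started L-BFGS partial step on
  the link-scale weighted binomial likelihood (generalized EM: the incumbent
  is kept if the step does not improve the objective).
- Initialisation is deterministic: uniform pi; item cell probabilities
  spread from the observed item mean to (mean - 0.1, mean + 0.1) null/full
  tiers, interpolated additively between.
- Convergence: absolute log-likelihood change < 1e-6 (default), at most
  2000 iterations; non-convergence is a warning recorded on the result, not
  an exception. The full-pool selection experiment uses 1e-4: the truncated
  EM tail there is worth < 0.01 log-likelihood units at N ~ 590 — orders of
  magnitude below sampling noise — and the looser stop keeps the 89-item
  loop fast on one CPU.

Per-item coefficient covariances come from the outer product of
per-respondent score vectors (Fisher-identity scores through the
posterior), assembled jointly over all items: the reported block is the
item's block of the full information inverse. Inverting an item's own
information block instead would ignore the cross-item dependence induced
by the shared latent posterior and understate the variance — in a
600-replication null study that pushed the model-selection Wald test from
~6% to ~7.3% rejections at the 5% level. The structural weights are
profiled out of this information (their score block is rank-deficient
whenever 2^K approaches N; including it moves the calibration by less
than half a point). A pseudo-inverse with a warning covers singular
information.

EAP classification thresholds each marginal criterion posterior at 0.5,
with exact ties classified present — a screening instrument should err
toward sensitivity. MAP takes the modal profile (lowest index on ties).

## Item-level model selection

For every multi-criterion item, each reduced candidate is Wald-tested
against the saturated fit: restrictions are the orthonormal basis of the
complement of the candidate's design space, applied on the candidate's link
scale (delta-method covariance transport for LLM/RRUM). Among non-rejected
candidates (alpha = 0.05) the largest p-value wins; ties prefer fewer
parameters, then a fixed DINA/DINO/ACDM/LLM/RRUM order; if everything is
rejected the saturated model is retained. Single-criterion items are not
tested — all family members coincide there.

## Item-quality screens

- **Discrimination**: Disc = P(all required present) - P(none present);
  items below 0.4 are deleted. The cited discrimination index's formula is
  not printed in the source literature; this full-vs-null gap is our
  formalization.
- **S-X² item fit**: respondents grouped by raw score; expected endorsement
  proportions mix, over profiles, the Poisson-binomial rest-score
  distribution of the other items (obtained by deconvolving the item from
  the total-score pmf, running the recurrence from whichever end keeps the
  divisor away from zero; verified against direct re-convolution to ~1e-16).
  Adjacent groups collapse until expected counts reach `sx2_min_cell`
  (default 1); df = surviving groups minus the item's free parameters, and
  df <= 0 marks the item untestable rather than misfitting. Deletion
  threshold p < 0.01.
- **DIF Wald**: per two-level demographic factor,
  W = (b_A - b_B)' (Sigma_A + Sigma_B)^{-1} (b_A - b_B), df = the item's
  free coefficient count. Two measurement-driven choices here:
  - a two-step formulation: respondent profile weights are fixed at the
    pooled fit's leave-one-*item*-out posteriors (the studied item's own
    responses cannot tilt the weights), and only the studied item's
    coefficients are re-estimated per group, with OPG covariances at those
    weights. Group ability differences (impact) enter through each
    respondent's own posterior and therefore do not read as DIF; at the
    same time no per-group structural distribution is estimated —
    re-estimating 2^K class weights per group from a few hundred
    respondents inflated the far-tail rejection rate several-fold in
    simulation, which under an iterated deletion procedure shreds clean
    pools. The adopted test measures 2–4.5% at alpha = 0.05 and 0–0.8% at
    alpha = 0.01 on clean 45–89-item pools, with p <= 8e-3 on all
    +0.25-shift items at the study scale. A label-permutation reference
    for the same statistic is available (``dif_permutations``), exactly
    calibrated for the exchangeability null, at roughly ten times the
    cost;
  - anchor purification is on by default (`dif_purify`): items flagged in a
    first pass are re-tested with all flagged items dropped from the anchor
    set, so one genuinely DIF item cannot drag clean items over the
    threshold through a contaminated anchor scale.
  The deletion threshold is alpha = 0.01 per factor (matching the item-fit
  rule), no multiplicity correction. At 0.05 per factor, two factors,
  repeated passes and a validation re-screen would delete a quarter of a
  clean pool by multiple testing alone — far beyond the deletion profiles
  instrument developers report. Groups smaller than 50 skip the test with
  a warning.

## Selection procedure

Split the sample (default 50/50; N = 1181 splits 591/590), then iterate on
the calibration half: delete misfits, refit, delete DIF items, refit,
delete low-Disc items — batch deletion within a step, Wald model
re-selection after every refit — until a complete pass deletes nothing.
A criterion losing its last item aborts with a structural error; so does
shrinking below `min_items`. The validation half then re-runs all three
screens once and drops newly failing items. Items may carry multiple flags;
the log records every deletion event with its step.

## Reliability indices

From marginal posteriors p_ik: consistency Pc_k = mean(p² + (1-p)²),
accuracy Pa_k = mean(ahat·p + (1-ahat)(1-p)). The accuracy estimator is
exact in expectation under a correctly specified model; the consistency
estimator is the standard posterior-based approximation to
paired-administration agreement and is validated by simulation. It is
slightly optimistic for sparse instruments (measured gap ~0.019 at 6 items
per criterion, ~0.008 at 10); the validation design therefore uses ten
items per criterion, the density of the calibrated 56-item instrument
(10.4 items per criterion).

## Severity rules

ICD-10 counting rules on (t, c) = (typical, common) criteria counts:
severe iff t = 3 and c >= 4; else moderate iff t >= 2 and c >= 3; else mild
iff t >= 2 and c >= 2; else none — thresholds read as "at least", highest
category wins. The "of severe intensity" qualifier for the severe grade has
no representation with binary criteria and is dropped. Over the 1024
profiles the categories partition as none 544, mild 84, moderate 332,
severe 64 (verified by independent enumeration). Severity probabilities
aggregate the joint profile posterior; a product-of-marginals shortcut
exists but is off by default since profile posteriors are dependent.
Both 1 - P(none) and P(moderate or severe) are reported as "probability of
depressive disorder" candidates. A marginal posterior above 0.5 (config)
on C8 (self-harm/suicide) raises a flag in the report.

## Synthetic data

The generator emulates the development-study design: N = 1181 (41%
symptom prevalence, matching the recruited patient share), an 89-item pool
over K = 10 criteria, criteria-per-item histogram supported on 1–4 with
mean 1.67, a response-model mixture matching the calibrated instrument's
tag frequencies, guessing/slip in [0.05, 0.2] (clean Disc 0.6–0.9), and a
50/50 split. Latent profiles come from a thresholded equicorrelated
Gaussian (single shared factor, rho = 0.5) — the one-knob way to make
symptom criteria realistically dependent. Contamination: low-Disc items
draw Disc in [0.15, 0.35]; DIF items shift every cell by +0.25 for the
focal group; misfit items are generated from a substitute Q-row
(conjunctive dependence on criteria absent from the declared row), a
mechanism guaranteed outside the fitted family.

What the generator does not emulate: Likert-scale raw responses and their
dichotomization, item wording effects, clinician ratings, and real
attribute dependence structure beyond equicorrelation. Passing tests
therefore demonstrate internal statistical correctness of the pipeline
under its own assumptions, not clinical validity of any instrument.

## Validation experiments and problem sizes

All in `cdmscreen.experiments`, each reproducible from one seed: EM
log-likelihood against brute-force enumeration (K <= 3, J <= 6, N = 100);
parameter recovery (K = 4, J = 30, N = 2000); null calibration of the Wald,
S-X² and DIF tests (K = 3, J = 12, N = 1000, 50 replications, exact
binomial bands); reliability indices against simulated paired
administrations (200 replications of 500 respondents); contaminated-pool
selection (89 items, 10 low-Disc + 5 DIF + 5 misfit, N = 1181); screening
coherence (severity probabilities sum to one; an all-zero responder on a
well-discriminating instrument lands in "none" with high probability).
Replication counts are sized for a single CPU.

## Known limitations

- OPG covariances and the frozen-anchor DIF approximation are asymptotic;
  at N of a few hundred with 8–16 coefficient items, Wald tests run a point
  or two above nominal.
- The saturated structural model (1024 class weights from ~600 respondents)
  relies on smoothing; structural estimates themselves are not
  interpretable at this N, only their marginals.
- The iterative deletion procedure re-tests survivors each pass, so some
  clean-item attrition beyond single-pass false-positive rates is inherent
  to the design it reproduces.
- Anchor-based DIF testing has a localization limit at a few hundred
  respondents per group: a chance association between group labels and a
  criterion block's anchor noise is attributed to individual block-mate
  items. All structural variants examined (per-group saturated,
  independent-attribute, tilted, fixed pooled weights; chi-square and
  permutation references) share this behavior; it occasionally costs a
  clean item its place in the instrument.
- Severity probabilities inherit any Q-matrix misspecification; the
  Q-matrix is taken as given (expert-constructed), and no Q-matrix
  discovery or validation is attempted.
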