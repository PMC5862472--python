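# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `polycat`. It is the package's account of its own science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The measurement model

Items are scored in ordered categories 0..m (m ≤ 3), with 0 the lowest
performance level ("total assistance" on a caregiver-report scale). The
generalized partial credit model (GPCM) puts adjacent-category logits
linear in the latent trait θ:

    log[ P_k(θ) / P_{k-1}(θ) ] = a_i (θ − b_ik),   k = 1..m

so the category probabilities are softmax over cumulative logits
Σ_{v≤k} a_i(θ − b_iv). The slope a_i > 0 is the item's discrimination; the
step difficulty b_ik is the θ at which categories k−1 and k are equally
likely. The partial credit model (PCM) constrains a_i ≡ a. We use the pure
logistic metric (D = 1) throughout; parameters imported from software that
uses the 1.7 normal-ogive scaling must be divided/multiplied accordingly.
Cumulative logits are max-shifted before exponentiation, so probabilities
are stable over θ ∈ [−40, 40] at the slopes seen in practice.

Fisher information is I_i(θ) = a_i² Var(K | θ), additive over items. The
dichotomous case reduces exactly to the 2PL with peak information a²/4 at
the step.

## Calibration (MML-EM)

`fit_gpcm` / `fit_pcm` maximize the marginal likelihood under a N(0, 1)
latent prior discretized on 41 equally spaced quadrature points on [−4, 4]
with renormalized normal weights (a PARSCALE-like default; finer grids
change estimates by far less than their standard errors at these slopes).
The E-step forms each respondent's posterior over the grid; the M-step
maximizes the expected complete-data log-likelihood per item by L-BFGS-B
with analytic gradients (slope bounded in [0.05, 10], steps in [−8, 8]),
warm-started at the current parameters and guarded never to accept a worse
point — so the marginal likelihood is monotone non-decreasing across
iterations, which is asserted on every fit. The PCM alternates per-item
step updates with a bounded 1-D search for the common slope (an ECM step,
also monotone). Convergence is declared when the largest absolute parameter
change falls below 1e-4 (default; `CalibConfig.tol`).

Missing responses simply drop out of the likelihood (skip-cell handling);
an item whose observed responses are constant is rejected by name.
Identification comes from the fixed N(0, 1) prior — no post-hoc rescaling —
which matches the prior the CAT engine uses for MAP scoring. Note the
consequence used throughout the tests: parameter *recovery* experiments
must draw generating abilities from N(0, 1); a cohort with SD 1.7 is
perfectly legitimate data but recovers slopes on a rescaled metric
(≈ 1.7 × the generating values).

Standard errors come from the empirical cross-product of per-respondent
score vectors, using the identity that the marginal score equals the
posterior expectation of the complete-data score.

Deviance is −2 × marginal log-likelihood; the GPCM-vs-PCM likelihood ratio
test compares the deviance difference to chi-square with df equal to the
parameter-count difference (K − 1 for K items).

## Item fit

The grouped G² statistic is a likelihood-ratio chi-square of observed
versus expected category counts in ability-ordered respondent groups
(deciles by default), with df = G·m − (m + 1) and adjacent groups merged
while any expected count is below 5. Two constructions commonly seen in
legacy software — expected counts evaluated at the group-mean θ, or
grouping on a trait score that includes the item's own response — are both
badly anticonservative: in our null simulations (data generated from the
fitted model itself) they flagged roughly a third of items at α = .05,
because they ignore within-group ability spread and select groups on the
response being tested. `polycat` therefore groups each item's respondents
by their **leave-one-out** EAP (the trait posterior computed from the other
items) and takes expected counts as leave-one-out posterior-predictive
probabilities summed within groups. O − E is then exactly mean-zero under
the fitted model; measured type-I error is ≈ 6% at nominal 5% (n = 1000,
20-item banks), and a grossly mis-specified slope is detected with
p < 1e-60. Because expected counts use estimated parameters and the
rest-score posterior, the chi-square reference is approximate; G² values
are not comparable across software.

## Unidimensionality screen

A simplified one-factor screen rather than a full weighted-least-squares
CFA: pairwise polychoric correlations (two-step maximum likelihood —
thresholds fixed at the empirical margins, the latent correlation maximized
by bounded 1-D search; the bivariate normal rectangle probabilities are
computed via Owen's T function and unit-tested against
scipy.stats.multivariate_normal), followed by iterated principal-factor
extraction of one factor. Items with loading < 0.4 are flagged; items with
a single observed category are excluded with a warning. The ratio of the
first two eigenvalues of the reduced correlation matrix summarizes first-
factor dominance. The polychoric matrix is eigenvalue-clipped to the
nearest correlation matrix when sampling noise makes it indefinite.

## Differential item functioning

Per item, three nested proportional-odds models on the item response:
trait; trait + group; trait + group + trait×group — fit with statsmodels'
`OrderedModel`. Uniform DIF is the df-1 likelihood-ratio test of the group
main effect, non-uniform the df-1 test of the interaction, and the total
test df-2. The matching trait is the EAP score under the current purified
anchor set; purification re-scores excluding flagged items and re-scans
until the flagged set is a fixed point (≤ 10 iterations). An item is
flagged when total-test p < .01 **and** the McFadden pseudo-R² change from
the trait-only model is ≥ .02 — the conjunction guards against flagging
trivially small effects in large samples; both thresholds are
configurable. Flagged items are classified non-uniform when the
interaction test is significant at .05, else uniform. Separation or
non-convergence marks the item unevaluable rather than failing the scan.
The pseudo-R² conjunct is deliberately strict: a doubled slope on a
well-targeted item can show a clear interaction p-value yet a ΔR² below
.02; users who prefer the purely significance-based convention can set
`r2_threshold = 0`.

## Calibration pipeline

Fixed stage order, each removal logged with its reason into a
machine-readable report: (1) minimum-response screens — group-specific
items with fewer than 20 responses are dropped, degenerate items dropped,
and categories observed fewer than 10 times are merged into a neighbor
before fitting; (2) unidimensionality screen, dropping loadings < 0.4;
(3) GPCM and PCM fits with the LRT selecting the model (α = .05);
(4) item fit, dropping misfits at α = .01 — stricter than the per-item
nominal level because with ~56 items a straight .05 would discard ~3 clean
items by chance; (5) step-reversal detection, merging the under-used
category at the first reversal downward (toward "total assistance") and
re-fitting; (6) DIF scan when binary group labels are present, dropping
flagged items; (7) final re-fit. The pipeline aborts if fewer than
`min_items` survive.

## CAT engine

MAP scoring by Newton ascent from the prior mean — for the GPCM the
observed log-likelihood Hessian in θ is −Σ a²Var(K|θ), response-free, so
Newton is exactly Fisher scoring on a strictly concave posterior and
converges to the global maximum (a coarse-scan fallback guards pathological
inputs); with no responses the prior itself is returned. SE is the inverse
root of posterior information I(θ̂) + 1/σ²; reliability is 1 − SE²/σ² with
σ² = 1, making "reliability 0.9" equivalent to SE ≤ 0.3162. Selection is
maximum Fisher information at the current estimate, ties broken by bank
order; the first item is chosen at θ = 0 and is identical for every
respondent. The reliability rule is checked before the length rule after
every response, so a session meeting both reports the reliability stop.
The engine contains no randomness: the administered sequence is a function
of (bank, config, responses) only. An age-equivalent report maps θ and its
CI endpoints through a user-supplied strictly monotone (age, typical-θ)
table by linear interpolation, clamped to the table range with a flag; no
normative table ships with the package.

## Post-hoc simulation

`post_hoc_cat` replays each respondent's complete recorded (or simulated)
response vector through the engine — the responder answers whichever item
the CAT selects from the stored matrix, never imputing — and reports the
share of respondents stopped by the reliability rule, mean test length
among them, mean final reliability of the rest, the Pearson correlation of
CAT versus full-bank MAP scores, and the mean percentage of items saved.
`reliability_curve` runs one length-capped session per respondent (MFI
selection does not depend on the stopping rule, so the length-L prefix *is*
the length-L CAT) and aggregates per-length reliability as the cohort mean
with an empirical 90% band (5th/95th percentiles across respondents — the
across-respondent reading of a "90% confidence interval" for a curve of
this kind).

## Synthetic data

The generator emulates the published summaries of a 56-item pediatric
self-care bank; its defaults are the study conditions, not tuning knobs:

- **Composition**: 32 dichotomous + 24 trichotomous items.
- **Slopes**: raw draws are affinely standardized so the sample mean and
  SD (ddof = 1) are exactly 1.666 and 0.57, then the whole sample is
  redrawn (fresh substream, ≤ 100 times) if any slope leaves
  (0.839, 3.547). Raw draws are lognormal (σ_log = 0.5): discrimination
  estimates are right-skewed in practice, and the printed range is itself
  asymmetric about the mean (−1.45 SD to +3.3 SD) — a symmetric normal
  sample of size 56 almost surely violates the lower bound after
  standardization, a lognormal sample passes ~40% of attempts.
- **Locations**: equally spaced across (−1.313, 3.232) with uniform jitter
  at interior positions; trichotomous items place steps at location ± 0.4
  (step spread 0.8 logits, chosen to make middle categories low-but-nonzero
  frequency, matching the sparse middle categories such instruments show);
  dichotomous items place their single step at the location.
- **Cohort**: θ ~ N(0, 1.7), n = 215. The SD is pinned by the only printed
  anchor of the person distribution: Φ(−1.5/1.7) ≈ 0.19 of respondents
  below −1.5 logits.
- Slopes and locations are drawn independently; only marginal summaries of
  the real bank are published, so the joint distribution is unknowable.

`generate_study` composes bank, cohort and GPCM response simulation with a
provenance block (configs + derived response seed) that regenerates the
study bit-identically.

### What the synthetic study does and does not show

Synthetic respondents answer *exactly* according to the GPCM. Passing the
simulation checks therefore demonstrates the engine, the stopping rules and
the scoring are correct under the stated conditions; it does not
demonstrate robustness to the model misfit, response styles, or
slope-location dependence of real caregiver data. One measured consequence:
with model-exact responses, the few highest-slope items near a central
respondent's level carry ~3 units of information each, so respondents who
reach the reliability target do so in about 6.6 items on average across
seeds — a real cohort, whose response patterns accumulate information more
slowly, sits nearer 8–9 — while the cohort-mean reliability curve still
first crosses 0.9 at 9 items and the remaining efficiency/validity
statistics (share meeting the rule, precision of the remainder, CAT-vs-full
correlation, items saved) match the published scale.

## Problem sizes

The default test-suite problem sizes are chosen to make every stochastic
check decisive at interactive run times: recovery studies use 10 items ×
1000 respondents × 20 seeds; type-I calibrations 20 items × 1000
respondents × 5 replications; DIF power 12 items × 500 per group × 5
replications; the simulation harness always runs the full default study
(56 × 215) over 10 derived seeds.

## Known limitations

- No exposure control, content balancing, or randomesque selection; not
  needed for a clinician-administered instrument, and deliberately out of
  scope.
- The unidimensionality screen is not a CFA; its eigenvalue ratio and
  loadings are screening heuristics, and WLSMV-style fit indices (RMSEA,
  CFI, TLI) are not computed.
- G² item-fit values are calibrated but construction-specific; they will
  not numerically match legacy software.
- Only binary groups are supported in the DIF scan (no Mantel–Haenszel or
  IRT-LR variants).
- `ItemBank` objects are treated as immutable after construction (kernel
  arrays are cached per bank identity); mutate by constructing a new bank.
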