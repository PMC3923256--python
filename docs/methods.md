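# Methods

## Calibration model

The response is the expert panel's majority verdict on a molecule pair:
*similar* when strictly more than 50% of responses are Yes (a 50/50 tie is
non-similar — the committee this emulates requires a majority to act). Given
a computed Tanimoto similarity *s* ∈ [0, 1], the probability of a majority
"similar" verdict is modelled as

    logit p = β₀ + β₁·(10·s).

Coefficients are stored on the 0.1-similarity scale throughout: thresholds
near 0.5 and odds multipliers like exp(β₁) ≈ 12 per 0.1 similarity are the
natural working units for fingerprint similarities, and the probability-0.5
threshold is then t_LR = −β₀/(10·β₁). Fitting on raw similarity and
multiplying the slope by 10 yields the identical curve (tested as a
reparameterization-invariance property).

Estimation is maximum likelihood via IRLS (statsmodels GLM, binomial
family), convergence at log-likelihood change < 1e−8 or 100 iterations.
Two response forms are supported:

* **binary majority labels** — the form used by the pipeline proper;
* **grouped vote fractions** with a trials count (e.g. 143 experts/pair),
  fitted as a grouped binomial — the statistically efficient form when the
  full vote fractions are available.

### Separation

With a sharp panel, the majority labels can be completely or
quasi-completely ordered by similarity, and the binary-label MLE diverges.
For a single monotone predictor this is detected exactly (the classes'
similarity ranges do not overlap) and additionally guarded post-fit
(non-finite coefficients or |linear predictor| > 36). The default handling
is a Jeffreys-prior (Firth) penalized fit — finite, near-median-unbiased
coefficients with a well-defined crossing point — returned with
`separation=True` and `method="firth"`; `on_separation="error"` raises
instead. t_LR from a Firth fit is a sensible "middle of the gap" threshold,
which is exactly what the downstream classification needs.

### Diagnostics

* **Nagelkerke R²** = [1 − exp(2(ℓ₀ − ℓ₁)/n)] / [1 − exp(2ℓ₀/n)], computed
  from hand-evaluated Bernoulli log-likelihoods (for grouped fits, the
  disaggregated-trials likelihood with n = total votes).
* **Hosmer–Lemeshow**: observations sorted by fitted probability, cut into
  g = 10 equal-size groups (ties kept together; groups with degenerate
  expected counts merged into a neighbour with a warning), statistic
  Σ (O−E)²/(E(1−E/n_g)) referred to χ² with g − 2 df. Type-I error at
  α = 0.05 is verified to lie in [0.03, 0.08] over 500 well-specified
  replicates (n = 400 per replicate) in the acceptance tests.
* **Outliers**: |standardized Pearson residual| > 3 flags a pair (e.g. a
  pair most experts call similar sitting far below a steep fitted curve).
  Removal is never automatic; `calibrate_profiles(refit_without_flagged=True)`
  reports a second fit alongside the full-data fit.

## Threshold evaluation

Classification is inclusive: predicted similar iff *s* ≥ t. Candidate
thresholds are the midpoints between consecutive distinct similarities —
knife-edge equality with an observed value can then never flip a
classification — plus two sentinel endpoints so the ROC curve always
contains (0,0) and (1,1). AUC is the trapezoid over (1−specificity,
sensitivity), which equals the Mann–Whitney concordance probability with
ties counted 1/2 (asserted to 1e−12 against an O(n²) oracle).

All seven statistics at an operating point (sensitivity, specificity,
precision, accuracy, F, Youden, Matthews) are computed from unrounded
integer confusion counts; the MCC numerator and the product under its root
are exact integer arithmetic before one floating division. Ratios with zero
denominators are reported as NaN, never as 0. The Youden index is
sensitivity + specificity − 1. t_ROC maximizes Youden among candidates
meeting sensitivity ≥ 0.9 and specificity ≥ 0.85 (both configurable; chosen
to admit every operating point a regulator would plausibly accept), with
ties broken by MCC, then accuracy, then the smaller threshold; unmeetable
floors are relaxed with a warning rather than silently ignored.

## Consensus

Each configured scheme votes via its own threshold (t_LR or t_ROC); the
fused verdict is similar when ≥ 3 schemes (default) agree. With an even
number of schemes, exactly half voting similar still means "three or more",
hence similar. A pair missing any configured scheme's similarity is excluded
from the consensus with a warning — imputation is the wrong default in a
regulatory setting. Consensus is not guaranteed to beat its components; the
test suite constructs an explicit counterexample by exhaustive search.

## Fingerprints

Morgan radius-2 (diameter-4) circular fingerprints in binary (1024 bits) and
count (1024 counts) form, RDKit's hashed path fingerprint (2048 bits), the
166 public MACCS keys, and hashed atom-pair keys (1024 bits) as a generic
key-based family. These are open stand-ins for the commercial fingerprint
families used in regulatory practice (BCI, Daylight, Unity, MDL, Pipeline
Pilot ECFP/ECFC); no bit-exact emulation is attempted, and the pipeline is
deliberately scheme-agnostic — every threshold and calibration is re-derived
per scheme, never transferred. Tanimoto on counts is Σmin/Σmax, which
reduces exactly to |A∩B|/|A∪B| on 0/1 vectors. A pair of empty fingerprints
has no evidence either way and is scored 0.0 with a warning — the
conservative choice when dissimilarity is what earns market approval.
Input SMILES are canonicalised and salt-stripped (largest covalent fragment)
before hashing, so any SMILES variant of a structure fingerprints
identically.

## Training-set construction

Drug-likeness filtering is inclusive at the bounds: ≤ 10 H-bond acceptors,
≤ 5 donors, ≤ 500 Da, logP ≤ 5, and ≥ 1 carbon. Stratified pair selection
splits the observed similarity range into 10 equal-width bins (the spread
requirement does not dictate a bin count; 10 matches the percentile
granularity used elsewhere in the pipeline) and samples each bin's share
without replacement, redistributing shortfalls to the nearest bins with
spare candidates so the selection still spans the range. Selection is a pure
function of (candidates, seed); duplicate unordered pairs are dropped, but
duplicate *structures* (similarity 1.0) are allowed — observed similarity
ranges genuinely reach 1.0.

## Synthetic panel generator

What it emulates: the similarity span (0.116–1.0), panel size (143), a
bimodal agreement distribution (with defaults β₀ = −12.75, β₁ = 2.5,
expert_sd = 2.0: on average ≈ 34% of pairs draw < 10% Yes, ≈ 35% draw ≥ 90%
Yes, ≈ 5% sit in the 0.4–0.6 disagreement band), a near-balanced training
prevalence (0.49) and an imbalanced test prevalence (0.11). Heterogeneity is
a per-expert random intercept only; slope heterogeneity is omitted as
unidentifiable at 100 pairs and unnecessary for the bimodal shape. The
defaults sit near a published fingerprint calibration so simulated data
occupy a realistic regime. `analog-series` mode replaces the abstract
similarity grid with real Tanimoto values over enumerated substituent
variants of four hard-coded scaffold families (benzodiazepine-,
β-blocker-, sulfonamide- and salicylate-like), with a few self-pairs
anchoring similarity 1.0.

What it does **not** emulate — and what that means for the tests: there is
no pair-level effect (depiction/alignment quirks, pharmacological-class
familiarity) in the vote model, so the panel-average Yes-fraction is a
smooth function of similarity alone and majority labels are almost
deterministic in *s*. Two consequences, both visible and intended:

* binary-label refits on synthetic panels are steep and usually separated
  (handled by the Firth path) — their slope is *not* an estimate of
  β₁_true, and passing end-to-end tests says the thresholding machinery
  works, not that real panels are this clean;
* parameter recovery is therefore validated on the grouped vote fractions
  with expert_sd = 0, the regime where the generating and fitted models
  coincide; with expert_sd > 0 the marginal (population-averaged) slope is
  attenuated by the random intercepts — the textbook random-effects
  attenuation, a property of the estimand, not an estimator defect.

Every generator operation is a pure function of (config, seed): independent
numpy Generator streams are derived from (seed, stage) so adding a stage
never perturbs another stage's draws.

## Problem sizes and numerical choices

Simulation-backed tests use the study-scale defaults (100 pairs × 143
experts) with replicate counts chosen for stable verdicts at interactive
runtimes: 200 panels for parameter recovery, 500 replicates for the
Hosmer–Lemeshow type-I rate, 100 datasets for the AUC oracle, 10 seeds for
the end-to-end train/test run; the whole suite completes in well under a
minute. Reported tables round to 3 decimals (4 for MCC); all internal
computation is full precision, and identical (config, seed) pairs reproduce
byte-identical output files.

## Known limitations

* Open fingerprint analogues, not the commercial originals: absolute
  threshold values are scheme-specific and must be re-derived for any new
  fingerprint implementation.
* The vote model's missing pair-level variance (above) makes synthetic
  calibration slopes optimistic relative to real panels.
* Single-predictor calibration only; multi-fingerprint logistic models and
  rater-level modelling are out of scope.
* The Hosmer–Lemeshow p-value is undefined (NaN, with a warning) when ties
  collapse the risk groups below three.
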