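# Methods

## The model

`cmrselect` works with open-population capture-mark-recapture data: uniquely
marked individuals, repeated sampling occasions, imperfect detection, and
entry (recruitment) and exit (death or permanent emigration) between
occasions. The Cormack–Jolly–Seber (CJS) model conditions on each
individual's first capture, so only recaptures carry information; it
separates apparent survival φ (per interval) from detection probability p
(per occasion).

The variant implemented is deliberately minimal, matching the study design
it supports: p constant across time and individuals, φ constant across time
but logit-linear in one per-individual covariate,

    logit(φ_i) = β0 + β1 x_i,        p = expit(ζ).

For a history first caught at occasion f, last seen at l, with detection
indicators h_t over T occasions, the conditional log-likelihood is

    Σ_{t=f+1}^{l} [ log φ_i + h_t log p + (1−h_t) log(1−p) ] + log χ_l ,

where χ_t, the probability of never being seen after t, satisfies χ_T = 1
and χ_t = (1−φ_i) + φ_i (1−p) χ_{t+1}. Histories whose first capture is the
terminal occasion contribute zero. The test suite verifies by exhaustive
enumeration that the post-release history probabilities sum to one for any
(φ, p, f).

**Fitting.** Joint maximization over (β, ζ) on the unconstrained scale with
BFGS and analytic gradients (the χ recursion is differentiated alongside the
forward pass), by default from three starts — the origin and ±1 on every
coordinate — keeping the best optimum; gradient tolerance 1e-8. Standard
errors are the square roots of the diagonal of the inverse observed
information (central-difference Hessian of the analytic gradient); when the
information is singular or ill-conditioned (eigenvalue ratio below 1e-10),
SEs are reported absent rather than as meaningless large numbers — this is
what happens on the T=2 ridge, where only the product φ·p is identifiable.
A dataset with no recaptures at all is flagged non-identifiable. Intervals
between occasions are treated as equal, matching the constant-φ assumption;
the short first-season gap in the presets is therefore not exponent-scaled.

**Model scan.** For each trait and each measurement-instance selector the
covariate is one number per individual: the first measurement, the last, or
the numeric median of all measurements (mean of the central pair for even
counts; single-capture individuals give the same value under all three).
Covariates are z-scored across included individuals (n−1 denominator) for
optimizer conditioning — β1 is then per SD of the covariate; signs are
unaffected. The null model is refit on exactly the trait's complete-case
individuals so AICs are comparable; ΔAIC = AIC_trait − AIC_null, with
AIC = −2 logL + 2k (k = 2 null, 3 univariate). Per-trait failures (constant
covariates, too few individuals, no recaptures) are recorded and the scan
continues. A trait's three selector fits are "consistent" when all ΔAIC are
negative; a stricter margin (ΔAIC ≤ −2) is available behind a flag.

## Trait preparation

Anatomical traits scale with body size, so analyses run on residuals of an
ordinary least-squares regression of trait on snout-vent length (SVL),
fitted per species pooling all capture events, with the residual computed
per event from the same-event SVL; instance selection happens after
residualization. Body condition is the residual of weight on SVL (a log-log
variant sits behind a flag; the default is linear). Color traits (CIELAB
L, a, b) are used as measured; L-channel columns are validated to [0, 100].
Whether to pool events or use one event per individual in the size
regression was an open choice; pooling uses all information and keeps the
residual definition per event.

## Variance partition

For individuals with at least two measurements of a trait (single-capture
individuals are excluded here, although they do enter the CJS fits — the two
inclusion rules intentionally differ), a one-way ANOVA on individual
identity gives SS_among and SS_within, F = MS_among/MS_within and
R² = SS_among/SS_total. Exactly zero within-group SS is flagged F = +inf
with R² = 1 (and classifies as low intraindividual variation); an all-equal
trait yields F = NaN, R² = 0. Repeatability is the one-way intraclass
correlation ICC = (MS_among − MS_within)/(MS_among + (m0 − 1) MS_within)
with the standard unbalanced-design effective group size
m0 = (N − Σn_i²/N)/(k − 1), clamped to [0, 1]. ICC was chosen over a
duplicate-measurement correlation as the repeatability definition because it
generalizes to unbalanced designs and reduces to the same quantity for
balanced pairs.

## Contingency classification

The verdict crosses two binary axes. Column: *lower intraindividual
variation* iff F ≥ 4.0 AND R² ≥ 0.5 (both thresholds configuration-exposed;
boundary values count as high; F = +inf counts as high). Row: *stronger
evidence of directional selection* iff all three selectors' ΔAIC fall below
−strict_margin (default margin 0; a laxer any-negative row rule sits behind
`require_all_negative=False`). Cells: stronger+low-IIV → under selection;
stronger+high-IIV → possibly spurious (the conclusion depends on when the
trait was measured); weaker+low-IIV → not under selection; weaker+high-IIV →
obscured. Direction is the common sign of β̂1 across selectors, `mixed` when
signs differ, and `none` for the not-under-selection cell. The classifier is
a pure function of its inputs; it is a descriptive confidence heuristic, not
a calibrated hypothesis test, and no error rates are attached to it.

## The simulator

Each individual i carries per trait a stable latent value
a_i ~ N(μ, σ²_among); the value realized at occasion t is
x_it = a_i + growth·(time_t − entry_time_i) + e_it with
e_it ~ N(0, σ²_within). Survival over each interval is Bernoulli with
logit(φ) = β0 + Σ_j β1_j z_j, where z is the latent component standardized
by σ_among (default) or the realized value at the start of the interval —
the distinction matters because selection on a "moving target" is exactly
the regime where the measurement instance changes the answer. Detection
while alive is Bernoulli(p); recruits enter at each occasion with fresh
latent traits; the dead never revive (no temporary emigration); measurements
exist only at detections and never-detected individuals are absent from the
emitted dataset but present in the truth sidecar. All draws come from one
`numpy` Generator in a fixed order, so a seed determines the output
byte-for-byte.

Defaults encode the two study populations: the `cowlesi` preset has
φ = 0.45, p = 0.55, 140 initial individuals (13.1/ha over the ~10.7 ha
area) and higher within-individual trait variance; `maculata` has φ = 0.68,
p = 0.57, 68 initial individuals (6.4/ha) and lower within-individual
variance. Both run five occasions — four yearly spring visits plus one extra
late-season visit in year one — and recruit a quarter of the initial
population per occasion. Presets carry no trait-dependent survival by
default (the demographic rates are marginal estimates); selection is
switched on per trait via `preset(..., selection={trait: beta1})`. Linear
drift is the minimal stand-in for growth in anatomical traits; no density
dependence, sex structure, or spatial process is modeled. Consequently,
passing tests show the estimator and classifier behave correctly under the
assumed two-level normal trait model and constant rates — not that real
field data meet those assumptions (heterogeneous detection, trap response,
and non-normal traits are all outside the generator).

## Problem sizes and numerical choices

The statistical test conditions are fixed design choices: parameter recovery
uses 100 replicates of n = 500 at the `maculata` rates; the AIC
null-preference calibration uses 2000 replicates at n = 400 (large enough
that the likelihood-ratio statistic is close to its χ²₁ limit, so AIC
prefers the spurious trait model at rate P(χ²₁ > 2) ≈ 0.157); the
instance-sensitivity contrast uses β1 = 0.75 per latent SD at n = 300 with
σ_within/σ_among ∈ {0.1, 2}; repeatability recovery uses 500 replicates of
the 12-individual × 2-replicate measurement-consistency design at true
ICC = 0.94. The acceptance script runs reduced replicate counts (40/500/100)
of the same conditions to report point estimates quickly; `--seed` drives
every stream through `numpy.random.SeedSequence` spawning.

Degenerate inputs are handled explicitly: χ is floored at 1e-300 inside the
optimizer so extreme parameter proposals stay finite; `logit`-scale
parameters are unconstrained so no boundary handling is needed; duplicate
within-occasion captures are collapsed with trait averaging (a season is one
sampling occasion — how within-season recaptures were handled in the field
is not documented, so the collapse rule is this package's choice); missing
trait cells are allowed per event and resolved per trait downstream.

## Known limitations

* No overdispersion (ĉ) adjustment, time-varying p or φ, multi-state or
  Bayesian fitting, abundance estimation, or model averaging.
* One covariate at a time; no multivariate selection gradients.
* The classifier emits exactly one cell per trait; borderline traits near
  the F/R² thresholds flip cells under small threshold changes, which is why
  the thresholds are exposed in the configuration.
* Restricting the CLI to a single selector (`--selector first|median|last`)
  produces the scan and variance partition but no verdicts, since the
  contingency row needs all three selectors.
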