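# Methods

## Model and likelihood

The package implements a parametric accelerated-failure-time model: event
times are Weibull in scale form, `S(t|x) = exp(-(t/λ)^k)`, with a single
shape `k` shared across subjects and a per-subject scale `λ_i = exp(η_i)`.
Two predictors for `η_i` are provided behind the same likelihood:

* **Linear**: `η_i = β₀ + x_iᵀβ` — the interpretable baseline.
* **Network**: `η_i = FFN(x_i; θ)` — a dense net with two SoftPlus hidden
  layers and a linear single-node output. The output is linear because
  `log λ` is unconstrained; SoftPlus is used only on hidden units. The
  default widths (24, 24) on a 55-feature input give 1970 learnable
  scalars including the shared shape.

Both are fitted by minimizing the right-censored negative log-likelihood:
events contribute `-log f(t_i)`, censored subjects `-log S(t_i)`. A
censored observation at `t = 0` contributes exactly zero; an *event* at
`t = 0` is rejected rather than clamped, because the log-density is never
finite there. The shape is parameterized internally as `log k` so
positivity is structural; it is initialized at `k = 1` and learned jointly.
No `k > 1` constraint is imposed even though an age-at-onset hazard is
expected to rise with time — the data decide, and a warning is emitted when
the fitted `k ≤ 1`.

### Optimization

The linear model is maximized with L-BFGS-B on the exact NLL with analytic
gradients; standard errors come from the inverse observed information
(central differences of the analytic score). Paired carrier indicators
(`*_ref`, `*_alt`) are nearly collinear, which leaves very flat likelihood
directions; a residual gradient that is negligible relative to the NLL
scale is accepted as converged, and an optional ridge penalty on the slopes
is available for stricter conditioning.

The network is trained by full-batch Adam (default learning rate 1e-3,
500 epochs), i.e. plain backpropagation of the likelihood gradient
`∂NLL/∂η_i = k (d_i - (t_i/λ_i)^k)` through the net, with the shared
`log k` updated by the same optimizer. Options: minibatch mode, L2 weight
decay on dense weights, early stopping on a held-out validation split
(default 10%, patience 50, best weights restored), and a final L-BFGS
"polish" on the exact NLL. Training is fully reproducible given the seed.

**Training guidance learned from the package's own experiments.** On small
feature sets, Adam can sit well above the likelihood optimum after a few
hundred epochs — visible as the shared shape lingering near its `k = 1`
init — which depresses test discrimination in a way that looks like (but is
not) a property of the feature set. The cross-validated experiments in this
package (feature ladder in particular) therefore train longer (up to 1500
epochs) with early stopping and weight decay 1e-3; the polish option exists
for cases where the exact optimum matters, such as verifying that the
zero-hidden-layer network reproduces the linear MLE.

## Data model and encoding

* APOE genotype labels (`"E3/E4"`) become three carrier indicators
  (E2, E3, E4); an indicator is 1 iff the allele appears at least once.
* Each biallelic SNP becomes **two** carrier indicators — carries-ref,
  carries-alt (hom-ref → (1,0), het → (1,1), hom-alt → (0,1)) — so that
  both alleles of one variant can surface separately in attribution
  rankings; a single alt-carrier column is available as a config option.
* VCF extraction matches variants strictly on (chrom, pos, ref, alt),
  1-based coordinates; no allele flipping or strand complementing, because
  a silent mismatch is worse than an explicit error. Missing genotype calls
  are imputed to hom-ref with a warning by default; a strict mode errors.
* Continuous covariates (MMSE) are standardized on the training fold only;
  binary indicators pass through untouched. The standardizer detects
  indicator columns as those whose training values all lie in {0, 1}.
* The event-stratified k-fold splitter deals shuffled events then censored
  subjects round-robin with one shared cycling counter, so per-fold event
  counts are within 1 of proportional *and* total fold sizes differ by at
  most 1 (e.g. n = 956, k = 5 gives sizes {191, 192}).

## Evaluation

* **C-index** (Harrell): pairs `(i, j)` with `t_i < t_j` and `d_i = 1` are
  comparable; score ties count 0.5; time-tied pairs are not comparable. The
  ranking score is the predicted `log λ` (any strictly monotone transform —
  λ, median time — gives the same value; an invariance the tests assert).
* **Brier score** (Graf IPCW): subjects dead by the horizon contribute
  `Ŝ²/G(t_i⁻)`, subjects observed past it `(1-Ŝ)²/G(t*)`, subjects
  censored earlier nothing; `G` is the Kaplan-Meier estimate of the
  censoring survival (events-before-censorings tie convention, left limits
  at event times). A horizon where a needed `G` weight is zero raises with
  advice to shrink the grid.
* **Integrated Brier score**: trapezoidal integral over 100 equispaced
  points between the 5th and 95th percentiles of the evaluation split's
  observed times, normalized by the span.
* **Cross-validation** retrains from a fresh initialization on each
  training fold (per-fold seed offset), standardizes on the training fold,
  and reports per-fold train/test C-index and IBS plus Mean/Std rows.

## Attribution

Both estimators target the interventional Shapley value of the model's
`log λ` output: the value of a coalition S is the model output with the
explained subject's features on S and background-row features elsewhere,
averaged over the background. Exact enumeration is used up to 15 features
(2^p coalitions); beyond that, the permutation-sampling estimator draws
feature orderings, accumulates marginal contributions, and reports a
Monte-Carlo standard error per value (standard deviation across orderings /
√n). The estimator is unbiased and seed-reproducible; additivity
(`base + Σφ = f(x)`) is exact for enumeration and holds within Monte-Carlo
tolerance for sampling.

Sign semantics: positive φ pushes toward later predicted onset (lower
risk), so carriers of a harmful planted indicator have negative mean φ.
For dependence plots, an interaction shows as partner-dependent vertical
dispersion of φ at a *fixed* feature value; under a pure XOR the
unconditional partner-stratified means coincide (±γ/4 symmetric within
each stratum), so interaction tests condition on the carrier stratum.
Linear-baseline importance is `|β_j| · sd(x_j)` — the coefficient magnitude
on the standardized-feature scale.

## Feature ladder

Starting from the fixed clinical/APOE baseline {MMSE, APOE E2, APOE E3,
APOE E4, sex}, features are added in descending mean-|φ| order until each
configured *total* size (5, 10, 20, 30, 40, all by default) is reached;
every step re-runs the full cross-validation with fresh initialization but
the same fold assignment, isolating the feature-set effect. Feature sets
are nested by construction.

## Synthetic cohort generator

The generator emulates the structure of a small age-at-onset genetics
cohort and is the ground-truth channel for every test:

* **Defaults**: 956 subjects; 25 panel variants (gene/rsID labels from
  common dyslipidemia and type-2-diabetes loci) under Hardy-Weinberg with
  allele frequencies cycling over 0.08–0.45, encoded as 50 paired carrier
  indicators; APOE allele frequencies E2/E3/E4 = 0.06/0.79/0.15 drawn as
  two i.i.d. alleles; MMSE; sex; 55 features total.
* **Effects on log λ** (negative = earlier onset): APOE E4 −0.5 (dominant,
  at least 5× any panel SNP effect, which alternate in sign with
  magnitudes ≤ 0.06 and several exact zeros), APOE E2 +0.35 (protective),
  sex −0.05, MMSE +0.15 per SD. Baseline log-scale 3.3 (≈ 27 years past
  the age-55 entry), true shape k = 1.5.
* **MMSE** is `30 − Binomial(30, p_i)` with `p_i` increasing in the genetic
  risk via a configurable coupling (default 1.5), so lower scores attach to
  earlier onset. Because MMSE is a risk *proxy* by construction, its
  realized association can rival APOE E4 under defaults; experiments that
  need a strictly dominant single effect set the coupling and the direct
  MMSE effect to ≤ 1/5 of the E4 effect.
* **Censoring**: administrative horizon (40 years) plus an independent
  exponential time whose rate is calibrated by bisection — against
  pre-drawn unit-exponential variates, so the procedure is deterministic —
  to a target event fraction of 473/956. If the horizon alone cannot reach
  the target, a warning reports the achieved fraction.
* **Epistasis benchmark**: two dedicated variants get alt-carrier frequency
  0.5 (allele frequency 1 − √0.5) and zero marginal effect; their XOR adds
  γ to log λ. Balanced independent carriers make each feature marginally
  uninformative — the canonical pattern a linear model cannot represent —
  and setting γ = 0 is the matched ablation.

**What the generator does not emulate**: linkage disequilibrium,
population stratification, genotyping error, informative censoring, and
any real effect-size spectrum. Passing tests therefore demonstrate that
the machinery recovers what it is designed to recover under clean
conditions, not that comparable performance is attainable on real cohorts.

## Numerical choices and degenerate inputs

* Likelihood terms are computed on the log scale with `w = exp(k(log t −
  η))`; `t = 0` handled by masking rather than clamping.
* C-index enumerations are vectorized O(n²); the test suite checks exact
  agreement with a literal pair-loop enumerator and with scikit-survival
  on tie-free data.
* Ties: score ties count 0.5 in the C-index; time ties make pairs
  non-comparable; censoring-vs-event ties at the same time keep the event
  subject at risk for the censoring KM.
* Importance rankings break exact ties by feature name, so orderings are
  deterministic.
* Cohort CSVs round-trip bitwise (round-trip float parsing on read).

## Known limitations

* Adam's slow shape convergence on small designs (above) means default
  500-epoch fits can under-estimate `k`; prefer early stopping with a
  larger epoch budget, or the polish option, when the shape matters.
* The permutation sampler's standard errors are per-value and assume
  approximate normality of averaged marginal contributions; joint
  statements across many features need a multiplicity-aware reading.
* Only right censoring is supported: no left truncation, competing risks,
  time-varying covariates, or alternative parametric families.
* The exact Shapley enumerator is capped at 15 features by design.
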