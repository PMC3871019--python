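# Methods

## The scientific question

Pre-weaning growth of a lamb is shaped by two individuals: the lamb itself
(direct effects — suckling drive, growth capacity) and its dam (maternal
effects — chiefly the milk she supplies).  Routine genetic evaluations assume
these contributions are additive.  If lambs differ genetically in how
efficiently they convert milk into gain, the maternal contribution is not
additive and a direct-by-maternal interaction exists.  `maternorm`
implements the analysis that tests this on experimental data in which the
maternal phenotype (milk yield) is *measured* rather than latent: a linear
reaction norm in which each lamb's genetic effect may have its own slope on
the dam's milk yield, fitted as a recursive structural mixed model, with the
interaction assessed by a restricted likelihood ratio test (RLRT).

## The model

Two equations are fitted jointly.  For ewe milk records (MY in dL/day) and
lamb average daily gain records (ADG in g/day over the periods 0–15, 15–21
and 21–35 days, matched to the milk measurement days 15/21/35):

    MILK = age + year + totsex + dam_age + v + e1
    ADG  = age + year + sex + dam_age + WB + LW + LSB + LW*age
           + beta * MILK + u_int + u_slope * MILK + e2

* `v` — additive genetic effect of the dam on milk yield;
* `u_int`, `u_slope` — additive genetic effects of the lamb on the intercept
  and slope of its reaction norm on the dam's observed milk yield;
* `beta` — structural regression of gain on milk, treated as a fixed effect
  (it sits in the mean of the ADG equation);
* `(u_int, u_slope, v)` jointly Gaussian over the pedigree with covariance
  `A ⊗ G`, where `A` is the additive relationship matrix (tabular method,
  inbreeding included) and `G` the 3×3 genetic covariance with entries
  σ²_int, σ²_slope, σ²_v and the three covariances;
* `(e1, e2)` residuals with 2×2 covariance Σ = [[σ²_e1, σ_e12], [σ_e12, σ²_e2]].

The *recursive intercept model* is the same system without the
`u_slope × MILK` term (σ²_slope and its covariances fixed at zero); it is
nested in the reaction-norm model, and

    RLRT = −2 logL_intercept + 2 logL_reaction-norm

is the interaction test statistic.

Because the system is triangular with a unit diagonal (milk affects gain,
not conversely), its Jacobian is 1 and the joint likelihood equals a Gaussian
likelihood in which the *observed* milk value enters the ADG mean (via beta)
and the slope incidence.  No Jacobian correction is required.

### Twin residual structure

Milk is measured once per ewe-day while both twins have a gain record
matched to it.  The residual pairing is: one `e1` per ewe-day, shared by the
twin pair; each twin's `e2` has covariance σ_e12 with that `e1` and the two
twins' `e2` are conditionally independent given `e1` (marginal twin–twin
residual covariance σ²_e12 / σ²_e1).  This is the minimal extension of the
paired-trait residual notation to twin litters, and the generator and the
fitter implement it identically by construction.

### Likelihood evaluation

The restricted likelihood is evaluated through the mixed-model equations:
with `W = [X Z]`, `C = W'R⁻¹W + diag(0, G⁻¹ ⊗ A⁻¹)` (effect-major ordering),

    −2 logL = log|R| + log|G ⊗ A| + log|C| + y'Py + (n − p) log 2π,

which equals the textbook dense form `log|V| + log|X'V⁻¹X| + y'Py` with
`V = Z (G ⊗ A) Z' + R`; the test suite checks the identity against a
brute-force dense oracle to 1e−8 on small fixtures.  R⁻¹ is assembled from
identical per-pattern blocks (milk-only, milk+1, milk+2 records per ewe-day),
so its cost is negligible.  Gradients are computed exactly for the expensive
terms (traces against C⁻¹ and the solution vector) and chained through the
closed-form derivatives of the small residual/genetic blocks under the
parameterisation below.  Problems with fewer than ~250k design cells use a
dense fast path; the experiment-scale problem (~1900 records, ~1300 mixed
model equations) evaluates in ~0.1 s and fits in a few seconds on one core.

### Parameterisation, optimisation, convergence

Variance matrices are optimised on an unconstrained log-Cholesky scale
(logs of the Cholesky diagonal, raw off-diagonal entries), which keeps every
iterate positive semi-definite and lets boundary solutions (e.g. a zero slope
variance under the null) be approached smoothly.  The optimiser is L-BFGS-B
with the analytic gradient; the default is three starts (the given or
moment-based start plus jittered copies) because boundary-heavy surfaces can
be multimodal.  Convergence is declared at |ΔlogL| < 1e−6; a line-search
abort near a boundary triggers one restart and is accepted as converged only
if the restart no longer moves the likelihood beyond that tolerance.
Iteration-limit exhaustion returns a diagnosed non-converged result rather
than raising.  Singular parameter matrices are signalled
(`SingularModelError`), never silently regularised.

The milk covariate enters on the raw dL scale by default (so beta is read as
g/day per dL); centering is available as a flag since reaction-norm practice
varies.  A caveat: published reaction-norm slope variances of the source
analysis are hard to reconcile with a raw-dL covariate (a slope variance of
~126 on a covariate of magnitude ~23 dL would dwarf the printed phenotypic
variance), suggesting the original slope covariate was effectively on a
different scale or centered.  This does not affect the intercept-model
analyses, which carry all the recovery checks.

### RLRT calibration

The null hypothesis pins σ²_slope to the boundary of the parameter space
with two covariances vanishing alongside it, so no exact chi-square null
exists.  Three calibrations are provided, all labelled in the output:

* `parametric_bootstrap` (default): simulate from the fitted intercept model
  (respecting the recursive structure — bootstrap milk feeds the bootstrap
  gain equation), refit both models, compare the observed statistic with the
  bootstrap distribution; p = (1 + #{boot ≥ obs}) / (B + 1).
* `chi2_mixture`: the 50:50 χ²₀:χ²₁ mixture (single boundary parameter).
* `chi2_3`: a naive χ²₃ counting all three extra parameters.

### Heritabilities

h²_MILK = σ²_v / (σ²_v + σ²_e1) from the milk equation.  For ADG,
h²_direct = σ²_int / σ²_P and h²_mat = β²σ²_v / σ²_P.  The source's printed
σ²_P term list is ambiguous (one term appears twice; the covariance term's
coefficient is unclear), so two declared variants are always computed side
by side: *as-printed* (the literal term list,
σ²_int + σ²_e2 + β²σ²_e1 + σ_int-v + β²σ²_v + σ²_e1) and *conventional*
(the variance implied by the recursive model,
σ²_int + σ²_e2 + β²(σ²_v + σ²_e1) + 2βσ_int-v).  Neither reproduces the
previously published h² = 0.34/0.23 or phenotypic variance 2887 from the
same table of components; the report flags this discrepancy instead of
adjusting anything towards it.

## The synthetic-data generator

No data accompany the source analysis, so the generator emulates the study
conditions and is the substrate for every stochastic check.

* **Design**: three maternal-merit ewe groups (80 ewes each) × two
  direct-merit ram groups (6 rams each) in a factorial plan; every ewe is
  mated twice with the ram group alternating between matings; litters are
  twin-reared; milk measured at days 15/21/35; two cohorts spread the matings
  over three years (so `year` has three levels).
* **Genetics**: founder (ram/ewe) breeding values drawn from N(shift, G);
  descendants by gene dropping — parental average plus Mendelian-sampling
  deviation with covariance ½(1 − (F_s + F_d)/2) G.  Group shifts emulate
  parent selection: ram groups shift u_int by the reported group-mean direct
  EBVs, ewe groups shift v by the reported maternal EBVs divided by beta.
  The shift scale defaults to 0.5 because EBVs are shrunken predictors and
  full-gap shifts would overstate the observed group contrasts; it is
  configurable and affects only descriptive emulation.
* **Records**: generated from the model equations exactly, with the twin
  residual structure above.  Fat and protein contents are drawn around 60
  and 50 g/L to support TMS = (MF + MP)·MY; overall means are calibrated so
  MY ≈ 2.3 L/day and 0–35 d ADG ≈ 207 g/day; all other fixed-effect levels
  default to zero (the source prints no fixed-effect solutions) and are
  configurable.  The measurement-lag class LW is uniform on the integers
  −4…4 (only the range is documented).
* **Attrition** (optional, on in `study_design()`): ewe retention 166/240,
  litter retention 0.70 (fertility failures and allocation to artificial
  rearing), 2.5% lamb mortality removing the whole litter (a surviving
  single-suckled twin is excluded as unrepresentative), 2% individual record
  failures.  Expected counts land near the real experiment's 1284 records /
  442 lambs / 166 ewes.

What the generator does *not* emulate: litter sizes other than two, a
permanent environmental effect of ewe or lamb (both omitted from the final
source models), mortality as a process, non-Gaussian milk/gain noise, and
selection operating on phenotypes within the experiment.  Passing tests
therefore demonstrate correctness of the machinery under the stated model,
not robustness to real-data violations of it.

## Recovery studies and the choices behind them

Variance-component recovery is verified by simulating from the intercept
model at the fitted source components (σ²_e1 = 18, σ²_v = 35, σ²_e2 = 824,
σ²_int = 789, ρ_int-v = 0.47, β = 3.9; σ_e12 is not printed in the source
table and defaults to 0) at the attrited design scale, refitting each
replicate by REML, and averaging.  Two deliberate choices:

* **Founder shifts are off in recovery runs.**  The estimand (variance
  components) is defined under the zero-mean model; mean-shifted founder
  groups would add between-group genetic variance that the model attributes
  to σ²_int/σ²_v, biasing every recovery upward — the source itself notes
  heritability inflation from parent selection.  Shifts remain on by default
  for the descriptive tables.
* **Replicate counts are sized for routine desk runs**: 60 bivariate
  replicates (β, σ²_e2, ρ_int-v) and 100 milk-only replicates (h²_MILK) in
  the acceptance script; a 25-replicate smoke version in the test suite.
  Monte-Carlo standard errors are reported alongside every mean.

The RLRT calibration study runs on a reduced design (9 ewes, 4 rams, 162
records) so that a full parametric bootstrap is affordable: 30 null datasets
× 19 bootstrap draws (the bootstrap test has exact level 1/20 = 0.05 under
exchangeability), with power points at σ²_slope ∈ {63, 126} (8 and 12
datasets).  At this scale the binomial check on the type-I error is
necessarily coarse; it verifies consistency with the nominal level, not a
tight estimate of it.

## Numerical conventions and degenerate inputs

* Fixed-effect factors are treatment-coded against the first level in sorted
  order; single-level factors are dropped with a warning (litter size at
  birth is always single-level under twin rearing); never-observed
  interaction cells are skipped; residual collinearity is removed by
  pivoted-QR column pruning with a warning.  REML values are invariant to
  record order and to reference-level relabelling.
* Unknown parents are founders; parents referenced but not declared are
  auto-added as founders with a warning; pedigree cycles are errors.
* The pedigree is pruned to phenotyped animals plus ancestors before the
  relationship matrix is formed.
* Milk yield is dL/day internally; files store L/day; the per-day summary
  table reports mL/day.  TMS uses MY in L/day.
* 0–35 d ADG is the day-length-weighted mean of period gains
  (15·ADG₀₋₁₅ + 6·ADG₁₅₋₂₁ + 14·ADG₂₁₋₃₅)/35, i.e. (weight₃₅ − weight₀)/35
  when all periods are present; weights renormalise over observed periods.
* A simulated non-positive milk yield (probability ≪ 1% at the default
  parameters) is clipped to 0.1 dL with a warning.

## Known limitations

* Only the linear reaction norm is implemented; higher-order polynomials are
  out of scope (the source reports them non-convergent).  TMS can be used as
  the covariate through the same code path, but no convergence is promised.
* The parametric bootstrap refits with a single start per draw (warm-started
  at the parent estimates); rare refit non-convergence contributes noise to
  the bootstrap distribution rather than being resolved by multi-start.
* Delta-method standard errors for heritabilities are not implemented; the
  `HeritabilitySet` carries an optional SE field for future use.
* The nested-LRT fixed-effect selection operates on single-trait ordinary
  linear models (no relationship matrix), mirroring how such step-down
  selection is usually done in practice; it is not a mixed-model selection.
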