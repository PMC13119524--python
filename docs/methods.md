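# Methods

This note documents the models and numerical choices behind `phagesteer`:
what the simulator assumes, what its defaults mean, which design decisions
were genuinely open, and what a green test does and does not establish.

## 1. The serial-passage simulator

### 1.1 State and within-day dynamics

One culture is a well-mixed 4 mL batch holding, per bacterial genotype *i*,
a bulk count `N_i`, a dormant persister count `D_i`, and per phage *p* a free
particle count `P_p`.  Within a day the bulk follows, over short intervals,

    dN_i/dt = r (1 − c_i) (1 − N_tot/K) N_i  −  φ_p s_ip (P_p / V) N_i  (summed over phages)

the short-interval exponential growth/killing model extended with a logistic
crowding factor.  Infected cells are removed and release β_p new particles
within the same integration step (no explicit latent period — the 24 h
transfer cadence dominates, so collapsing the phage life cycle into the step
changes timing by minutes, not days).  Adsorbed particles are removed one per
infection; free particles additionally decay at rate δ_p.

Three structural extensions beyond that core are required for the model to
reach the empirically observed regime of *days-long suppression below optical
detection with continued evolution*:

1. **Carrying capacity K** (default 2×10⁹ cells/mL): rich-medium cultures
   plateau; without K, OD grows without bound.
2. **Wall-population refuge** (default 4×10⁶ cells total): the infection
   hazard of every cell is scaled by `max(0, 1 − R/N_tot)`.  A population at
   or below the floor is effectively inaccessible to phage, which is the
   standard explanation for why serial-culture phage experiments do not
   sterilize their hosts.
3. **Persister pool** (defaults: switching on 0.01 h⁻¹, off 0.05 h⁻¹):
   a per-genotype dormant compartment that neither grows nor adsorbs phage
   and is transferred like any other cell.  Persisters carry a lineage
   through transient overexposure — in particular, the ancestral lineage
   survives the hours-long windows in which a resistant clone's expansion
   lifts the total count far above the refuge floor.  Without this
   compartment those windows sterilize the ancestor, after which no further
   resistance routes can arise; with it, the mutational substrate recovers
   wherever phage pressure later relaxes.

Free-phage decay δ (default 0.6 h⁻¹ for both phages) is likewise essential:
with 1% daily transfers as the only sink, a single amplification burst leaves
a lethal particle stock for the rest of the experiment and no suppressed
coexistence exists at any (φ, β).

### 1.2 Stochastic scheme

The engine advances in fixed steps of `dt_hours` (default 0.05 h):

- **Divisions**: Poisson with mean `r (1−c_i)(1−N_tot/K) N_i dt` (a linear
  tau-leap; guarded — the per-cell division probability per step must stay
  ≤ 0.1, otherwise a `StepSizeError` instructs a smaller dt).
- **Infections**: `Binomial(N_i, 1 − exp(−Σ_p φ_p s_ip (P_p/V) · exposed · dt))`,
  allocated between phages by hazard weight.  This exponential-hazard
  thinning is the *exact* conditional sampling for a constant-P step and
  remains valid at the particle densities amplification produces
  (P/V ~ 10⁹–10¹⁰ mL⁻¹), where a linear-mean Poisson leap would not be.
- **Mutations** ride on divisions: `Poisson(divisions_src × μ(src→dst))`.
- **Persister switching** and **phage decay**: binomial thinning with
  exponential fractions.

Hazards are frozen over each step (explicit scheme); during amplification
bursts the phage count can grow by more than 10% per step, which delays
crash timing by at most a step or two — irrelevant at the 24 h observation
cadence.  A deterministic-expectation mode replaces every draw by its mean
(with a midpoint correction for the logistic factor) so that analytic tests
recover the exponential, logistic and constant-P killing closed forms to
high precision.

The inner loop is a numba-jitted kernel.  It seeds numpy's legacy
`RandomState` once per `grow_and_infect` call with a 31-bit integer drawn
from the per-population `Generator` stream, so every run is reproducible
given `(spec, params, seed, population_id)` and independent of execution
order (per-population streams derive from the experiment seed by a stable
CRC32 hash of the population id).

### 1.3 The day loop and measurement layer

Each day: apply any scheduled dose (doses are added right after the daily
transfer, so a 24/48/72 h second dose lands at the start of day 1/2/3) →
grow 24 h → record OD600, phage presence and genotype frequencies → transfer
1% into fresh medium (binomial thinning of every count).  OD600 uses a
saturating calibration `OD = OD_max · n/(n + n_half)` (defaults 1.5 and 10⁹
cells/mL, so a culture at carrying capacity reads OD 1.0); values below the
detection limit (0.01) are recorded at the limit and flagged censored.
Phage presence mimics the spot assay: free particles ≥ 10³ mL⁻¹.

Killing assays are simulated from the same parameters: both arms start at
the standard prep density (2.5×10⁶ cells/mL), run 30 min, the no-phage arm
grows at `r(1−c)`, the phage arm is additionally killed at
`φ s P/V` with ~10⁹ PFU of lysate (interpreted as total PFU in the ~4.1 mL
assay volume), and both densities are plated with Poisson colony noise at a
dilution targeting 30–300 colonies.  Expected counts below one colony on the
undiluted plate yield a flagged below-detection record imputed at the
plating limit.  Growth curves are logistic at `r(1−c)` from the prep
density, passed through the OD calibration, with multiplicative log-normal
noise.

### 1.4 The genotype lattice and what the defaults encode

The defaults encode the receptor biology of the study system — two
dual-receptor phages sharing one receptor — as a five-genotype lattice:

| genotype           | s_T2  | s_λ   | cost | μ from sensitive |
|--------------------|-------|-------|------|------------------|
| sensitive          | 1     | 1     | 0    | —                |
| t2_resistant       | 0.05  | 6.0   | 0    | 3×10⁻⁷           |
| cross_resistant    | 3×10⁻⁵| 3×10⁻⁵| 0    | 3×10⁻⁹           |
| mucoid             | 3×10⁻⁵| 3×10⁻⁵| 0.15 | 6×10⁻¹⁰          |
| lambda_resistant   | 1     | 0.5   | 0    | 5×10⁻¹⁰          |

plus a rare second-hit route t2_resistant → cross_resistant (10⁻¹⁰).
T2-specific resistance is the easy route but is only partial (T2 holds the
mutant in a below-detection quasi-equilibrium, feeding on it) and
collaterally hypersensitive to lambda — the pattern the source experiments
observed phenotypically.  The regulatory cross-resistant route and the
costly mucoid route are near-complete escapes from both phages but orders of
magnitude rarer.  Phage parameters: φ = 8×10⁻⁸ mL h⁻¹ for both, burst 50
(T2) vs 3 (lambda), so T2 amplifies explosively and crashes the culture
within hours while lambda amplifies weakly and catches the population late.
The per-population collateral-sensitivity draw (probability 0.3, s_λ → 1.5)
is retained for custom lattices whose T2-specific genotype still has
ancestral lambda susceptibility; the default lattice is already
hypersensitive.

None of these rates are measurements.  The study reports no adsorption
rates, burst sizes or mutation rates; all defaults are stand-ins calibrated
once — before the acceptance tests were frozen — to reproduce the
*qualitative* behaviour of the experiments (T2 alone suppresses below
detection for ≥ 3 days; lambda alone fails within days via cross-resistance;
the mean 14-day density orders T2-first < cocktail < lambda-first; the
cross-resistant-majority day orders lambda-first < cocktail < T2-first), and
never revisited.  The mechanism producing the orderings: under T2-only
selection the T2-specific sweep installs a persistent T2-fed lawn, the
ancestral persister pool drains, and cross-resistance is starved; in
cocktails lambda eliminates those sweeps, T2 then loses its food and washes
out, the ancestor resuscitates from dormancy and keeps supplying the rare
full-escape mutants; under lambda-first the population grows large before
lambda catches it, so the cross-resistance lottery is won on day 0–1.

### 1.5 What the generator does not emulate

No phage coevolution (phage genotypes are fixed), no sequence-level
mutation model, no receptor-expression mechanics, no spatial structure
beyond the scalar refuge, no latent period, and extinction is rare at
defaults (the refuge floor sustains populations; set `refuge_cells=0` and
`dormant_on=0` to recover absorbing extinctions).  A green steering test
therefore establishes that *this stated world* reproduces the published
orderings — not that the defaults estimate any biological rate.

## 2. Resistance coefficients

`compute_rc` implements the log-ratio statistic exactly; its preconditions
(positive densities, `wt_p < wt_np`) are enforced with typed errors, since a
benchmark in which the phage failed to kill the wild type makes the
denominator meaningless.  Confidence intervals are nonparametric percentile
bootstrap over replicate assay records (default 10⁴ resamples) — the paper
does not state its CI method, and the bootstrap needs no distributional
assumption on log-ratio noise; a closed-form t interval is available via
`method="normal"`.  Significance (CI excluding 0) drives the quadrant
classification: non-significant pairs are wild-type-like; otherwise signs of
the two means choose the quadrant, with a mixed-sign pair counting as
collateral sensitivity only when the negative dimension is itself
significant (otherwise single-phage resistance).  Below-detection records
are imputed at the plating limit and flagged, never silently dropped — the
resulting RC is then a lower bound on sensitivity.

## 3. Growth-rate estimation

The estimator fits OLS to `ln(OD − blank)` over every window of `h`
consecutive points, keeps windows with R² ≥ 0.95, takes the steepest, merges
overlapping neighbours whose slope is within 95% of the winner, and refits
over the merged span.  Points at or below the blank are clipped to
blank + 10⁻⁴ and flagged, and windows containing clipped placeholders are
excluded from both the competition and the merge (the placeholder creates
artificial jumps).  The default window is **h = 13 points (65 min)** rather
than the 5-point convention of the classic implementation: a max over ~50
correlated noisy 5-point slopes is ~15% upward-biased at 2% multiplicative
OD noise, whereas h = 13 recovers the true rate within 0.6% (mean over 50
simulated curves) at standard-deviation 0.009.  Slopes are computed per
minute and reported per hour.  `compare_growth_rates` is a one-way
fixed-effects ANOVA plus Welch t tests against the wild type with Holm
adjustment; an all-constant input yields a flagged undefined F rather than
an error.

## 4. Treatment-level statistics

The response is each population's arithmetic mean OD600 across the
experiment, censored days entering at the detection limit.  Regressions run
on the **rank-transformed response** (average ranks for ties) with
treatment-coded categorical predictors — the response is the only sensible
target of the rank transform since all predictors are categorical.  AIC is
the Gaussian likelihood of the rank-scale residuals with the constant
included consistently across candidates.  Model selection takes the minimum
AIC; a candidate within 2 AIC replaces the winner only when it has higher
adjusted R² with *no more* parameters — a pure adjusted-R² tie-break would
systematically pick the larger of two nested models on noise, defeating the
AIC parsimony penalty.

Mann–Whitney U tests are exact by full enumeration of the
`C(n_a+n_b, n_a)` rank assignments when the pooled sample is ≤ 14 and tie
free (two-sided p by symmetric deviation from the null mean, reported
statistic `min(U_a, U_b)`), otherwise the normal approximation with tie and
continuity corrections.  Families of pairwise comparisons use Holm's
step-down adjustment.  "24 h after the second dose" means the OD recorded at
the end of the day on which the dose was administered at the start — e.g. a
late (day 3) dose is evaluated at the day 4 recording.

### Known statistical limitations

- With 12 replicates per arm the per-population outcome is a rebound
  lottery, so arm samples are bimodal and pairwise Mann–Whitney tests have
  little power even when the mean ordering is nearly deterministic; the
  T2-first vs cocktail contrast is significant in only a minority of
  simulated runs.  Direction, not significance, is the robust signature.
- A 1-SD two-group effect at n = 12/arm has analytic power ≈ 0.66 (noncentral
  t), and the rank regression tracks that benchmark; claims of higher power
  at that effect size are not attainable.

## 5. Files and reproducibility

All artifacts are plain CSV/TSV with commented `# key: value` headers
carrying the seed and a SHA-256 hash of the full run configuration; schemas
are validated strictly on read.  `run_pipeline` chains simulation, response
construction, model selection, pairwise tests, killing assays, RC profiles
and growth-rate estimation deterministically from one `RunConfig`.
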