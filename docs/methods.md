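# Methods

`outcome_qba` implements quantitative bias analysis (QBA) for
misclassification of *cause-specific* outcomes in a two-arm
(active-comparator) cohort, together with the propensity-score weighting
that such analyses are usually combined with, and a synthetic cohort
generator that makes the whole chain testable without patient-level data.

## The problem being modelled

In routinely collected health data, whether a patient was hospitalised or
died is recorded reliably, but the *cause* attached to the event may not
be. If a condition's diagnosis code has sensitivity Se and specificity Sp
among patients with an any-cause event, the observed exposure–outcome
association is distorted — under non-differential error, biased toward the
null. QBA inverts that distortion under explicit assumptions about
(Se, Sp).

The central structural choice, carried through every module, is the
**cause-specific restriction**: the correction operates only among patients
with an any-cause event (hospitalised, or died, of any cause). Patients
without an event are treated as correctly recorded non-cases and are
re-inserted unchanged before effect estimation. Event *occurrence* is taken
as accurate; only the recorded *cause* can be wrong.

## Correction algebra

For one exposure arm with `N` any-event patients, `x` of them observed
cases, the corrected (true) case count is

    A = (x − (1 − Sp)·N) / (Se + Sp − 1),

which requires Se + Sp > 1 (otherwise the correction is not identifiable
and the package refuses). Corrected prevalence π = A/N gives predictive
values

    PPV = Se·π / (Se·π + (1−Sp)(1−π))
    NPV = Sp·(1−π) / ((1−Se)·π + Sp·(1−π)),

and re-adjusting the observed table with PPV/NPV reproduces the corrected
cells exactly (an algebraic identity the tests verify numerically). A
corrected cell ≤ 0 means the assumed (Se, Sp) are incompatible with the
observed counts — typically too many implied false positives. Such
corrections are *flagged*, never patched: simple bias analysis raises an
error naming the offending arm; Monte Carlo analyses count and discard the
iteration, and the discard fraction is reported. Discarded iterations are
not resampled.

Effect estimation is by odds ratio throughout: `OR = (a/b)/(c/d)` with Wald
95% intervals `exp(log OR ± 1.96·SE)`, `SE = sqrt(1/a + 1/b + 1/c + 1/d)`.
Fractional corrected cells flow through unrounded; rounding happens only at
reporting. No continuity correction is applied to zero cells — a zero cell
is treated as a failed correction, matching the discard policy.

## Bias-parameter priors

Se and Sp priors are beta distributions, optionally rescaled affinely onto
`[lower, upper]` ⊂ [0, 1]. The rescaling expresses hard data-driven bounds:
if only 5% of any-cause hospitalisations are observed cause-specific, the
false-positive fraction cannot exceed 5%, so Sp ≥ 0.95 and a prior of the
form `Sp = 0.95 + 0.05·X, X ~ Beta(1, 1)` is natural. A degenerate spec
with `lower == upper` is an exact point mass, used for fixed-parameter
analyses.

Elicitation goes from a `(2.5th, 50th, 97.5th)` percentile triple to
shapes by least squares on the quantile function over `(log α, log β)`,
accepting the fit only if every quantile is matched within **0.005** (half
a unit in the second decimal, the precision at which such summaries are
typically communicated). Three quantile constraints on two parameters are
generically over-determined: symmetric triples around a high median are
often infeasible because betas there are left-skewed, and the error then
reports the best-achieved quantiles so the user can adjust. Se and Sp are
sampled independently (no prior correlation).

## Simple bias analysis (SBA)

One pass of: subpopulation table → matrix correction → re-insert
non-events → crude OR, at fixed (Se, Sp). Deliberately a *point estimate
only*: a standard error computed from the adjusted table would ignore the
uncertainty in the bias parameters themselves and overstate precision, so
no interval is attached (downstream report tables carry interval type
`none`).

## Summary-level probabilistic bias analysis

Each of `n_iterations` (default 100 000) iterations draws (Se, Sp) from
the priors, corrects the table, computes PPV/NPV, and re-adjusts. Two
optional error layers, both on by default:

- **misclassification random error** — instead of the expected adjusted
  counts, a binomial realisation: `Binomial(x, PPV) + Binomial(N−x, 1−NPV)`
  per arm. This is the summary-level analogue of the record-level Bernoulli
  trials and has exactly the expected-adjustment mean; the precise
  mechanism is a design choice of this package.
- **conventional random error** — one standard-normal multiple of the
  iteration's conventional log-OR standard error, subtracted from the log
  OR (the sign is irrelevant by symmetry).

Retained draws are summarised by the median and the 2.5th/97.5th
percentiles (the 95% simulation interval, SI). The SI therefore reflects
systematic error, bias-parameter uncertainty, misclassification randomness
and conventional random error together, and is wider than the conventional
CI. Turning layers on can only widen the SI at a fixed seed (tested).

Randomness under one seed is consumed in a fixed order — Se draws, Sp
draws, binomial draws, normal draws — so results are bit-reproducible.

## Record-level probabilistic bias analysis

Per iteration (default 10 000): draw (Se, Sp); correct the observed
subpopulation table to get per-arm PPV/NPV *for that draw*; then
reclassify each any-event patient by a Bernoulli trial — observed-positive
patients remain cases with probability PPV, observed-negative patients
flip with probability 1 − NPV; non-event patients always remain non-cases.
Unweighted and IPT-weighted logistic models of the simulated outcome on
exposure are then fitted on the full cohort, producing paired OR streams
from the same iterations.

Hospitalisation outcomes are handled per episode: each observed-positive
episode keeps with PPV, each observed-negative episode flips with 1 − NPV,
and the patient is a case if any episode simulates positive. Since episode
dates are out of scope, "first positive episode" and "any positive
episode" select identical patients, and the per-episode trials are realised
through the exact closed-form patient probability
`1 − (1−PPV)^k⁺ · NPV^k⁻` (distributionally identical; verified against
explicit per-episode trials in the tests). Episode-level predictive values
are taken equal to the patient's arm-level values.

Two implementation economies, both with test-enforced equivalences:

- Propensity scores are fitted **once** and reused across iterations —
  outcome reclassification cannot alter treatment assignment.
- The per-iteration logistic fits contain exposure as the sole covariate,
  so their ML odds ratios equal the (weighted) 2×2 crude ORs; iterations
  use the 2×2 path, and the model-vs-table equivalence is asserted against
  statsmodels separately.

## Propensity scores and weighting

Main-effects logistic regression of exposure on the covariate battery
(statsmodels GLM); ATE weights `1/PS` (exposed) and `1/(1−PS)`
(comparator), unstabilised by default with stabilised weights behind a
flag. Scores are trimmed to the common support (intersection of arm-wise
score ranges) before outcome modelling and before QBA table construction;
trimming is *not* repeated inside PBA iterations. Weighted outcome models
use a robust HC0 sandwich variance, the standard choice for weighted
estimating equations. Balance is reported as standardised mean differences
`(m₁ − m₀)/sqrt((v₁ + v₀)/2)` with weighted moments after weighting.

## Sensitivity grids

Deterministic sweeps over fixed (Se, Sp) values — including arm-specific
sensitivities at a shared specificity, for probing differential
misclassification — with random-error layers off by default so each cell
is a pure function of the observed table. Invalid cells (negative
corrected counts) carry a sentinel status rather than an exception so that
heatmaps over partially-infeasible regions still render.

## Synthetic cohort generator

The generator emulates the data structure the method assumes:

1. A small covariate battery (age ~ Normal(70, 10); gender, smoking,
   prior exacerbation, history of asthma as Bernoullis) standing in for a
   full confounder set — sufficient to create and remove confounding.
2. Treatment assignment by a logistic model on (centred) covariates; the
   intercept is solved by bisection so the expected exposed count equals
   `n_exposed`. History of asthma and prior exacerbations carry the
   largest assignment effects, mirroring the kind of channeling seen in
   respiratory cohorts.
3. Any-cause hospitalisation and death from logistic models on covariates
   plus arm (`any_event_or_exposed`, default 1.15).
4. True cause-specific outcomes only among any-event patients, with
   exposure log-odds `ln(true_or_*)` and no further covariate terms, so
   the subpopulation effect is exactly the configured odds ratio.
5. Hospital episodes: `1 + Poisson(episode_rate − 1)` per hospitalised
   patient (the episode-count distribution is a free parameter; no
   empirical distribution was available to copy). A true case carries its
   cause on exactly one uniformly chosen episode.
6. An observation layer produced by the misclassification operator:
   per-patient for deaths, per-episode for hospitalisations, optionally
   differential by arm.

Default scale: 56 059 exposed vs 22 319 comparator patients; any-cause
death ~2.6% (comparator) with ~12.5% of any-cause deaths cause-specific;
any-cause hospitalisation ~12% with ~5% cause-specific; cause-specific
risks ≈0.9%/0.6% (hospitalisation) and ≈0.5%/0.3% (death). Under these
defaults the expected true case counts are ≈529/133 hospitalisations and
≈294/72 deaths.

Note one estimand subtlety the test suite leans on: the generator's
`true_or_*` is a *subpopulation* odds ratio, while the analyses report
*full-cohort* ORs. For rare outcomes the two nearly coincide; for common
outcomes they differ by a deterministic margin factor, and experiments
that target a specific full-cohort OR solve for the subpopulation
parameter analytically.

What the generator does **not** emulate: treatment-episode construction
from prescriptions, censoring (follow-up is implicit and complete),
missing covariate data, calendar-time variation in coding accuracy, and
misclassification differential by a confounder. Passing tests show the
*method* behaves correctly under the generator's assumptions; they cannot
show that any particular real dataset satisfies those assumptions.

## Numerical choices and degenerate inputs

- Elicitation tolerance 0.005 per quantile; infeasible triples raise with
  the best-achieved quantiles and shapes attached.
- Corrections with any cell ≤ 0 are invalid; with Se + Sp ≤ 1,
  non-identifiable (error). Zero any-event counts in an arm make the
  subpopulation table degenerate (error).
- All Monte Carlo stages derive their generator from
  `SeedSequence([root_seed, crc32(stage_label)])`, giving independent,
  platform-stable streams per stage; the pipeline fans one root seed out
  to per-stage seeds the same way.
- Iteration counts in the test suite are 100–2000 (simulation intervals
  then carry proportionally more Monte Carlo error than the 100 000 /
  10 000 defaults; medians are stable well below that).
- Binomial sizes in the summary-level misclassification layer are the
  observed (integer) cell counts; observed tables are integer by
  construction.

## Known limitations

- Only outcome (cause) misclassification is modelled — not exposure or
  covariate error.
- Only beta (optionally rescaled) priors; no trapezoidal/triangular/
  logit-normal alternatives, and no Se–Sp correlation.
- Logistic/OR estimation only; no time-to-event analysis within
  iterations.
- The summary-level misclassification random-error mechanism is one
  reasonable realisation (binomial with observed-cell sizes); other
  choices would change SI width slightly, not the median.
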