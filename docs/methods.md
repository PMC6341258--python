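# Methods

## The fuzzy evaluation system

`fuzzpk` aggregates three model-selection criteria — AIC, the Schwarz
criterion (CS) and the estimated error variance (MSE) — into one Fuzzy System
Evaluation (FSE) score with a Mamdani system: AND = min, implication = min
(clipping), aggregation = max. Each input carries five ordered linguistic
terms (Very Low … Very High) as triangular/trapezoidal membership functions;
the output "Evaluation" variable spans [0, 100] with terms Optimal
(trapezoid [0,0,10,30]), High Acceptable (triangle [10,30,50]), Acceptable
(triangle [30,50,70]), Low Acceptable (triangle [50,70,90]) and Rejected
(trapezoid [70,90,100,100]). Lower FSE is better; the robot selects the
minimum-FSE candidate, ties broken by the earliest row (and reported).

Input universes are taken as the hull of each variable's membership supports:
AIC [670, 680], CS [676.6, 698], MSE [0.092, 0.14]. The published table that
lists a CS maximum of 795 is inconsistent with the membership parameters (no
term has support above 698) and is treated as a typo. The High Acceptable
output term ships with three breakpoints and no shape tag; it is triangular.

### Defuzzifiers

Two variants are provided because the source material describes a centroid
("center of gravity") while printing a center-average formula:

* `discretized_centroid` (default): Σ xᵢ·μ(xᵢ) / Σ μ(xᵢ) of the
  max-aggregated output profile on a uniform grid. Grid resolution defaults
  to 10,001 points on [0, 100]; doubling it moves results by < 0.01 FSE
  units, and the engine agrees with an independent 100,001-point brute-force
  implementation to better than 0.1 FSE over the whole input space. The grid
  sum order is fixed, so results are bitwise deterministic.
* `center_average`: C = Σ bᵢ·Aᵢ / Σ Aᵢ over fired *rules*, where bᵢ is the
  consequent's center (apex, or plateau midpoint for trapezoids) and Aᵢ the
  area of the consequent clipped at the rule's firing strength.

The default is the centroid: it is the variant that reproduces the published
worked example (75.2) and six-model table; the center-average variant yields
systematically higher scores for Rejected-dominated inputs (it collapses any
pure-Rejected firing to the fixed center 95).

### Out-of-range inputs

Candidate models can have criteria outside the membership supports (the
published table contains one with AIC = 682.7 and CS = 707.5). Two policies:

* `saturate_extremes` (default): the first and last term of each input are
  treated as open-shouldered — degree 1 beyond their peak breakpoint. Every
  finite input then receives a nonzero degree somewhere (coverage), and
  extreme candidates are scored rather than dropped. This also covers the
  sliver of the CS universe (676.6–679.6) where the printed Very Low
  trapezoid's ascending edge would otherwise leave degrees near zero.
* `clamp_to_universe`: inputs are clipped to the universe and the printed
  shapes evaluated verbatim. Under this policy an input can legitimately fire
  no rule; that is surfaced as a distinct "no rule fired" diagnostic
  (an exception in the library, a flagged last-ranked row in the robot),
  never silently mapped to a number.

### The rulebase and its corrections registry

The 125-rule base is the full 5×5×5 product of input terms. The published
table has three defects, handled by an explicit registry
(`fuzzpk.popk.CORRECTIONS`) and two modes:

1. rule 5 prints the impossible MSE label "Very" with consequent Optimal:
   read as (Very Low, Very Low, Very High); corrected consequent Rejected
   (the ordinal continuation of rules 1–4 and of every other Very-High-MSE
   row);
2. rule 6 (Very Low, Low, Very Low) is missing: corrected mode inserts it
   with consequent Optimal (its best-possible neighbours are all Optimal);
3. rule 80 duplicates rule 100's antecedent (High, Very High, Very High),
   leaving (High, Very Low, Very High) unmapped: corrected mode reassigns
   rule 80 to the unmapped antecedent, keeping Rejected.

`corrected` is the default (it is the only mode satisfying the exhaustive
125-rule completeness claim, which is verified at build time); `as_printed`
keeps the table verbatim for comparison. The two modes differ only on inputs
whose fired rules include a corrected combination.

The corrected base is ordinally monotone along the MSE antecedent (for fixed
AIC/CS terms, a worse MSE term never improves the consequent) — this is
asserted in the tests. It is *not* monotone along AIC and CS: several printed
rules rate AIC "Low" one notch better than "Very Low" at equal CS/MSE (e.g.
(Low, Medium, Very Low) → Optimal vs (Very Low, Medium, Very Low) → High
Acceptable), and the CS direction inverts once ((High, High, Low) → Rejected
but (High, Very High, Low) → Low Acceptable). These
rules are load-bearing for the published six-model scores, so they are
preserved; as a consequence the crisp FSE surface is not globally monotone in
each input, and the corresponding acceptance check documents the failure
rather than papering over it. Users who need a monotone evaluator should
edit the shipped YAML configuration.

### Configuration

The complete system (variables, universes, terms, rules, options) round-trips
losslessly through YAML; the corrected default ships as package data
(`fuzzpk/data/popk_fis.yaml`). A configuration hash is recorded in every run
report so results are attributable to an exact configuration.

## Criteria

* `AIC = N·log(OFV) + 2·NP`
* `SC  = N·log(OFV) + NP·log(NP)` — as published. The penalty differs from
  the textbook Schwarz `NP·log(N)`; the textbook form is available behind
  `penalty="np_log_n"` and is never substituted silently.
* `MSE = Σ r² / (n − p)` — the REML-adjusted error variance; `p = 0` gives
  the plain divide-by-n estimator.

The objective function value (OFV) entering AIC/SC is not fixed by the
formulas; it is a declared configuration choice with default `"mse"`
(= SSE/N from the fit's population residuals), alternatives `"sse"` and
`"minus_two_loglik"`. Logarithms are natural by default; the base is a
parameter. All choices are recorded in run metadata.

## The NLME machinery

Structural model: one-compartment IV bolus, `Cp(t) = (D/V)·e^{−(Cl/V)t}`.
Population model: linear covariate models for V and Cl (intercept plus
per-covariate coefficients), additive independent random effects
η ~ N(0, diag(ω²_V, ω²_Cl)), additive residual ε ~ N(0, σ²) shared across
candidate models. Simulated concentrations may be negative under additive
error; they are kept, not truncated. Subjects whose drawn V would be
non-positive (or Cl negative) are redrawn and logged. Simulation is fully
reproducible from a seed, which is also written to a sidecar metadata file
next to every simulated CSV.

### Default study conditions

The reference population is tobramycin-like adult: V = 20 L, Cl = 5 L/h
(intercept-only), ω²_V = 4 L², ω²_Cl = 0.25 (L/h)² (≈10% between-subject CV
each), σ² = 0.04 (mg/L)², a single 100 mg bolus sampled at 0.5, 1, 2, 4, 6
and 8 h. Covariates (WT, AGE, HT, SEX; BMI derived from WT and HT) are drawn
from plausible adult marginals and carried in the dataset even when the
generating model ignores them, so misspecified covariate models can be fit
to the same data. The recovery study in the test suite uses 50 subjects × 6
samples and 20 seeded replicates — large enough for ~1–5% fixed-effect error
under these conditions while keeping the whole suite fast on one CPU.

What the generator does *not* emulate: dosing by body weight, multiple or
infusion dosing, proportional/combined residual error, correlated random
effects, censoring below a quantification limit, and irregular per-subject
sampling. Passing recovery tests therefore demonstrate the estimator on
clean, balanced, additive-error data — not on the messier designs of real
therapeutic-drug-monitoring datasets.

### Estimation

The marginal likelihood of a nonlinear mixed model has no closed form; the
package uses the classical first-order (FO) approximation: f is linearized
in η around η = 0, giving per-subject Gaussian marginals
y_i ~ N(f_i(θ), Z_i Ω Z_iᵀ + σ²I) with Z_i the analytic (∂f/∂V, ∂f/∂Cl)
sensitivities. The objective is −2× this log-likelihood plus the REML
adjustment log det(Σ_i X_iᵀ V_i⁻¹ X_i), X_i the Jacobian in θ. Variances are
optimized on the log scale (positivity by construction).

Optimization is quasi-Newton (L-BFGS-B) capped at `max_iter` (default 100)
iterations, entered from fixed-effect initial values of 0.01 (default)
through two preparatory steps that make that deliberately remote start
workable:

1. a pooled nonlinear-least-squares warm-up for θ (trust-region reflective,
   with a smooth penalty keeping individual V positive), and
2. moment-style variance starts: per-subject residuals are projected onto
   the (V, Cl) sensitivities to give crude η estimates whose spread
   initializes ω², the leftover within-subject spread initializing σ².

Without step 2 the FO-REML surface has a slow ridge along which fixed-effect
error trades off against inflated ω², and the quasi-Newton stage can
terminate on it. Non-convergence is flagged on the returned fit rather than
raised, because the selection loop must still be able to compute criteria
for a poorly behaved candidate. NP is counted as fixed effects + 2 random-
effect variances + σ², and is exposed so users can reconcile parameter
counts with external software.

### Degenerate inputs and numerical guards

Non-finite or non-positive individual V during likelihood evaluation returns
a large finite objective (1e12) instead of NaN; Cholesky failures likewise.
The centroid defuzzifier raises on an identically-zero profile; `find_lowest`
raises on empty input and breaks ties to the earliest index. Evaluation-table
rows with a "no rule fired" diagnostic are excluded from selection and ranked
last.

## Known limitations

* The membership ranges are tuned to one drug's criteria scale; applying the
  evaluator to another drug requires re-ranging the input variables (edit the
  shipped YAML config). No automatic re-ranging is attempted.
* Only AIC/CS/MSE are aggregated; likelihood-ratio tests, VPCs and other
  diagnostics are out of scope.
* The estimator is FO-REML only (no FOCE/Laplace/SAEM), one-compartment
  bolus only, additive residual error only.
* The crisp FSE surface is not globally monotone in each criterion (see the
  rulebase discussion above): two near-tied bad models can swap order within
  a fraction of an FSE unit.
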