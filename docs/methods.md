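# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and
the numerical choices a maintainer would want written down.

## Data model and cleaning

A report store is a set of normalized pandas tables (one row per report;
child tables for drugs, reactions, outcomes, indications) plus a
vocabulary mapping each PT to exactly one System Organ Class and holding
the DME/IME term sets. Ingestion accepts the dollar-delimited quarterly
dialect (DEMO/DRUG/REAC/THER/OUTC/INDI joined on `primaryid`) or a flat
one-row-per-(report, reaction) CSV. Values are parsed forgivingly —
unparseable dates become missing and are logged; ages are converted from
their unit codes (YR/DEC/MON/WK/DY/HR) and set missing outside 0–120
years, weights likewise outside 1–500 kg — while structure is strict: a
missing mandatory column is a hard error naming file and column, and a
report without any reaction row is dropped (it describes no analysable
event).

Deduplication keeps, within each group sharing a case key, the report
with the greatest receipt date (ties broken by the lexicographically
greatest report id). The key is the case identifier when present;
otherwise the (event-onset date, primary-suspect drug, sorted reaction
list) triple, i.e. the fields that identify "the same patient, drug and
event description" when no registry id is available. The operation is
idempotent and its removal count is logged in the store's provenance.

Drug-name matching is case-insensitive on alphanumeric-only strings with
a caller-supplied alias map (brand → generic), so trade-name spellings
match without shipping a proprietary dictionary.

For the baseline table, multi-outcome reports are collapsed to a single
worst outcome with precedence death > life-threatening > disability >
hospitalization > other; reports with no severe outcome code fall into
an "others" bucket. This precedence is a design choice (the usual
published tables do not state one); it is pinned by tests and
configurable in code.

## Disproportionality

The counting unit is the (report, event) pair: a report with k distinct
PTs contributes k pairs, and at SOC level PTs are first mapped and
de-duplicated within report. The comparator is the full cleaned database
(or, for subgroup screens, the same stratum — the stratum is its own
background, so a subgroup signal means disproportionate *within* that
stratum, not merely a reflection of overall imbalance).

Formulas and flags are as in the README table. Numerical details:

* ROR: the Haldane–Anscombe 0.5 correction is applied to all four cells
  when any cell is zero, and flagged in the result. PRR, IC and EBGM
  handle `a = 0` natively, so no correction is applied there.
* χ² uses the Yates continuity correction by default (switchable off);
  the statistic is clamped at zero when the correction exceeds the raw
  difference.
* The BCPNN information component uses the closed-form shrinkage version
  `IC = log2[(a+½)/(E+½)]` whose posterior is `Gamma(a+½, E+½)` on the
  rate ratio; IC025 uses the standard two-term credible-interval
  expansion. The test suite checks both against a 10⁶-draw Monte-Carlo
  sample of that posterior (tolerance 0.15 for a ≥ 5; the error of the
  mean approximation is ≈ `1/(2a·ln2)`, so the bound is tight at a = 5).
  A four-cell Dirichlet posterior was considered as the oracle and
  rejected: it targets a different quantity and diverges from the
  shrinkage IC by more than 0.15 on legitimate tables.

### MGPS

The two-gamma mixture prior is fitted by EM on the negative-binomial
marginal likelihood of all (primary-suspect drug, event) pairs. Each
M-step maximizes the responsibility-weighted component likelihood
numerically in (log α, log β) with analytic gradients, warm-started at
the current values and accepted only if it does not decrease the
objective — so the marginal log-likelihood trace is non-decreasing by
construction (asserted in tests). Stopping is at relative log-likelihood
change ≤ 1e-8, capped at 10,000 iterations (non-convergence returns the
best-so-far, flagged).

Two numerical safeguards matter in practice. First, log-parameters are
box-bounded at ±9: on near-null data the two components merge and would
otherwise drift toward infinite-precision gamma spikes, creeping through
thousands of iterations. Second, EM is run from three starts — a
moment-based split of the observed a/E ratios at their median, the
classic diffuse start (0.2, 0.1, 2, 4, ⅓), and a tail-targeted start
with a tiny-weight component at the largest observed ratio — keeping the
highest-likelihood fit. The third start exists because with only one or
two truly elevated pairs in a few thousand, both generic starts converge
to a merged single-component optimum that over-shrinks the real signal
(a verified inferior local maximum). Components are relabelled by
ascending prior mean.

EBGM is `exp(Σ wⱼ[ψ(αⱼ+a) − ln(βⱼ+E)])` over the posterior components;
EB05 is found by Brent root-finding on the analytic mixture CDF
(tolerance 1e-12). Both are checked against direct numerical integration
of the posterior density to 1e-4.

## Clinical priority

The rubric is exactly the four-dimension 0/1/2 scoring with bands 0–2 /
3–5 / 6–8. Boundary conventions are pinned by tests: a reporting rate of
exactly 10 % scores 1 (the top band is strictly above 10 %); fatality of
exactly 25 % or 50 % scores 1 (middle band inclusive on both ends).
Stability counts positives among exactly three designated algorithms,
defaulting to PRR, BCPNN and MGPS — the screen's remaining algorithm
(ROR) acts as the headline filter, and the designated subset is
configurable because the choice is not canonical. Case fatality for an
event is the share of that event's cohort reports listing a death
outcome.

## Time-to-onset

TTO is onset minus therapy start in whole days, same-day events coded 1
(so the minimum observable TTO is 1; exclusion of same-day events is
available by flag). Reports missing either date, with onset before
start, or beyond 3,650 days are excluded and counted by reason. There is
no censoring model: a spontaneous report exists only because its event
occurred, so Kaplan–Meier curves are descriptive (survival = 1 − ECDF)
and the log-rank test compares observed distributions; both are
delegated to lifelines, with exact tie handling via the hypergeometric
variance.

The Weibull fit solves the 1-D profile score equation for the shape by
bracketed Brent root-finding (the equation is monotone in β), takes the
scale in closed form, and builds 95 % CIs from the finite-difference
observed information in (ln α, ln β) — log-scale Wald intervals, chosen
because they respect positivity; coverage is verified at 93–97 % in
simulation. The failure-type label uses the CI against 1, not the point
estimate. Day-resolution rounding biases the fitted shape slightly
upward (≈0.67 → ≈0.70–0.72 at cohort scale); this is a property of the
day-coded data, not of the estimator, and is visible in the acceptance
output.

## Demographic risk model

The response marks reports listing any designated target PT; covariates
are dummy-coded age (<18 reference / 18–65 / ≥65), weight (<80 kg
reference / 80–100 / >100) and sex (female reference). Rows with any
missing covariate are dropped and counted; no imputation. The fit is
straight Newton/IRLS to gradient sup-norm 1e-10 with standard errors
from the inverse observed information; Wald ORs by default,
profile-likelihood intervals available per term (sparse-outcome
intervals are asymmetric, and published intervals for such models are
often wider than Wald — both are exposed, neither certified). Complete
or quasi-separation (a covariate cell with no events) is detected by
coefficient blow-up and flagged; the OR table refuses to print a
separated fit. With the realistic 80 % weight missingness, a cohort of
~10,000 reports leaves only a few hundred complete rows and the under-18
reference cell routinely separates — the analysis scripts therefore show
both the cohort-scale behaviour and a recovery fit on a larger universe
(120,000 reports, focal-drug share 0.3, weight missingness 0.45, ~14,000
complete rows) where every planted coefficient is recovered within two
standard errors.

## Synthetic data generator

The generator emulates the structure of a quarterly spontaneous-report
extract with known ground truth. Defaults are the study conditions of
the oncology cohort the package was built around: sex mix 38.0 % female
/ 54.7 % male / 7.3 % missing; age Normal(60, 18) truncated to 0.5–100
with 21.8 % missing; weight Normal(72, 16) kg with 80.95 % missing;
reporter and country mixes from the published baseline table; onset
times Weibull(shape 0.67, scale 37.64 days) added to therapy start and
ceiled to whole days (minimum 1); therapy-start/onset missingness set so
about a third of reports yield a computable TTO; focal-drug share 5 % of
reports (one drug against a large background, scaled to desk size);
2 % of cases carry an injected earlier version to exercise
deduplication.

Events are independent Bernoulli draws per report at baseline × planted
relative risk (capped at 0.95); baselines for unnamed events are drawn
log-uniformly in [0.001, 0.015] from a *fixed* condition stream, so
different sampling seeds share one universe. A designated target event
("hepatic_failure", a DME with 55 % fatality) instead follows a
demographic logit model on the focal drug — intercept −2.80, age 18–65
−0.02, age ≥65 +1.16, weight 80–100 kg −1.55, >100 kg −1.56, male +0.61
— so the risk-model stage has exact planted coefficients. Reports that
draw no event are assigned the nonspecific filler term
"drug_ineffective" rather than a re-draw: a baseline-proportional filler
was measured to bias a planted relative risk of 10 down to ≈3 in sparse
vocabularies, whereas a dedicated filler leaves every studied event's
law exact (and mimics the nonspecific terms that dominate real data).
An empty coefficient dictionary disables the logit override entirely,
giving a pure null universe for calibration runs.

What the generator does **not** emulate: correlated co-reporting of
events within a report, concomitant-drug structure and confounding by
co-medication, indication-dependent event rates, stimulated-reporting
waves, duplicate records that differ between versions, and real MedDRA
granularity (the vocabulary is a fixture). Passing tests therefore show
the statistics behave correctly under the stated sampling laws — they do
not show robustness to reporting biases that violate those laws.

## Problem sizes in tests and acceptance

Calibration and power checks run at 50,000 reports: the null universe
(200 events, no plants, 20 seeds) bounds the all-four-positive rate at
1 % and the any-algorithm rate at 10 %; the power check (100 seeds)
plants relative risk 5 on an event sized for an expected drug-event
count of ~30, with the focal-drug share at 2 % — the pair-level
observed/expected ratio under a planted report-level RR is
`RR/(1 + (RR−1)·s)` for focal share `s`, so a rare focal drug (as in
real extracts) is the regime where the Bayesian shrinkage statistics are
diagnostic. Weibull recovery uses n = 3,000 (point recovery ±0.05) and
500 replicates at n = 200 (CI coverage). The acceptance script's
end-to-end run uses ~200,000 reports, giving a primary-suspect cohort of
~9,800 — the scale of the real cohort.

## Known limitations

* The EM likelihood surface is multimodal; three starts cover the
  regimes seen in testing but a pathological universe could still defeat
  them (the likelihood-ordered selection makes this detectable: a merged
  fit over-shrinks visibly).
* Subgroup screens use the stratum as its own background; the
  alternative (full-database background) is not implemented.
* The logistic model drops incomplete rows; with informative
  missingness its estimates are biased accordingly.
* SOC-level MGPS operates on a small universe (drugs × SOCs), so its
  prior is fitted on few pairs and shrinkage at SOC level is strong.
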