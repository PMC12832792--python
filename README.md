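# pvsignal

Pharmacovigilance signal detection on spontaneous adverse-event reports,
for drug-safety analysts and methodologists who want the full post-market
workflow — ingestion, deduplication, disproportionality screening,
clinical triage, onset-time modelling and demographic risk modelling — as
one reproducible, testable Python pipeline.

Spontaneous reporting databases (the FDA's quarterly ASCII releases are
the canonical example) hold millions of reports, each naming a suspect
drug, one or more reaction terms coded as MedDRA Preferred Terms (PTs),
demographics, outcomes and dates. Because there is no denominator of
exposed patients, safety signals are found by *disproportionality*: a
drug–event pair is suspicious when it is reported more often than the
database background predicts.

## Methods at the core

Every (drug, event) pair is summarised by the 2×2 table of (report,
event) pairs — `a` with drug and event, `b` drug only, `c` event only,
`d` neither, with `E = (a+b)(a+c)/n` the count expected under
independence. Four standard statistics are computed, each with its
conventional positivity criterion:

| statistic | definition | positive when |
|---|---|---|
| ROR | `ad/bc`, 95 % Wald CI on the log scale (Haldane–Anscombe 0.5 correction on zero cells) | `a ≥ 3` and CI lower bound > 1 |
| PRR | `[a/(a+b)] / [c/(c+d)]` with Yates-corrected χ² | PRR ≥ 2, χ² ≥ 4, `a ≥ 3` |
| BCPNN IC | `log2[(a+½)/(E+½)]`, closed-form 95 % credible bound `IC025 = IC − 3.3(a+½)^−½ − 2.4(a+½)^−3/2` | IC025 > 0 |
| MGPS EBGM | posterior geometric mean of the reporting-rate ratio λ under an empirically fitted two-component gamma mixture prior, with 5th posterior percentile EB05 | EB05 > 2 |

The MGPS prior `λ ~ p·Gamma(α₁,β₁) + (1−p)·Gamma(α₂,β₂)` is fitted by EM
on the negative-binomial marginal likelihood over the whole screening
universe; the per-pair posterior is again a two-gamma mixture, so EBGM
and EB05 follow from digamma identities and root-finding on the mixture
CDF.

Positive signals are triaged by a semi-quantitative rubric scoring four
dimensions 0/1/2 — reporting rate (>10 % / 1–10 % / ≤1 %), stability
across three designated algorithms (3/3, 2/3, fewer), reported case
fatality (>50 % / 25–50 % / <25 %), and designated / important medical
event (DME/IME) list membership — banded into low (0–2), moderate (3–5)
and high (6–8) clinical priority.

Time-to-onset (days from therapy start to event onset, same-day coded 1)
is fitted with a two-parameter Weibull by profile maximum likelihood;
shape β with 95 % CI entirely below 1 labels the hazard *early failure*
(events concentrate right after initiation), above 1 *wear-out*,
otherwise *random*. Kaplan–Meier curves and log-rank tests compare
strata. A multivariable logistic model (IRLS, implemented in-package)
estimates odds ratios of designated target events by age band, weight
band and sex.

Because real quarterly extracts are too large to ship, the package
includes a synthetic report generator with planted ground truth (known
relative risks, Weibull onset law, demographic logit coefficients) whose
defaults mirror a published oncology cohort; every stage is validated
against what was planted.

## Worked example

```bash
cd analysis
python 01_simulate_reports.py   # 50,000-report universe, seed 1
python 03_signal_screen.py
python 04_prioritize.py
```

prints (abridged):

```
PT screen: 199 events, 6 positive by >=1 algorithm, 3 by all four
   hepatic_failure: a=284 ROR 27.01 (22.42-32.55) EBGM 10.46 (EB05 9.48) IC025 3.20
   decreased_appetite: a=164 ROR 4.64 (3.89-5.53) EBGM 3.71 (EB05 3.26) IC025 1.64
   palmar_plantar_erythrodysaesthesia: a=65 ROR 8.08 (6.01-10.88) EBGM 5.45 (EB05 4.43) IC025 2.06

prioritized 3 all-four-positive signals
  hepatic_failure: rate 11.4% (2) stability 3/3 (2) fatality 53.9% (2) DME/IME 2 -> total 8 [high]
  palmar_plantar_erythrodysaesthesia: rate 2.6% (1) stability 3/3 (2) fatality 13.8% (0) DME/IME 1 -> total 4 [moderate]
  decreased_appetite: rate 6.6% (1) stability 3/3 (2) fatality 10.4% (0) DME/IME 0 -> total 3 [moderate]
```

The three events flagged by all four algorithms are exactly the planted
ones: the lethal hepatic DME driven by the demographic logit model (it
scores the rubric's maximum of 8 and ranks high priority) and the two
planted relative risks of 10 and 5; the RR 2.5 plant is picked up by the
inclusive any-algorithm screen but not by all four. `05_time_to_onset.py`
recovers the planted Weibull onset law (shape 0.70, CI 0.67–0.74, early
failure, against a generator truth of 0.67) and `06_risk_model.py`
recovers the planted demographic odds ratios.

The same pipeline runs on real quarterly-dialect files or a flat CSV via
the `pvsignal` command line (`pvsignal ingest`, `screen`, `prioritize`,
`tto`, `riskmodel`, or `all`).

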