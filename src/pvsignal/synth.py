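"""Synthetic spontaneous-report generator with planted ground truth.

Emulates the structure of a public adverse-event reporting database at
desk scale: each report carries one primary-suspect drug, one or more
reaction PTs, demographics with realistic missingness, outcome codes, and
therapy-start / event-onset dates whose difference follows a configured
Weibull law.  Ground truth — planted drug-event relative risks, the
Weibull onset parameters, and the logit coefficients of a designated
target event — is returned alongside the store so every downstream stage
can be validated against known values.

Default conditions mirror the regorafenib cohort this package was built
around: the focal drug holds roughly the share of reports that cohort had
against its database background, demographic mixes and missingness rates
follow the published baseline table (54.7% male, 80.9% missing weight,
21.8% missing age, ~ one third of reports with computable onset times),
onset times default to Weibull(shape 0.67, scale 37.6) days, and the
designated target event ("hepatic_failure", a DME with high fatality)
follows the published demographic logit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .faers_io import write_faers_dialect  # noqa: F401  (module surface)
from .records import ReportStore, Vocabulary

NAMED_EVENTS = {
    # event name -> (baseline probability per report, death-outcome probability)
    "drug_ineffective": (0.08, 0.01),  # nonspecific filler term, never planted
    "hepatic_failure": (0.004, 0.55),
    "fulminant_hepatitis": (0.0015, 0.60),
    "palmar_plantar_erythrodysaesthesia": (0.003, 0.01),
    "diarrhoea": (0.020, 0.03),
    "fatigue": (0.025, 0.03),
    "decreased_appetite": (0.012, 0.05),
}

DME_TERMS = ("hepatic_failure", "fulminant_hepatitis")
IME_TERMS = DME_TERMS + ("palmar_plantar_erythrodysaesthesia",)

SOCS = [
    "hepatobiliary", "skin", "gastrointestinal", "general", "metabolism",
    "nervous_system", "investigations", "respiratory", "vascular", "cardiac",
]
EVENT_SOC_OVERRIDES = {
    "hepatic_failure": "hepatobiliary",
    "fulminant_hepatitis": "hepatobiliary",
    "palmar_plantar_erythrodysaesthesia": "skin",
    "diarrhoea": "gastrointestinal",
    "fatigue": "general",
    "decreased_appetite": "metabolism",
}

STUDY_START = np.datetime64("2012-07-01")
STUDY_END = np.datetime64("2025-03-31")

#: fixed stream for *condition* quantities (baseline rates, market shares)
#: so that different sampling seeds share one synthetic universe
_CONDITION_SEED = 20120701


@dataclass
class SyntheticConfig:
    """Conditions of the synthetic universe.  All rates are per report."""

    n_reports: int = 50_000
    n_drugs: int = 20
    n_events: int = 200
    target_drug: str = "regorafenib"
    #: share of reports carrying the focal drug as primary suspect
    target_drug_share: float = 0.05
    #: (drug, event, relative risk) triples multiplying the baseline rate
    planted_signals: List[Tuple[str, str, float]] = field(default_factory=lambda: [
        ("regorafenib", "palmar_plantar_erythrodysaesthesia", 10.0),
        ("regorafenib", "decreased_appetite", 5.0),
        ("regorafenib", "diarrhoea", 2.5),
    ])
    baseline_event_probs: Optional[Dict[str, float]] = None  # None: generated
    #: sex mix (female, male, missing)
    sex_probs: Tuple[float, float, float] = (0.3802, 0.5467, 0.0731)
    age_mean: float = 60.0
    age_sd: float = 18.0
    age_missing: float = 0.218
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    weight_missing: float = 0.8095
    reporter_probs: Dict[str, float] = field(default_factory=lambda: {
        "physician": 0.322, "consumer": 0.2846, "pharmacist": 0.1187, "other_hp": 0.2747})
    country_probs: Dict[str, float] = field(default_factory=lambda: {
        "US": 0.4959, "JP": 0.15, "CN": 0.0617, "FR": 0.0522, "CA": 0.0288, "other": 0.2114})
    indication_probs: Dict[str, float] = field(default_factory=lambda: {
        "colorectal_cancer": 0.6227, "hepatic_cancer": 0.1014,
        "gastrointestinal_stromal_tumor": 0.0612, "other_indication": 0.2147})
    #: global onset-time law (shape beta, scale alpha in days)
    tto_shape: float = 0.67
    tto_scale: float = 37.64
    #: optional per-(drug, event) Weibull overrides
    tto_models: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    therapy_start_missing: float = 0.30
    event_onset_missing: float = 0.52
    #: death probability for events without a named fatality rate
    default_fatality: float = 0.04
    other_outcome_probs: Dict[str, float] = field(default_factory=lambda: {
        "HO": 0.29, "LT": 0.022, "DS": 0.006, "OT": 0.50})
    #: designated target event driven by the demographic logit model
    target_event: str = "hepatic_failure"
    covariate_effects: Dict[str, float] = field(default_factory=lambda: {
        "(Intercept)": -2.80, "age[18-65]": -0.02, "age[>=65]": 1.16,
        "weight[80-100]": -1.55, "weight[>100]": -1.56, "male": 0.61})
    duplicate_rate: float = 0.02
    case_id_missing: float = 0.05
    seed: int = 0

    def __post_init__(self):
        probs = [self.age_missing, self.weight_missing, self.therapy_start_missing,
                 self.event_onset_missing, self.duplicate_rate, self.case_id_missing,
                 self.default_fatality, *self.sex_probs,
                 *self.reporter_probs.values(), *self.country_probs.values(),
                 *self.other_outcome_probs.values()]
        if self.baseline_event_probs:
            probs += list(self.baseline_event_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for _, _, rr in self.planted_signals:
            if rr <= 0:
                raise ValueError("planted relative risks must be positive")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if not 0.0 < self.target_drug_share < 1.0:
            raise ValueError("target_drug_share must lie strictly between 0 and 1")

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "planted_signals" in data:
            data["planted_signals"] = [tuple(t) for t in data["planted_signals"]]
        if "tto_models" in data:  # keys written as "drug|event"
            data["tto_models"] = {tuple(k.split("|", 1)): tuple(v)
                                  for k, v in data["tto_models"].items()}
        return SyntheticConfig(**data)


@dataclass
class GroundTruth:
    """Everything planted: lets tests score recovery quantitatively."""

    planted_rr: Dict[Tuple[str, str], float]
    baseline_event_probs: Dict[str, float]
    covariate_effects: Dict[str, float]
    target_event: str
    tto_shape: float
    tto_scale: float
    tto_models: Dict[Tuple[str, str], Tuple[float, float]]
    fatality_probs: Dict[str, float]
    seed: int


def _event_vocabulary(config: SyntheticConfig) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Event names, baseline probabilities and fatality probabilities.

    Baselines for unnamed events are drawn log-uniformly in [1e-3, 1.5e-2]
    from a fixed condition stream, so they define the universe rather than
    vary with the sampling seed.
    """
    if config.n_events < len(NAMED_EVENTS):
        raise ValueError(f"n_events must be at least {len(NAMED_EVENTS)} "
                         "(the named clinical terms)")
    names = list(NAMED_EVENTS)[: config.n_events]
    n_extra = config.n_events - len(names)
    names += [f"pt_{i:03d}" for i in range(n_extra)]
    crng = np.random.default_rng(_CONDITION_SEED)
    extra_probs = np.exp(crng.uniform(np.log(1e-3), np.log(1.5e-2), size=n_extra))
    probs = np.array([NAMED_EVENTS[n][0] for n in names[:len(names) - n_extra]]
                     + list(extra_probs))
    fatal = np.array([NAMED_EVENTS[n][1] for n in names[:len(names) - n_extra]]
                     + [config.default_fatality] * n_extra)
    if config.baseline_event_probs:
        for i, n in enumerate(names):
            if n in config.baseline_event_probs:
                probs[i] = config.baseline_event_probs[n]
    return names, probs, fatal


def _drug_universe(config: SyntheticConfig) -> Tuple[List[str], np.ndarray]:
    names = [config.target_drug] + [f"drug_{i:02d}" for i in range(1, config.n_drugs)]
    rest = 1.0 / np.arange(2, config.n_drugs + 1)  # gently skewed comparator shares
    rest = rest / rest.sum() * (1.0 - config.target_drug_share)
    return names, np.concatenate([[config.target_drug_share], rest])


def _vocabulary(event_names: List[str]) -> Vocabulary:
    crng = np.random.default_rng(_CONDITION_SEED + 1)
    mapping = {}
    for name in event_names:
        mapping[name] = EVENT_SOC_OVERRIDES.get(name, SOCS[int(crng.integers(len(SOCS)))])
    return Vocabulary(mapping, frozenset(DME_TERMS), frozenset(IME_TERMS))


def _categorical(rng, n, labels, probs):
    p = np.asarray(probs, dtype=float)
    return np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n, p=p / p.sum())]


def generate(config: SyntheticConfig) -> Tuple[ReportStore, GroundTruth]:
    """Draw a report store from the configured universe.

    Reproducible: the same config (including seed) yields an identical
    store.  Events are independent Bernoulli draws per report at rate
    baseline x RR (capped at 0.95), with at least one event forced per
    report; the designated target event instead follows the demographic
    logit model for reports of the target drug.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    event_names, base_p, fatal_p = _event_vocabulary(config)
    drug_names, shares = _drug_universe(config)
    vocab = _vocabulary(event_names)
    ev_index = {e: i for i, e in enumerate(event_names)}
    drug_index = {d: i for i, d in enumerate(drug_names)}

    drug_of = rng.choice(len(drug_names), size=n, p=shares)

    # per-drug event probability vectors (baseline x planted RR, capped)
    prob_by_drug = np.tile(base_p, (len(drug_names), 1))
    planted = {}
    for d, e, rr in config.planted_signals:
        if d not in drug_index or e not in ev_index:
            raise ValueError(f"planted signal ({d}, {e}) outside the universe")
        prob_by_drug[drug_index[d], ev_index[e]] *= rr
        planted[(d, e)] = rr
    prob_by_drug = np.clip(prob_by_drug, 0.0, 0.95)

    # demographics
    sex = _categorical(rng, n, ["female", "male", None], config.sex_probs)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.5, 100.0)
    age[rng.random(n) < config.age_missing] = np.nan
    weight = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 30.0, 180.0)
    weight[rng.random(n) < config.weight_missing] = np.nan
    reporter = _categorical(rng, n, list(config.reporter_probs), list(config.reporter_probs.values()))
    country = _categorical(rng, n, list(config.country_probs), list(config.country_probs.values()))
    indication = _categorical(rng, n, list(config.indication_probs),
                              list(config.indication_probs.values()))

    # reaction matrix
    events = rng.random((n, len(event_names))) < prob_by_drug[drug_of]

    # designated target event follows the logit model on the focal drug;
    # an empty coefficient dict disables the override (pure-null universe)
    ce = config.covariate_effects
    if ce:
        t_idx = ev_index[config.target_event]
        is_target_drug = drug_of == drug_index[config.target_drug]
        lp = np.full(n, ce.get("(Intercept)", -3.0))
        age_mid = ~np.isnan(age) & (age >= 18) & (age < 65)
        age_hi = ~np.isnan(age) & (age >= 65)
        w_mid = ~np.isnan(weight) & (weight >= 80) & (weight < 100)
        w_hi = ~np.isnan(weight) & (weight >= 100)
        lp += ce.get("age[18-65]", 0.0) * age_mid + ce.get("age[>=65]", 0.0) * age_hi
        lp += ce.get("weight[80-100]", 0.0) * w_mid + ce.get("weight[>100]", 0.0) * w_hi
        lp += ce.get("male", 0.0) * (sex == "male")
        p_target = 1.0 / (1.0 + np.exp(-lp))
        draw = rng.random(n)
        events[:, t_idx] = np.where(is_target_drug, draw < p_target,
                                    events[:, t_idx])

    # every report must describe at least one event; empties collapse onto
    # the nonspecific filler term so the planted laws of every studied
    # event stay exact
    empty = ~events.any(axis=1)
    events[empty, ev_index["drug_ineffective"]] = True

    # outcomes: death driven by the most lethal event present
    death_p = np.where(events.any(axis=1), (events * fatal_p).max(axis=1), 0.0)
    de = rng.random(n) < death_p
    oo = config.other_outcome_probs
    ho = rng.random(n) < oo.get("HO", 0.0)
    lt = rng.random(n) < oo.get("LT", 0.0)
    ds = rng.random(n) < oo.get("DS", 0.0)
    ot = rng.random(n) < oo.get("OT", 0.0)

    # onset-time law per report
    shape = np.full(n, config.tto_shape)
    scale = np.full(n, config.tto_scale)
    for (d, e), (b, a) in config.tto_models.items():
        mask = (drug_of == drug_index[d]) & events[:, ev_index[e]]
        shape[mask], scale[mask] = b, a
    tto = np.ceil(scale * rng.weibull(shape, n)).astype(int)
    tto = np.maximum(tto, 1)

    span_days = int((STUDY_END - STUDY_START) / np.timedelta64(1, "D"))
    start_offset = rng.integers(0, span_days - 400, n)
    therapy_start = STUDY_START + start_offset.astype("timedelta64[D]")
    event_onset = therapy_start + tto.astype("timedelta64[D]")
    receipt = event_onset + rng.integers(1, 60, n).astype("timedelta64[D]")

    start_missing = rng.random(n) < config.therapy_start_missing
    onset_missing = rng.random(n) < config.event_onset_missing
    therapy_start = pd.Series(therapy_start).mask(start_missing)
    event_onset_s = pd.Series(event_onset).mask(onset_missing)

    report_id = np.array([f"R{i:07d}" for i in range(n)], dtype=object)
    case_id = np.array([f"C{i:07d}" for i in range(n)], dtype=object)
    case_id[rng.random(n) < config.case_id_missing] = None

    reports = pd.DataFrame({
        "report_id": report_id,
        "case_id": case_id,
        "receipt_date": pd.to_datetime(receipt),
        "sex": sex,
        "age_years": age,
        "weight_kg": weight,
        "reporter": reporter,
        "country": country,
        "therapy_start": pd.to_datetime(therapy_start),
        "event_onset": pd.to_datetime(event_onset_s),
    })

    rep_idx, ev_idx = np.nonzero(events)
    reactions = pd.DataFrame({"report_id": report_id[rep_idx],
                              "pt": np.asarray(event_names, dtype=object)[ev_idx]})
    drugs = pd.DataFrame({"report_id": report_id,
                          "drug": np.asarray(drug_names, dtype=object)[drug_of],
                          "role": "PS"})
    out_rows = []
    for code, mask in (("DE", de), ("HO", ho), ("LT", lt), ("DS", ds), ("OT", ot)):
        out_rows.append(pd.DataFrame({"report_id": report_id[mask], "outcome": code}))
    outcomes = pd.concat(out_rows, ignore_index=True)
    indications = pd.DataFrame({"report_id": report_id, "pt": indication})

    # earlier versions of a fraction of cases, to exercise deduplication
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        dup_ids = np.array([f"R{i:07d}V0" for i in dup_idx], dtype=object)
        dup_reports = reports.iloc[dup_idx].copy()
        dup_reports["report_id"] = dup_ids
        dup_reports["receipt_date"] = dup_reports["receipt_date"] - pd.to_timedelta(
            rng.integers(30, 300, n_dup), unit="D")
        old_to_new = dict(zip(report_id[dup_idx], dup_ids))

        def _dup_child(table):
            sub = table[table["report_id"].isin(old_to_new)].copy()
            sub["report_id"] = sub["report_id"].map(old_to_new)
            return sub

        reports = pd.concat([reports, dup_reports], ignore_index=True)
        drugs = pd.concat([drugs, _dup_child(drugs)], ignore_index=True)
        reactions = pd.concat([reactions, _dup_child(reactions)], ignore_index=True)
        outcomes = pd.concat([outcomes, _dup_child(outcomes)], ignore_index=True)
        indications = pd.concat([indications, _dup_child(indications)], ignore_index=True)

    provenance = {"generator": "synthetic", "seed": config.seed,
                  "n_reports": int(len(reports)), "n_duplicates_injected": n_dup, "log": []}
    store = ReportStore(reports, drugs, reactions, outcomes, indications, vocab, provenance)
    truth = GroundTruth(
        planted_rr=planted,
        baseline_event_probs=dict(zip(event_names, base_p)),
        covariate_effects=dict(ce),
        target_event=config.target_event,
        tto_shape=config.tto_shape,
        tto_scale=config.tto_scale,
        tto_models=dict(config.tto_models),
        fatality_probs=dict(zip(event_names, fatal_p)),
        seed=config.seed,
    )
    return store, truth
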