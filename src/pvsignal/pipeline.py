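"""End-to-end orchestration: ingest -> deduplicate -> primary-suspect
filter -> descriptives -> four-algorithm screen -> prioritization ->
time-to-onset -> demographic risk model, with a reproducible report
bundle (CSV tables, JSON manifest, plain-text summary).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .cleaning import deduplicate, filter_primary_suspect
from .demographics import summarize_demographics
from .faers_io import read_faers_tables, read_flat_csv
from .logistic import build_design, fit_logistic_irls, or_table
from .priority import prioritize_signals
from .records import ReportStore
from .signals import Thresholds, evaluate_signals, forest_frame, subgroup_screen
from .synth import SyntheticConfig, generate
from .tto import extract_tto, stratified_weibull, tto_histogram

INPUT_MODES = ("faers_dialect", "flat_csv", "synthetic")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    input_mode: str = "synthetic"
    input_paths: Dict[str, str] = field(default_factory=dict)  # per-table or {"flat": path}
    drug: str = "regorafenib"
    drug_aliases: Dict[str, str] = field(default_factory=dict)
    levels: Tuple[str, ...] = ("PT", "SOC")
    thresholds: Thresholds = field(default_factory=Thresholds)
    screen_min_count: int = 1
    priority_criterion: str = "positive_all"
    target_pts: Tuple[str, ...] = ("hepatic_failure", "fulminant_hepatitis")
    subgroups: Tuple[str, ...] = ("sex", "age_bins")
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "pvsignal_run"

    def validate(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        for lv in self.levels:
            if lv not in ("PT", "SOC"):
                raise ValueError(f"unknown level {lv!r}")
        if self.input_mode == "faers_dialect":
            for key in ("demo", "drug", "reac"):
                if key not in self.input_paths:
                    raise ValueError(f"faers_dialect input needs path for {key!r}")
        if self.input_mode == "flat_csv" and "flat" not in self.input_paths:
            raise ValueError("flat_csv input needs input_paths['flat']")
        if self.priority_criterion not in ("positive_all", "positive_any"):
            raise ValueError("priority_criterion must be positive_all or positive_any")

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            data["synthetic"] = SyntheticConfig(**data["synthetic"])
        for key in ("levels", "target_pts", "subgroups"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = RunConfig(**data)
        cfg.validate()
        return cfg


def _load(config: RunConfig, vocabulary=None) -> ReportStore:
    if config.input_mode == "synthetic":
        synth_cfg = config.synthetic
        if synth_cfg.seed != config.seed:
            synth_cfg = SyntheticConfig(**{**asdict_shallow(synth_cfg), "seed": config.seed})
        store, _ = generate(synth_cfg)
        return store
    if config.input_mode == "faers_dialect":
        return read_faers_tables(config.input_paths, vocabulary)
    return read_flat_csv(config.input_paths["flat"], vocabulary)


def asdict_shallow(obj) -> dict:
    return {k: v for k, v in asdict(obj).items()}


def run_full_analysis(config: RunConfig, vocabulary=None) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``): versions,
    seed, stage counts, and the path of every table produced.  A stage
    failure raises after writing the manifest with the failure point
    recorded, so partial outputs remain inspectable.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    tm = cfg_dict.get("synthetic", {}).get("tto_models")
    if tm:  # tuple keys are not JSON keys
        cfg_dict["synthetic"]["tto_models"] = {"|".join(k): list(v) for k, v in tm.items()}
    manifest: dict = {
        "pvsignal_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(cfg_dict, default=str)),
        "counts": {},
        "outputs": {},
        "failed_stage": None,
    }
    summary: List[str] = []

    def _emit(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = str(path)

    stage = "ingest"
    try:
        store = _load(config, vocabulary)
        manifest["counts"]["ingested"] = store.n_reports
        summary.append(f"ingested reports: {store.n_reports}")

        stage = "deduplicate"
        store = deduplicate(store)
        manifest["counts"]["deduplicated"] = store.n_reports
        summary.append(f"after deduplication: {store.n_reports}")

        stage = "primary_suspect_filter"
        cohort = filter_primary_suspect(store, [config.drug], config.drug_aliases)
        manifest["counts"]["ps_cohort"] = cohort.n_reports
        summary.append(f"primary-suspect cohort ({config.drug}): {cohort.n_reports}")
        if cohort.n_reports == 0:
            manifest["counts"]["empty_cohort"] = True
            summary.append("empty cohort: nothing to analyse")
            _finish(out, manifest, summary)
            return manifest

        stage = "demographics"
        _emit("demographics", summarize_demographics(cohort))

        stage = "screen"
        signal_frames = {}
        for level in config.levels:
            frame = evaluate_signals(store, config.drug, level, config.thresholds,
                                     min_count=config.screen_min_count)
            signal_frames[level] = frame
            _emit(f"signals_{level.lower()}", frame)
            _emit(f"forest_{level.lower()}", forest_frame(frame))
            manifest["counts"][f"signals_{level.lower()}_positive_any"] = int(frame["positive_any"].sum())
            manifest["counts"][f"signals_{level.lower()}_positive_all"] = int(frame["positive_all"].sum())
            summary.append(f"{level} screen: {len(frame)} events, "
                           f"{int(frame['positive_any'].sum())} positive by >=1 algorithm, "
                           f"{int(frame['positive_all'].sum())} by all four")

        stage = "subgroups"
        for stratifier in config.subgroups:
            sg = subgroup_screen(store, stratifier, config.drug, config.thresholds,
                                 criterion="positive_any", min_count=config.screen_min_count)
            for name, frame in sg.per_stratum.items():
                _emit(f"subgroup_{stratifier}_{name.replace('<', 'lt').replace('>=', 'ge')}", frame)
            manifest["counts"][f"subgroup_{stratifier}_shared"] = len(sg.shared)

        stage = "prioritize"
        if "PT" in signal_frames:
            prio = prioritize_signals(signal_frames["PT"], store,
                                      criterion=config.priority_criterion)
            _emit("priority", prio)
            if len(prio):
                n_high = int((prio["priority_class"] == "high").sum())
                summary.append(f"prioritized {len(prio)} signals; {n_high} high priority; "
                               f"top: {prio.iloc[0]['event']} (total {prio.iloc[0]['total']})")

        stage = "time_to_onset"
        tto_frame, exclusions = extract_tto(cohort)
        manifest["counts"]["tto_eligible"] = int(len(tto_frame))
        manifest["counts"]["tto_exclusions"] = exclusions
        if len(tto_frame) >= 10:
            _emit("tto_weibull", stratified_weibull(tto_frame))
            _emit("tto_histogram", tto_histogram(tto_frame["tto_days"]))
            med = tto_frame["tto_days"].median()
            summary.append(f"time-to-onset: n={len(tto_frame)}, median {med:.0f} days")

        stage = "risk_model"
        try:
            X, y, dropped = build_design(cohort, list(config.target_pts))
            fit = fit_logistic_irls(X, y, n_dropped_missing=dropped)
            _emit("risk_model", or_table(fit))
            manifest["counts"]["risk_model_n"] = fit.n_used
            manifest["counts"]["risk_model_dropped_missing"] = dropped
            summary.append(f"risk model: n={fit.n_used} complete-covariate reports "
                           f"({dropped} dropped), converged={fit.converged}")
        except ValueError as exc:
            manifest["counts"]["risk_model_skipped"] = str(exc)
            summary.append(f"risk model skipped: {exc}")

    except Exception:
        manifest["failed_stage"] = stage
        _finish(out, manifest, summary)
        raise

    _finish(out, manifest, summary)
    return manifest


def _finish(out: Path, manifest: dict, summary: List[str]) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                  default=str))
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
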