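"""Reproducible simulate -> score -> evaluate -> derive pipeline.

Builds the report bundle a diagnostic-accuracy study prints: a per-feature
predictive-value table, per-score panels for the appendicitis and
perforation dichotomies, and a missed-perforation counterfactual ("if only
score-positive children had undergone appendectomy").  Every report cell is
recomputable from the emitted confusion matrices, which ship with the
bundle; row counts at each stage reconcile with the input and are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import metrics
from .records import PERFORATED, PatientRecord, read_cohort_csv
from .scoring import (
    DEFAULT_POLICY,
    FEATURES,
    ScoreDefinition,
    ThresholdPolicy,
    apply_scores,
    derive_features,
    get_definitions,
)
from .simulate import CohortParameters, generate_cohort

log = logging.getLogger("appendiscore")

PERCENT_FIELDS = ("sensitivity", "specificity", "ppv", "npv")
RATIO_FIELDS = ("lr_pos", "lr_neg", "auc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed is stamped on every output."""

    cohort_path: Optional[str] = None   # None -> simulate with defaults
    scores: Optional[Sequence[str]] = None  # None -> all six built-ins
    dichotomies: Sequence[str] = ("appendicitis", "perforation")
    ci: str = "wilson"
    seed: int = 0
    n: Optional[int] = None             # simulated cohort size override
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ReportBundle:
    """All tables of one run plus the confusion matrices behind them."""

    feature_report: pd.DataFrame
    appendicitis_panel: Optional[pd.DataFrame]
    perforation_panel: Optional[pd.DataFrame]
    missed_cases: Optional[pd.DataFrame]
    confusion_matrices: dict
    exclusion_log: list
    seed: int
    n_input: int
    n_evaluated: int
    score_frame: pd.DataFrame = field(repr=False, default=None)


def _panel_row(panel: metrics.DiagnosticPanel) -> dict:
    row: dict = {"n": panel.n_evaluated}
    for name in PERCENT_FIELDS + RATIO_FIELDS:
        est = getattr(panel, name)
        if est is None:
            row[name] = row[f"{name}_low"] = row[f"{name}_high"] = float("nan")
        else:
            row[name] = est.value
            row[f"{name}_low"] = est.ci_low
            row[f"{name}_high"] = est.ci_high
    return row


def feature_report(
    cohort: Sequence[PatientRecord],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Per-feature presence counts and predictive values for appendicitis.

    Each feature is assessed among the patients in whom it is derivable and
    whose outcome is known; PPV/NPV carry Wilson 95% CIs.
    """
    rows = []
    for name in FEATURES:
        present = absent = tp = tn = 0
        for patient in cohort:
            if patient.appendicitis is None:
                continue
            indicator = derive_features(patient, policy)[name]
            if indicator is None:
                continue
            if indicator:
                present += 1
                tp += int(patient.appendicitis)
            else:
                absent += 1
                tn += int(not patient.appendicitis)
        row = {"feature": name, "present": present, "n": present + absent}
        for label, count, nobs in (("ppv", tp, present), ("npv", tn, absent)):
            if nobs > 0:
                est = metrics.wilson_ci(count, nobs)
                row[label], row[f"{label}_low"], row[f"{label}_high"] = est
            else:
                row[label] = row[f"{label}_low"] = row[f"{label}_high"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def evaluate_scores(
    cohort: Sequence[PatientRecord],
    definitions: Sequence[ScoreDefinition],
    dichotomy: str = "appendicitis",
    ci: str = "wilson",
    seed: int = 0,
    score_frame: Optional[pd.DataFrame] = None,
    exclusion_log: Optional[list] = None,
) -> tuple[pd.DataFrame, dict]:
    """Diagnostic panels for several scores under one outcome dichotomy.

    ``appendicitis`` contrasts appendicitis vs none over the complete-case
    cohort; ``perforation`` contrasts perforated vs non-perforated WITHIN
    appendicitis cases (non-appendicitis patients are excluded from that
    dichotomy).  Returns (panel frame, confusion matrices keyed by score).
    """
    if dichotomy not in ("appendicitis", "perforation"):
        raise ValueError(f"unknown dichotomy {dichotomy!r}")
    if score_frame is None:
        score_frame, exclusion_log = apply_scores(cohort, definitions)
    by_id = {p.id: p for p in cohort}

    rows = []
    matrices: dict = {}
    for definition in definitions:
        ids, outcomes, predictions, totals = [], [], [], []
        for pid in score_frame.index:
            patient = by_id[pid]
            if patient.appendicitis is None:
                continue
            if dichotomy == "perforation" and not patient.appendicitis:
                continue
            truth = (patient.outcome == PERFORATED) if dichotomy == "perforation" \
                else patient.appendicitis
            ids.append(pid)
            outcomes.append(bool(truth))
            predictions.append(bool(score_frame.at[pid, f"{definition.name}_positive"]))
            totals.append(int(score_frame.at[pid, f"{definition.name}_total"]))
        matrix = metrics.confusion(predictions, outcomes, dichotomy=dichotomy)
        matrices[definition.name] = matrix
        panel = metrics.panel(matrix, score_totals=totals, outcomes=outcomes,
                              ci=ci, seed=seed)
        rows.append({"score": definition.name, **_panel_row(panel)})
        log.info("%s / %s: n=%d tp=%d fp=%d fn=%d tn=%d", definition.name,
                 dichotomy, matrix.n, matrix.tp, matrix.fp, matrix.fn, matrix.tn)
    return pd.DataFrame(rows).set_index("score"), matrices


def missed_perforation_table(perforation_matrices: dict) -> pd.DataFrame:
    """Counterfactual: perforations missed if only score-positive children
    had an appendectomy, from each score's perforation sensitivity."""
    rows = []
    for name, matrix in perforation_matrices.items():
        sens = matrix.tp / matrix.n_positive if matrix.n_positive else float("nan")
        missed, fraction = metrics.missed_cases(sens, matrix.n_positive)
        rows.append({
            "score": name,
            "perforation_sensitivity": sens,
            "n_perforated": matrix.n_positive,
            "missed": missed,
            "missed_fraction": fraction if fraction is not None else float("nan"),
        })
    return pd.DataFrame(rows).set_index("score")


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute score -> evaluate -> report on a cohort (loaded or simulated)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.cohort_path:
        cohort = read_cohort_csv(config.cohort_path)
        log.info("loaded %d patients from %s", len(cohort), config.cohort_path)
    else:
        params = CohortParameters(seed=config.seed)
        if config.n is not None:
            params.n_total = config.n
        cohort = generate_cohort(params)
        log.info("simulated %d patients (seed %d)", len(cohort), config.seed)

    definitions = get_definitions(config.scores)
    score_frame, exclusion_log = apply_scores(cohort, definitions)
    log.info("evaluated %d / excluded %d of %d patients",
             len(score_frame), len(exclusion_log), len(cohort))

    features = feature_report(cohort)
    matrices: dict = {}
    panels: dict = {}
    for dichotomy in config.dichotomies:
        frame, mats = evaluate_scores(
            cohort, definitions, dichotomy=dichotomy, ci=config.ci,
            seed=config.seed, score_frame=score_frame, exclusion_log=exclusion_log,
        )
        panels[dichotomy] = frame
        matrices[dichotomy] = mats

    missed = (missed_perforation_table(matrices["perforation"])
              if "perforation" in matrices else None)

    bundle = ReportBundle(
        feature_report=features,
        appendicitis_panel=panels.get("appendicitis"),
        perforation_panel=panels.get("perforation"),
        missed_cases=missed,
        confusion_matrices=matrices,
        exclusion_log=exclusion_log,
        seed=config.seed,
        n_input=len(cohort),
        n_evaluated=len(score_frame),
        score_frame=score_frame,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _format_panel(frame: pd.DataFrame) -> pd.DataFrame:
    """Percentages to 1 decimal, ratios/AUC to 2 decimals (report precision)."""
    out = frame.copy()
    for col in out.columns:
        base = col.replace("_low", "").replace("_high", "")
        if base in PERCENT_FIELDS:
            out[col] = (out[col] * 100).round(1)
        elif base in RATIO_FIELDS:
            out[col] = out[col].round(2)
    return out


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Emit the bundle as CSV + JSON; deterministic for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features = bundle.feature_report.copy()
    for col in ("ppv", "ppv_low", "ppv_high", "npv", "npv_low", "npv_high"):
        features[col] = (features[col] * 100).round(1)
    features.to_csv(out / "feature_report.csv")

    for name, frame in (("appendicitis_panel", bundle.appendicitis_panel),
                        ("perforation_panel", bundle.perforation_panel)):
        if frame is not None:
            _format_panel(frame).to_csv(out / f"{name}.csv")
            frame.to_json(out / f"{name}.json", orient="index", indent=2)

    if bundle.missed_cases is not None:
        formatted = bundle.missed_cases.copy()
        formatted["perforation_sensitivity"] = (formatted["perforation_sensitivity"] * 100).round(1)
        formatted["missed_fraction"] = (formatted["missed_fraction"] * 100).round(1)
        formatted.to_csv(out / "missed_cases.csv")

    matrices = {
        dichotomy: {
            score: {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn}
            for score, m in mats.items()
        }
        for dichotomy, mats in bundle.confusion_matrices.items()
    }
    meta = {
        "seed": bundle.seed,
        "n_input": bundle.n_input,
        "n_evaluated": bundle.n_evaluated,
        "n_excluded": len(bundle.exclusion_log),
    }
    with open(out / "confusion_matrices.json", "w") as fh:
        json.dump({"meta": meta, "matrices": matrices}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "exclusion_log.json", "w") as fh:
        json.dump({"meta": meta, "excluded": bundle.exclusion_log}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
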