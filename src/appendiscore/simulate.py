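"""Seeded synthetic cohorts of children hospitalized for suspected appendicitis.

The generator emulates the structure of a two-center pediatric
abdominal-pain cohort of 463 children (336 histologically confirmed
appendicitis cases, of which 234 simple and 102 perforated, and 127 without
appendicitis): class mix, per-class age / sex / symptom-duration
distributions, per-class frequencies of the binary score items, and joint
missingness of the laboratory + ultrasound block (7/463).

Feature probabilities default to values calibrated from the reference
cohort's published predictive-value rows (present count, PPV, NPV per item),
inverted back into 2x2 tables.  Several published rows are internally
inconsistent with the stated case count; the calibration flags these and
renormalizes them to the implied margins rather than silently correcting
the publication.

The central simplification: binary features are conditionally independent
given the outcome class, and simple and perforated appendicitis share one
set of feature probabilities (the source only dichotomizes appendicitis vs
none).  Continuous laboratory magnitudes are synthetic conveniences — only
their thresholded indicators are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .metrics import invert_feature_row
from .records import NO_APPENDICITIS, PERFORATED, SIMPLE, PatientRecord
from .scoring import DEFAULT_POLICY, FEATURES, ThresholdPolicy, derive_features

CLASSES = (NO_APPENDICITIS, SIMPLE, PERFORATED)


class PredictiveValueRow(NamedTuple):
    """Published per-feature row: presence count, PPV and NPV for appendicitis."""

    name: str
    present: int
    total: int
    ppv: Optional[float]
    npv: Optional[float]


#: reference-cohort predictive-value rows used to calibrate the default
#: feature probabilities (463 children, 336 appendicitis; lab/US rows cover
#: the 456 children with a complete work-up)
REFERENCE_FEATURE_ROWS: tuple[PredictiveValueRow, ...] = (
    PredictiveValueRow("continuous_pain", 7, 463, 0.400, 0.500),
    PredictiveValueRow("nausea_vomiting", 319, 463, 0.815, 0.453),
    PredictiveValueRow("anorexia", 176, 463, 0.821, 0.380),
    PredictiveValueRow("migration_of_pain", 0, 463, None, None),
    PredictiveValueRow("fever", 312, 463, 0.974, 0.300),
    PredictiveValueRow("tenderness_rlq", 334, 463, 0.733, 0.583),
    PredictiveValueRow("rebound_tenderness", 293, 463, 0.897, 0.365),
    PredictiveValueRow("cough_hop_tenderness", 205, 463, 0.897, 0.372),
    PredictiveValueRow("wbc_elevated", 333, 463, 0.857, 0.488),
    PredictiveValueRow("neutrophilia", 72, 463, 0.964, 0.136),
    PredictiveValueRow("crp_elevated", 332, 456, 0.946, 0.477),
    PredictiveValueRow("us_appendicitis", 287, 456, 0.959, 0.681),
)

REFERENCE_CASE_TOTAL = 336
REFERENCE_NONCASE_TOTAL = 127


def calibrate_feature_probs(
    rows: Sequence[PredictiveValueRow],
    case_total: int,
    noncase_total: int,
    tolerance: int = 5,
) -> tuple[dict, list[dict]]:
    """Per-class feature probabilities from published predictive-value rows.

    For each row the implied 2x2 gives ``P(feature | case) = tp / case_total``
    and ``P(feature | non-case) = fp / noncase_total``.  Rows whose implied
    case margin (tp + fn) misses ``case_total`` by more than ``tolerance``
    are flagged and renormalized to their own margins (tp/(tp+fn) and
    fp/(fp+tn)), distributing the gap proportionally; every adjustment is
    listed in the returned report.

    A row with zero presences (or no predictive values) yields probability 0
    in both classes.
    """
    if len(rows) == 0:
        raise ValueError("no rows to calibrate")
    probs: dict[str, dict[str, float]] = {}
    report: list[dict] = []
    for row in rows:
        if row.present == 0 or row.ppv is None or row.npv is None:
            probs[row.name] = {"case": 0.0, "noncase": 0.0}
            report.append({"feature": row.name, "flagged": False, "gap": 0,
                           "note": "absent feature; probability 0 in both classes"})
            continue
        inverted = invert_feature_row(row.present, row.total, row.ppv, row.npv, case_total)
        flagged = inverted.consistency_gap > tolerance
        if flagged:
            p_case = inverted.tp / (inverted.tp + inverted.fn)
            p_noncase = inverted.fp / (inverted.fp + inverted.tn)
            note = (
                f"implied case margin {inverted.implied_cases} vs reported "
                f"{case_total}; renormalized to implied margins"
            )
        else:
            p_case = inverted.tp / case_total
            p_noncase = inverted.fp / noncase_total
            note = ""
        probs[row.name] = {"case": min(p_case, 1.0), "noncase": min(p_noncase, 1.0)}
        report.append({
            "feature": row.name,
            "flagged": flagged,
            "gap": inverted.consistency_gap,
            "p_case": probs[row.name]["case"],
            "p_noncase": probs[row.name]["noncase"],
            "note": note,
        })
    return probs, report


def _default_feature_probs() -> dict:
    calibrated, _ = calibrate_feature_probs(
        REFERENCE_FEATURE_ROWS, REFERENCE_CASE_TOTAL, REFERENCE_NONCASE_TOTAL
    )
    out = {}
    for name in FEATURES:
        p = calibrated[name]
        out[name] = {
            NO_APPENDICITIS: p["noncase"],
            SIMPLE: p["case"],
            PERFORATED: p["case"],
        }
    return out


@dataclass
class CohortParameters:
    """Generative parameters of a synthetic abdominal-pain cohort.

    Defaults encode the reference cohort: n=463 with class mix
    (127 none, 234 simple, 102 perforated)/463; ages (years, truncated to
    the 1-17 inclusion range) none 11.6 (3.7), simple 10.9 (3.3), perforated
    10.0 (4.2); female fractions 53/127, 143/234, 70/102; symptom durations
    (hours, lognormal moment-matched) none 57.8 (73.4), simple 34.3 (39.7),
    perforated 52.1 (48.7); lab/US block jointly missing with probability
    7/463.
    """

    n_total: int = 463
    class_probs: dict = field(default_factory=lambda: {
        NO_APPENDICITIS: 127 / 463,
        SIMPLE: 234 / 463,
        PERFORATED: 102 / 463,
    })
    feature_probs: dict = field(default_factory=_default_feature_probs)
    age_mean_sd: dict = field(default_factory=lambda: {
        NO_APPENDICITIS: (11.6, 3.7),
        SIMPLE: (10.9, 3.3),
        PERFORATED: (10.0, 4.2),
    })
    female_frac: dict = field(default_factory=lambda: {
        NO_APPENDICITIS: 53 / 127,
        SIMPLE: 143 / 234,
        PERFORATED: 70 / 102,
    })
    duration_mean_sd: dict = field(default_factory=lambda: {
        NO_APPENDICITIS: (57.8, 73.4),
        SIMPLE: (34.3, 39.7),
        PERFORATED: (52.1, 48.7),
    })
    missing_prob: float = 7 / 463
    age_bounds: tuple = (1.0, 17.0)
    threshold_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        total = sum(self.class_probs[c] for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        for name, per_class in self.feature_probs.items():
            for c in CLASSES:
                if not (0 <= per_class[c] <= 1):
                    raise ValueError(f"feature probability out of [0,1]: {name}/{c}")
        for c in CLASSES:
            if self.age_mean_sd[c][1] <= 0 or self.duration_mean_sd[c][1] <= 0:
                raise ValueError("standard deviations must be positive")
            if not (0 <= self.female_frac[c] <= 1):
                raise ValueError("female fractions must lie in [0,1]")
        if not (0 <= self.missing_prob <= 1):
            raise ValueError("missing_prob must lie in [0,1]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal: returns (mu, sigma) of the underlying normal."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _magnitude(rng, indicator, cutoff, loc, scale, floor=0.01, mode="mult",
               low=None, high=None):
    """Continuous value strictly above/below a cutoff given its indicator.

    ``mult`` draws value = cutoff * exp(+/- d); ``add`` draws cutoff +/- d,
    with d = floor + |Normal(loc, scale)| so the cutoff is never hit exactly.
    """
    n = indicator.shape[0]
    d = floor + np.abs(rng.normal(loc, scale, size=n))
    sign = np.where(indicator, 1.0, -1.0)
    if mode == "mult":
        value = cutoff * np.exp(sign * d)
    else:
        value = cutoff + sign * d
    if low is not None:
        value = np.maximum(value, np.where(indicator, cutoff + floor, low))
    if high is not None:
        value = np.minimum(value, np.where(indicator, high, cutoff - floor))
    return value


def generate_cohort(params: CohortParameters, seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; a fixed seed yields bit-identical output.

    Outcome class is multinomial; binary features are independent Bernoulli
    given class; continuous labs are two-component draws whose thresholded
    indicator matches the Bernoulli draw exactly; the lab/US block is jointly
    missing with the configured probability, clinical findings never are.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_total
    policy = params.threshold_policy

    class_p = np.array([params.class_probs[c] for c in CLASSES])
    class_idx = rng.choice(len(CLASSES), size=n, p=class_p)

    indicators = {}
    for name in FEATURES:
        p = np.array([params.feature_probs[name][c] for c in CLASSES])[class_idx]
        indicators[name] = rng.random(n) < p

    lo, hi = params.age_bounds
    ages = np.empty(n)
    females = np.empty(n, dtype=bool)
    durations = np.empty(n)
    for k, c in enumerate(CLASSES):
        mask = class_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        mean, sd = params.age_mean_sd[c]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ages[mask] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=m, random_state=rng)
        females[mask] = rng.random(m) < params.female_frac[c]
        mu, sigma = _lognormal_params(*params.duration_mean_sd[c])
        durations[mask] = rng.lognormal(mu, sigma, size=m)

    wbc = _magnitude(rng, indicators["wbc_elevated"], policy.wbc_cutoff, 0.30, 0.20)
    crp = _magnitude(rng, indicators["crp_elevated"], policy.crp_cutoff, 0.60, 0.40)
    neut_abs = _magnitude(rng, indicators["neutrophilia"], policy.neutrophilia_abs_cutoff, 0.25, 0.15)
    neut_pct = _magnitude(
        rng, indicators["neutrophilia"], policy.neutrophilia_pct_cutoff,
        8.0, 5.0, floor=0.1, mode="add", low=5.0, high=99.0,
    )
    temperature = _magnitude(
        rng, indicators["fever"], policy.temp_cutoff,
        0.6, 0.4, floor=0.05, mode="add", low=36.0, high=41.5,
    )

    lab_missing = rng.random(n) < params.missing_prob

    def tri(name: str, i: int) -> bool:
        return bool(indicators[name][i])

    cohort = []
    for i in range(n):
        missing = bool(lab_missing[i])
        cohort.append(PatientRecord(
            id=f"P{i:05d}",
            age=float(ages[i]),
            sex="female" if females[i] else "male",
            duration_h=float(durations[i]),
            continuous_pain=tri("continuous_pain", i),
            nausea_vomiting=tri("nausea_vomiting", i),
            anorexia=tri("anorexia", i),
            migration_of_pain=tri("migration_of_pain", i),
            tenderness_rlq=tri("tenderness_rlq", i),
            rebound_tenderness=tri("rebound_tenderness", i),
            cough_hop_tenderness=tri("cough_hop_tenderness", i),
            temperature_c=float(temperature[i]),
            wbc=None if missing else float(wbc[i]),
            neutrophils_abs=None if missing else float(neut_abs[i]),
            neutrophils_pct=None if missing else float(neut_pct[i]),
            crp=None if missing else float(crp[i]),
            us_appendicitis=None if missing else tri("us_appendicitis", i),
            outcome=CLASSES[class_idx[i]],
        ))
    return cohort


def summarize_cohort(cohort: Sequence[PatientRecord], policy: ThresholdPolicy = DEFAULT_POLICY) -> dict:
    """Empirical summary of a cohort, mirroring the reference-study layout.

    Returns class counts, per-class age/sex/duration moments, per-class
    feature frequencies (among patients where the feature is derivable) and
    the complete-case count for the lab/US block.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    out: dict = {"n": len(cohort), "class_counts": {c: 0 for c in CLASSES}}
    by_class: dict[str, list] = {c: [] for c in CLASSES}
    for p in cohort:
        if p.outcome is not None:
            out["class_counts"][p.outcome] += 1
            by_class[p.outcome].append(p)

    out["age"] = {}
    out["female_frac"] = {}
    out["duration_h"] = {}
    out["feature_freq"] = {}
    for c in CLASSES:
        members = by_class[c]
        if not members:
            out["age"][c] = out["duration_h"][c] = (float("nan"), float("nan"))
            out["female_frac"][c] = float("nan")
            out["feature_freq"][c] = {name: float("nan") for name in FEATURES}
            continue
        ages = np.array([p.age for p in members])
        durs = np.array([p.duration_h for p in members])
        out["age"][c] = (float(ages.mean()), float(ages.std(ddof=1)) if len(members) > 1 else 0.0)
        out["duration_h"][c] = (float(durs.mean()), float(durs.std(ddof=1)) if len(members) > 1 else 0.0)
        out["female_frac"][c] = sum(p.sex == "female" for p in members) / len(members)
        vectors = [derive_features(p, policy) for p in members]
        freq = {}
        for name in FEATURES:
            values = [v[name] for v in vectors if v[name] is not None]
            freq[name] = (sum(values) / len(values)) if values else float("nan")
        out["feature_freq"][c] = freq

    complete = sum(
        1 for p in cohort
        if p.wbc is not None and p.crp is not None and p.us_appendicitis is not None
        and (p.neutrophils_abs is not None or p.neutrophils_pct is not None)
    )
    out["n_complete_lab_us"] = complete
    return out
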