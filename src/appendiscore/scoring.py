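"""Additive clinical appendicitis scores and their evaluation.

Implements the six scores routinely compared in pediatric appendicitis
work-ups — Alvarado, Pediatric Appendicitis Score (PAS), Tzanakis,
Heidelberg Appendicitis Score (HAS), modified HAS, and the four-item
"AI score" derived by random-forest analysis.  Each score is a weighted sum
of binary items with an inclusive positivity cutoff (total >= cutoff counts
as positive).

Raw values are binarized through a :class:`ThresholdPolicy` with strict
``>`` comparisons (e.g. WBC counted elevated iff wbc > 11 x 10^9/L).
Neutrophilia is positive if EITHER the absolute (>7.9 x 10^9/L) OR the
percentage (>75%) criterion holds.  The WBC cutoff has a published
alternative of 12 x 10^9/L; 11 is the default, the alternative is a policy
override.

Missing raw values propagate as incomplete feature indicators — a missing
item is never silently scored 0.  Cohort-level evaluation supports the
complete-case exclusion policy used in diagnostic-accuracy studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .records import PatientRecord

#: canonical binary feature names, in fixed declaration order
FEATURES = (
    "tenderness_rlq",
    "rebound_tenderness",
    "cough_hop_tenderness",
    "continuous_pain",
    "nausea_vomiting",
    "anorexia",
    "migration_of_pain",
    "fever",
    "wbc_elevated",
    "neutrophilia",
    "crp_elevated",
    "us_appendicitis",
)

BUILTIN_SCORE_NAMES = ("alvarado", "pas", "tzanakis", "has", "modified_has", "ai_score")


class ConfigurationError(ValueError):
    """A score definition references an unknown feature or violates invariants."""


@dataclass(frozen=True)
class ThresholdPolicy:
    """Cutoffs used to binarize continuous values (all comparisons strict >)."""

    wbc_cutoff: float = 11.0          # 10^9/L; published alternative: 12.0
    neutrophilia_abs_cutoff: float = 7.9   # 10^9/L
    neutrophilia_pct_cutoff: float = 75.0  # %
    crp_cutoff: float = 20.0          # mg/L
    temp_cutoff: float = 38.5         # degrees C

    def __post_init__(self) -> None:
        for name in (
            "wbc_cutoff",
            "neutrophilia_abs_cutoff",
            "neutrophilia_pct_cutoff",
            "crp_cutoff",
            "temp_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "wbc_cutoff": self.wbc_cutoff,
            "neutrophilia_abs_cutoff": self.neutrophilia_abs_cutoff,
            "neutrophilia_pct_cutoff": self.neutrophilia_pct_cutoff,
            "crp_cutoff": self.crp_cutoff,
            "temp_cutoff": self.temp_cutoff,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ThresholdPolicy":
        return cls(**data)


DEFAULT_POLICY = ThresholdPolicy()


@dataclass(frozen=True)
class FeatureVector:
    """Binary indicators derived from one patient; missing values stay None."""

    values: dict  # feature name -> 0 | 1 | None

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values.values())

    def missing_features(self) -> tuple:
        return tuple(name for name, v in self.values.items() if v is None)

    def __getitem__(self, name: str):
        return self.values[name]


def derive_features(patient: PatientRecord, policy: ThresholdPolicy = DEFAULT_POLICY) -> FeatureVector:
    """Binarize a patient's raw values into the canonical feature indicators.

    Tri-state clinical findings map yes->1, no->0, not recorded->None.
    Laboratory indicators are strict-threshold comparisons; neutrophilia is
    the OR of the absolute and percentage criteria over whichever of the two
    measurements were recorded (None only if neither was).
    """

    def tri(value: Optional[bool]):
        return None if value is None else int(value)

    def above(value: Optional[float], cutoff: float):
        return None if value is None else int(value > cutoff)

    neut_criteria = [
        above(patient.neutrophils_abs, policy.neutrophilia_abs_cutoff),
        above(patient.neutrophils_pct, policy.neutrophilia_pct_cutoff),
    ]
    recorded = [c for c in neut_criteria if c is not None]
    neutrophilia = max(recorded) if recorded else None

    values = {
        "tenderness_rlq": tri(patient.tenderness_rlq),
        "rebound_tenderness": tri(patient.rebound_tenderness),
        "cough_hop_tenderness": tri(patient.cough_hop_tenderness),
        "continuous_pain": tri(patient.continuous_pain),
        "nausea_vomiting": tri(patient.nausea_vomiting),
        "anorexia": tri(patient.anorexia),
        "migration_of_pain": tri(patient.migration_of_pain),
        "fever": above(patient.temperature_c, policy.temp_cutoff),
        "wbc_elevated": above(patient.wbc, policy.wbc_cutoff),
        "neutrophilia": neutrophilia,
        "crp_elevated": above(patient.crp, policy.crp_cutoff),
        "us_appendicitis": tri(patient.us_appendicitis),
    }
    return FeatureVector(values=values)


@dataclass(frozen=True)
class ScoreDefinition:
    """A named additive score: weighted binary items plus a positivity cutoff."""

    name: str
    items: tuple  # ordered ((feature name, integer weight >= 1), ...)
    positivity_cutoff: int
    threshold_policy: ThresholdPolicy = field(default=DEFAULT_POLICY)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple((str(f), int(w)) for f, w in self.items))
        for feature, weight in self.items:
            if feature not in FEATURES:
                raise ConfigurationError(f"{self.name}: unknown feature {feature!r}")
            if weight < 1:
                raise ConfigurationError(f"{self.name}: weight for {feature} must be >= 1")
        if not (1 <= self.positivity_cutoff <= self.max_score):
            raise ConfigurationError(
                f"{self.name}: positivity cutoff {self.positivity_cutoff} outside [1, {self.max_score}]"
            )

    @property
    def max_score(self) -> int:
        return sum(w for _, w in self.items)

    @property
    def feature_names(self) -> tuple:
        return tuple(f for f, _ in self.items)

    def with_policy(self, policy: ThresholdPolicy) -> "ScoreDefinition":
        return replace(self, threshold_policy=policy)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [[f, w] for f, w in self.items],
            "positivity_cutoff": self.positivity_cutoff,
            "threshold_policy": self.threshold_policy.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreDefinition":
        policy = data.get("threshold_policy")
        return cls(
            name=data["name"],
            items=tuple((f, w) for f, w in data["items"]),
            positivity_cutoff=int(data["positivity_cutoff"]),
            threshold_policy=ThresholdPolicy.from_dict(policy) if policy else DEFAULT_POLICY,
        )


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of evaluating one score on one patient."""

    name: str
    total: int
    positive: Optional[bool]  # None when incomplete
    contributing: tuple       # (feature, weight) pairs that scored
    complete: bool
    missing: tuple = ()


def compute_score(patient: PatientRecord, definition: ScoreDefinition) -> ScoreResult:
    """Evaluate one score on one patient.

    The total sums weight x indicator over the definition's items.  If any
    required indicator cannot be derived the result is flagged incomplete and
    ``positive`` is None (exclusion policy is the caller's decision); the
    total then covers the derivable items only.
    """
    vector = derive_features(patient, definition.threshold_policy)
    total = 0
    contributing = []
    missing = []
    for feature, weight in definition.items:
        indicator = vector[feature]
        if indicator is None:
            missing.append(feature)
        elif indicator:
            total += weight
            contributing.append((feature, weight))
    complete = not missing
    positive = (total >= definition.positivity_cutoff) if complete else None
    return ScoreResult(
        name=definition.name,
        total=total,
        positive=positive,
        contributing=tuple(contributing),
        complete=complete,
        missing=tuple(missing),
    )


class IncompletePatientError(ValueError):
    """Raised in ``error`` exclusion mode on the first incomplete patient."""


def apply_scores(
    cohort: Sequence[PatientRecord],
    definitions: Sequence[ScoreDefinition],
    exclusion: Literal["drop_incomplete", "error"] = "drop_incomplete",
) -> tuple[pd.DataFrame, list[dict]]:
    """Evaluate several scores across a cohort with a complete-case policy.

    With ``drop_incomplete``, any patient whose record cannot support every
    requested score is excluded from the evaluation set of ALL scores (the
    complete-case rule) and listed in the exclusion log.  Returns a frame
    indexed by patient id with ``<score>_total`` / ``<score>_positive``
    columns, and the log; included + excluded row counts always reconcile
    with the input.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    if exclusion not in ("drop_incomplete", "error"):
        raise ValueError(f"unknown exclusion policy {exclusion!r}")

    rows = []
    log: list[dict] = []
    for patient in cohort:
        results = [compute_score(patient, d) for d in definitions]
        missing = sorted({f for r in results for f in r.missing})
        if missing:
            if exclusion == "error":
                raise IncompletePatientError(
                    f"patient {patient.id} incomplete: missing {missing}"
                )
            log.append({"id": patient.id, "missing": missing})
            continue
        row = {"id": patient.id}
        for result in results:
            row[f"{result.name}_total"] = result.total
            row[f"{result.name}_positive"] = bool(result.positive)
        rows.append(row)

    columns = ["id"]
    for d in definitions:
        columns += [f"{d.name}_total", f"{d.name}_positive"]
    frame = pd.DataFrame(rows, columns=columns).set_index("id")
    assert len(frame) + len(log) == len(cohort)
    return frame, log


def _load_builtin_raw() -> dict:
    text = resources.files("appendiscore.data").joinpath("score_definitions.json").read_text()
    return json.loads(text)


def builtin_definitions(policy: Optional[ThresholdPolicy] = None) -> dict[str, ScoreDefinition]:
    """The six packaged score definitions, keyed by name.

    ``policy`` overrides the packaged default threshold policy for every
    score (e.g. to use the WBC > 12 x 10^9/L alternative cutoff).
    """
    raw = _load_builtin_raw()
    default_policy = policy or ThresholdPolicy.from_dict(raw["threshold_policy"])
    out = {}
    for entry in raw["scores"]:
        out[entry["name"]] = ScoreDefinition(
            name=entry["name"],
            items=tuple((f, w) for f, w in entry["items"]),
            positivity_cutoff=int(entry["positivity_cutoff"]),
            threshold_policy=default_policy,
        )
    return out


def get_definitions(
    names: Optional[Iterable[str]] = None,
    policy: Optional[ThresholdPolicy] = None,
) -> list[ScoreDefinition]:
    builtin = builtin_definitions(policy)
    if names is None:
        return list(builtin.values())
    out = []
    for name in names:
        if name not in builtin:
            raise ConfigurationError(
                f"unknown score {name!r}; built-ins: {sorted(builtin)}"
            )
        out.append(builtin[name])
    return out


def load_definitions_json(path) -> list[ScoreDefinition]:
    """Read score definitions from a JSON file (same schema as the packaged one)."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict) and "scores" in raw:
        policy = raw.get("threshold_policy")
        default_policy = ThresholdPolicy.from_dict(policy) if policy else DEFAULT_POLICY
        return [
            ScoreDefinition(
                name=e["name"],
                items=tuple((f, w) for f, w in e["items"]),
                positivity_cutoff=int(e["positivity_cutoff"]),
                threshold_policy=(
                    ThresholdPolicy.from_dict(e["threshold_policy"])
                    if "threshold_policy" in e
                    else default_policy
                ),
            )
            for e in raw["scores"]
        ]
    return [ScoreDefinition.from_dict(e) for e in raw]


def dump_definitions_json(definitions: Sequence[ScoreDefinition], path) -> None:
    with open(path, "w") as fh:
        json.dump([d.to_dict() for d in definitions], fh, indent=2)
        fh.write("\n")
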