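"""Diagnostic-accuracy panels for binary tests and integer-valued scores.

Computes the full panel a diagnostic study reports per score — sensitivity,
specificity, PPV, NPV, likelihood ratios and ROC-AUC, each with a 95% CI —
plus the closed-form identities linking the entries:

* ``LR+ = sens / (1 - spec)``, ``LR- = (1 - sens) / spec``;
* Bayes at prevalence p: ``PPV = sens*p / (sens*p + (1-spec)(1-p))`` and
  ``NPV = spec(1-p) / (spec(1-p) + (1-sens)p)``.

Confidence intervals default to Wilson score intervals for proportions, the
Simel log method for likelihood ratios, and DeLong's variance for the AUC;
a seeded multinomial bootstrap is offered as an alternative for all of them.
Undefined statistics (zero denominators) are reported as ``None``, never 0.

Also provides inversion of published predictive-value rows (a feature's
present count, PPV and NPV) back into the implied 2x2 table, reporting —
never silently correcting — any inconsistency with the stated case count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint


class Estimate(NamedTuple):
    """A point estimate with a 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of a binary prediction against a dichotomized outcome."""

    tp: int
    fp: int
    fn: int
    tn: int
    dichotomy: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(
    predictions: Sequence[bool],
    outcomes: Sequence[bool],
    dichotomy: str = "",
) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned prediction/outcome vectors."""
    pred = np.asarray(predictions, dtype=bool)
    outc = np.asarray(outcomes, dtype=bool)
    if pred.shape != outc.shape or pred.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-D vectors")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(pred & outc)),
        fp=int(np.sum(pred & ~outc)),
        fn=int(np.sum(~pred & outc)),
        tn=int(np.sum(~pred & ~outc)),
        dichotomy=dichotomy,
    )


@dataclass(frozen=True)
class DiagnosticPanel:
    """One row of a diagnostic-accuracy table; None marks undefined entries."""

    sensitivity: Optional[Estimate]
    specificity: Optional[Estimate]
    ppv: Optional[Estimate]
    npv: Optional[Estimate]
    lr_pos: Optional[Estimate]
    lr_neg: Optional[Estimate]
    auc: Optional[Estimate]
    n_evaluated: int


def wilson_ci(count: int, nobs: int, alpha: float = 0.05) -> Estimate:
    """Wilson score interval for a binomial proportion."""
    if nobs == 0:
        raise ValueError("nobs must be positive")
    low, high = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return Estimate(count / nobs, float(low), float(high))


def _lr_estimate(value: float, log_var: float, alpha: float) -> Estimate:
    z = norm.ppf(1 - alpha / 2)
    if value == 0 or not math.isfinite(log_var):
        return Estimate(value, float("nan"), float("nan"))
    half = z * math.sqrt(log_var)
    return Estimate(value, value * math.exp(-half), value * math.exp(half))


def lr_confidence(matrix: ConfusionMatrix, alpha: float = 0.05) -> tuple[Optional[Estimate], Optional[Estimate]]:
    """Likelihood ratios with log-method (Simel) confidence intervals."""
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    npos, nneg = matrix.n_positive, matrix.n_negative
    lr_pos = lr_neg = None
    if npos > 0 and nneg > 0:
        sens = tp / npos
        spec = tn / nneg
        if spec not in (0.0, 1.0):
            value = sens / (1 - spec)
            if tp > 0 and fp > 0:
                var = (1 / tp - 1 / npos) + (1 / fp - 1 / nneg)
                lr_pos = _lr_estimate(value, var, alpha)
            else:
                lr_pos = Estimate(value, float("nan"), float("nan"))
        if spec != 0.0:
            value = (1 - sens) / spec
            if fn > 0 and tn > 0:
                var = (1 / fn - 1 / npos) + (1 / tn - 1 / nneg)
                lr_neg = _lr_estimate(value, var, alpha)
            else:
                lr_neg = Estimate(value, float("nan"), float("nan"))
    return lr_pos, lr_neg


def roc_auc(score_totals: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Rank-based AUC (Mann-Whitney) with half credit for ties.

    Equals the trapezoidal area under the ROC curve traced over all
    thresholds of an integer-valued score.
    """
    scores = np.asarray(score_totals, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def delong_variance(score_totals: Sequence[float], outcomes: Sequence[bool]) -> tuple[float, float]:
    """AUC and its DeLong variance from per-patient scores and outcomes."""
    scores = np.asarray(score_totals, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("AUC requires both outcome classes")
    # midrank-based structural components (DeLong, DeLong & Clarke-Pearson)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-case components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-control components
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(score_totals, outcomes, alpha: float = 0.05) -> Estimate:
    auc, var = delong_variance(score_totals, outcomes)
    z = norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return Estimate(auc, max(0.0, auc - half), min(1.0, auc + half))


def binary_auc(sens: float, spec: float) -> float:
    """Two-point ROC AUC of a bare positive/negative classifier: (sens+spec)/2."""
    return (sens + spec) / 2.0


def _bootstrap_panel(
    matrix: ConfusionMatrix,
    n_boot: int,
    seed: int,
    alpha: float,
) -> dict:
    """Percentile bootstrap CIs by multinomial resampling of the 2x2 counts."""
    rng = np.random.default_rng(seed)
    counts = np.array([matrix.tp, matrix.fp, matrix.fn, matrix.tn], dtype=float)
    n = int(counts.sum())
    draws = rng.multinomial(n, counts / n, size=n_boot).astype(float)
    tp, fp, fn, tn = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = {
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "ppv": tp / (tp + fp),
            "npv": tn / (tn + fn),
            "lr_pos": (tp / (tp + fn)) / (fp / (fp + tn)),
            "lr_neg": (fn / (tp + fn)) / (tn / (fp + tn)),
        }
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {}
    for key, values in stats.items():
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            out[key] = (float("nan"), float("nan"))
        else:
            out[key] = (float(np.percentile(finite, lo)), float(np.percentile(finite, hi)))
    return out


def panel(
    matrix: ConfusionMatrix,
    score_totals: Optional[Sequence[float]] = None,
    outcomes: Optional[Sequence[bool]] = None,
    ci: str = "wilson",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiagnosticPanel:
    """Full diagnostic panel from a confusion matrix.

    ``score_totals`` and ``outcomes`` (aligned per-patient vectors) enable the
    ROC-AUC entry; without them AUC is omitted.  ``ci`` selects "wilson"
    (Wilson for proportions + Simel log method for LRs) or "bootstrap"
    (seeded multinomial percentile bootstrap for both).
    """
    if matrix.n_positive == 0 or matrix.n_negative == 0:
        raise ValueError("panel requires both condition classes to be represented")
    if ci not in ("wilson", "bootstrap"):
        raise ValueError(f"unknown CI method {ci!r}")

    def proportion(count: int, nobs: int) -> Optional[Estimate]:
        return wilson_ci(count, nobs, alpha) if nobs > 0 else None

    sens = proportion(matrix.tp, matrix.n_positive)
    spec = proportion(matrix.tn, matrix.n_negative)
    ppv = proportion(matrix.tp, matrix.tp + matrix.fp)
    npv = proportion(matrix.tn, matrix.tn + matrix.fn)
    lr_pos, lr_neg = lr_confidence(matrix, alpha)

    if ci == "bootstrap":
        boot = _bootstrap_panel(matrix, n_boot, seed, alpha)

        def rewrap(est: Optional[Estimate], key: str) -> Optional[Estimate]:
            if est is None:
                return None
            lo, hi = boot[key]
            return Estimate(est.value, lo, hi)

        sens = rewrap(sens, "sensitivity")
        spec = rewrap(spec, "specificity")
        ppv = rewrap(ppv, "ppv")
        npv = rewrap(npv, "npv")
        lr_pos = rewrap(lr_pos, "lr_pos")
        lr_neg = rewrap(lr_neg, "lr_neg")

    auc = None
    if score_totals is not None:
        if outcomes is None:
            raise ValueError("outcomes are required alongside score_totals for AUC")
        auc = auc_ci(score_totals, outcomes, alpha)

    return DiagnosticPanel(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc,
        n_evaluated=matrix.n,
    )


def ppv_npv_from_sens_spec_prev(sens: float, spec: float, prevalence: float) -> tuple[float, float]:
    """Predictive values implied by sensitivity, specificity and prevalence (Bayes)."""
    for name, value in (("sens", sens), ("spec", spec)):
        if not (0 <= value <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    p = prevalence
    ppv = sens * p / (sens * p + (1 - spec) * (1 - p))
    npv = spec * (1 - p) / (spec * (1 - p) + (1 - sens) * p)
    return ppv, npv


def lr_from_sens_spec(sens: float, spec: float) -> tuple[Optional[float], Optional[float]]:
    """Likelihood ratios from sensitivity and specificity; None when undefined."""
    lr_pos = sens / (1 - spec) if spec not in (0.0, 1.0) else None
    lr_neg = (1 - sens) / spec if spec != 0.0 else None
    return lr_pos, lr_neg


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def missed_cases(sens: float, n_cases: int) -> tuple[int, Optional[float]]:
    """Cases missed if only test-positive patients were treated.

    Returns ``(round((1 - sens) * n_cases), missed/n_cases)``; the fraction is
    None for an empty case group.
    """
    if not (0 <= sens <= 1):
        raise ValueError("sens must lie in [0, 1]")
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    missed = _round_half_away((1 - sens) * n_cases)
    return missed, (missed / n_cases if n_cases > 0 else None)


@dataclass(frozen=True)
class FeatureRow:
    """A published predictive-value row inverted back to its implied 2x2.

    ``consistency_gap`` is the absolute difference between the implied case
    count (tp + fn) and the study's reported case count; it is reported as-is,
    never corrected.
    """

    present_count: int
    total_n: int
    ppv: float
    npv: float
    tp: int
    fp: int
    fn: int
    tn: int
    consistency_gap: int

    @property
    def implied_cases(self) -> int:
        return self.tp + self.fn


def invert_feature_row(
    present: int,
    total: int,
    ppv: float,
    npv: float,
    reported_cases: int,
) -> FeatureRow:
    """Reconstruct the 2x2 behind a (present count, PPV, NPV) feature row.

    tp and tn are rounded half-away-from-zero; fp and fn follow by subtraction
    so the present/absent margins are preserved exactly.
    """
    if not (0 < present < total):
        raise ValueError("present must lie strictly between 0 and total")
    if not (0 <= ppv <= 1 and 0 <= npv <= 1):
        raise ValueError("ppv and npv must lie in [0, 1]")
    absent = total - present
    tp = _round_half_away(ppv * present)
    fp = present - tp
    tn = _round_half_away(npv * absent)
    fn = absent - tn
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("inverted row yields a negative cell")
    gap = abs((tp + fn) - reported_cases)
    return FeatureRow(
        present_count=present,
        total_n=total,
        ppv=ppv,
        npv=npv,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        consistency_gap=gap,
    )
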