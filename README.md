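# appendiscore

Clinical scoring and diagnostic-accuracy tooling for pediatric
appendicitis. Acute appendicitis is the most common reason for abdominal
surgery in children, and because the presentation is often atypical,
emergency departments use additive clinical scores to decide who needs
imaging or surgery. This package is for clinical epidemiologists and
methodologists who want to apply, evaluate, stress-test or re-derive such
scores on patient-level cohort tables — or on synthetic cohorts when no
patient-level data can be shared.

It provides:

* **Score engine** — the six scores commonly compared in pediatric
  cohorts: Alvarado (cutoff 5/10), Pediatric Appendicitis Score (6/10),
  Tzanakis (8/15), Heidelberg Appendicitis Score (3/4), modified HAS (3/5)
  and the four-item "AI score" (2/4). Raw values (WBC, CRP, neutrophils,
  temperature, ultrasound) binarize through strict-`>` threshold policies;
  missingness is explicit and handled by a complete-case rule, never
  imputed.
* **Diagnostic metrics** — sensitivity, specificity, PPV, NPV, LR±, and
  ROC-AUC with 95% CIs (Wilson / Simel log method / DeLong, or a seeded
  bootstrap), the closed-form identities linking them
  (`LR+ = sens/(1−spec)`; Bayes:
  `PPV = sens·p / (sens·p + (1−spec)(1−p))` at prevalence `p`), the
  missed-case counterfactual `round((1−sens)·n_cases)`, and inversion of
  published predictive-value rows back into 2×2 tables with an explicit
  consistency gap.
* **Synthetic cohort simulator** — seeded 463-child abdominal-pain
  cohorts with the reference class mix (127 no appendicitis / 234 simple /
  102 perforated), per-class demographics and symptom durations, feature
  frequencies calibrated from published predictive-value rows, and joint
  lab/ultrasound missingness (7/463).
* **Score derivation** — from-scratch CART (Gini splitting,
  cost-complexity pruning) and a bagged random forest (200 trees, Gini
  importances), plus the repeated 70/30 split procedure that turns
  retained features into a unit-weight score with a Youden-optimal cutoff.

See `docs/methods.md` for the models, assumptions and limitations.

## Worked example

```python
import appendiscore as ap

cohort = ap.generate_cohort(ap.CohortParameters(seed=1))   # 463 children
frame, excluded = ap.apply_scores(cohort, ap.get_definitions())
print(len(frame), len(excluded))                           # 459 4

from appendiscore.pipeline import evaluate_scores
panel, matrices = evaluate_scores(cohort, ap.get_definitions(["modified_has", "ai_score"]))
print(panel[["sensitivity", "specificity", "ppv", "npv", "auc", "n"]].round(3))
```

```
              sensitivity  specificity    ppv    npv    auc    n
score
modified_has        0.942        0.860  0.945  0.854  0.964  459
ai_score            0.976        0.729  0.902  0.922  0.962  459
```

Four of the 463 simulated children are missing the laboratory/ultrasound
block and are excluded complete-case; on the remaining 459, the modified
HAS flags 311 of the 330 appendicitis cases (sensitivity 0.942) while
keeping specificity 0.860 — the high-sensitivity/decent-specificity
profile these five-item unit scores are designed for. Each panel cell is
recomputable from the returned confusion matrix (here tp=311, fp=18,
fn=19, tn=111).

Re-deriving a score from the same cohort:

```python
complete = [p for p in cohort if p.wbc is not None]
result = ap.derive_score(complete, method="forest", repeats=5, n_trees=100, seed=1)
print([(name, round(imp, 3)) for name, imp in result.features])
# [('us_appendicitis', 0.367), ('crp_elevated', 0.159), ('wbc_elevated', 0.119),
#  ('fever', 0.109), ('rebound_tenderness', 0.053)]
print(result.score_definition.positivity_cutoff)   # 3
```

Ultrasound dominates the importance ranking, with CRP next — the same
qualitative ordering that motivated the modified HAS and AI score — and
the pooled-test-split Youden criterion lands on a 3-of-5 positivity
cutoff.

The same pipeline is scriptable from the shell:

```bash
appendiscore simulate --seed 1 --out cohort.csv
appendiscore report --cohort cohort.csv --seed 1 --out report/
appendiscore derive --cohort cohort.csv --method forest --seed 1 --out derived.json
```

`report/` then contains the per-feature predictive-value table, the
appendicitis and perforation panels, the missed-perforation
counterfactual, and the confusion matrices behind every cell.

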