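# Methods

`appendiscore` models the diagnostic work-up of children hospitalized with
suspected appendicitis: additive clinical risk scores applied to binarized
history / examination / laboratory / ultrasound items, evaluated against a
histology-based outcome in {no appendicitis, simple appendicitis,
perforated appendicitis}.

## Scores and binarization

Each score is a weighted sum of binary items with an inclusive positivity
rule, total ≥ cutoff. The packaged definitions are Alvarado (max 10,
cutoff 5), PAS (10, 6), Tzanakis (15, 8), HAS (4, 3), modified HAS (5, 3)
and the AI score (4, 2). The inclusive reading of the cutoff is a design
choice: the published cutoffs (e.g. 3 of 5 unit items) only discriminate as
inclusive bounds.

Raw values binarize through a `ThresholdPolicy` with strict `>`
comparisons, matching how the criteria are written clinically:

| cutoff | default | unit | note |
|---|---|---|---|
| WBC | 11 | 10⁹/L | published alternative 12; override per policy |
| neutrophils, absolute | 7.9 | 10⁹/L | OR-combined with the percentage rule |
| neutrophils, percent | 75 | % | |
| CRP | 20 | mg/L | |
| temperature | 38.5 | °C | |

Neutrophilia is positive if either recorded criterion (absolute or
percentage) holds; it is missing only when neither measurement was
recorded. Missing raw values propagate as incomplete indicators — never
silently 0 — and cohort evaluation applies a complete-case rule: a patient
who cannot support every requested score is excluded from all of them and
logged. Nothing is imputed anywhere in the package.

## Diagnostic panels

`panel()` computes sensitivity, specificity, PPV, NPV, LR+, LR− and
ROC-AUC from a 2×2 table (plus per-patient score totals for the AUC).
Confidence intervals are Wilson score intervals for proportions, the Simel
log method for likelihood ratios and DeLong's variance for the AUC; a
seeded multinomial percentile bootstrap (2000 resamples) is available as an
alternative for the 2×2-derived quantities. These are standard
diagnostic-accuracy choices; the methods behind the reference cohort's
printed intervals are not recoverable, so no claim of CI-method equivalence
is made. Undefined statistics (zero denominators, boundary specificity)
are reported as `None`, never coerced to 0.

AUC uses midranks (ties get half credit), which equals the trapezoidal
area over all integer thresholds of a discrete score. For a bare
positive/negative classifier the two-point AUC `(sens+spec)/2` is exposed
separately as `binary_auc` and labelled as such.

The perforation dichotomy contrasts perforated vs non-perforated
appendicitis *within* confirmed cases; children without appendicitis are
excluded from that contrast. The missed-case counterfactual is
`round((1−sens)·n_perforated)` with round-half-away-from-zero, i.e. the
perforations undetected if only score-positive children had surgery.

## Inverting published predictive-value rows

A published feature row (present count, PPV, NPV) inverts to an implied
2×2: `tp = round(ppv·present)`, `tn = round(npv·absent)`, with fp/fn by
subtraction so the present/absent margins are exact. The gap between the
implied case margin `tp+fn` and the study's stated case count is reported
as `consistency_gap` and never corrected — several reference rows are
internally inconsistent (rebound tenderness implies ~371 cases against 336
stated, gap 35; the temperature row's gap is 74).

## Synthetic cohort generator

The generator emulates a 463-child cohort: class mix
(127 none, 234 simple, 102 perforated)/463; per-class truncated-normal
ages on the 1–17-year inclusion range (none 11.6 (3.7), simple 10.9 (3.3),
perforated 10.0 (4.2) years); female fractions 53/127, 143/234, 70/102;
lognormal symptom durations moment-matched to none 57.8 (73.4), simple
34.3 (39.7), perforated 52.1 (48.7) hours (lognormal because SDs of this
size are incompatible with a positive normal; the simple class is the
shorter-duration appendicitis group); and joint missingness of the
laboratory + ultrasound block with probability 7/463 (clinical findings
are never missing).

Feature probabilities are calibrated by inverting the reference
predictive-value rows: consistent rows (gap ≤ 5) use
`P(f|case) = tp/336`, `P(f|non-case) = fp/127`; flagged rows are
renormalized to their own implied margins (`tp/(tp+fn)`, `fp/(fp+tn)`),
distributing the gap proportionally, with every adjustment listed in the
calibration report. The anomalous temperature row (present 312/463,
PPV 97.4) is deliberately taken at face value and flagged rather than
second-guessed.

Continuous laboratory magnitudes are two-component conveniences: the
thresholded indicator is drawn first from the calibrated Bernoulli, then a
magnitude strictly on that side of the cutoff (multiplicative lognormal-style
factors for WBC/CRP/absolute neutrophils, additive offsets for temperature
and neutrophil percentage). Only the indicators are calibrated; the
magnitudes are not meant to match any real laboratory distribution.

What the simulator does *not* model, and hence what passing tests cannot
show about real data:

* binary features are conditionally independent given class — real
  clinical signs co-occur (e.g. rebound and cough/hop tenderness);
* simple and perforated appendicitis share one set of feature
  probabilities (the calibration source only dichotomizes appendicitis vs
  none), so simulated scores carry no perforation signal beyond class mix,
  age and duration;
* no triage pre-selection or referral bias beyond the class mix.

## Score derivation (CART and random forest)

`fit_cart` grows a binary tree by greedy Gini-gain splitting of binary
features (no feature reused on a path; ties broken by feature declaration
order; growth stops at purity, `min_leaf`, or feature exhaustion), then
applies weakest-link cost-complexity pruning against resubstitution
misclassification risk. The complexity parameter defaults to 0.01; 0.0
still collapses zero-improvement subtrees, and a negative value disables
pruning (used for exact tree/forest equivalence checks). `fit_forest`
bags `n_trees` (default 200) unpruned trees on bootstrap resamples of size
n with `mtry = ⌈√p⌉` candidate features per split, aggregates
probabilities by averaging, and reports normalized mean-decrease-in-Gini
importances; permutation importance was considered and not adopted as the
default since impurity importance is the convention of the R forest
implementation this mirrors. Out-of-bag error is available from the stored
bootstrap indices.

`derive_score` repeats a 70/30 train/test split (default 20 times), fits
the chosen model per repeat, averages normalized importances, retains
features with mean importance ≥ a floor (default 0.05), and assembles them
into a unit-weight score. How the original analysis turned tree output
into a unit-weight 5-item score with cutoff 3/5 is not documented
anywhere; this package's reconstruction chooses the positivity cutoff that
maximizes the Youden index (sens + spec − 1) on the pooled test splits,
with ties going to the lower cutoff. Reported per-repeat metrics are test
split accuracy, sensitivity and specificity.

## Numerical and degenerate-input conventions

* All rounding of implied counts is half-away-from-zero.
* Gini-gain ties and importance-sort ties resolve by feature declaration
  order; everything randomized flows from one `numpy` `default_rng` seed,
  so fixed seeds give bit-identical cohorts, forests and report bundles.
* Single-class labels yield a stump; an all-noise derivation aborts with
  an informative error rather than emitting an empty score.
* Reports print percentages to 1 decimal and ratios/AUC to 2 decimals;
  underlying JSON keeps full precision.

## Problem sizes used in the test suite

The suite exercises the simulator at the study size (n = 463) and at
n = 10⁴ (parameter recovery, 20 seeds) and n = 10⁵ (law-of-large-numbers
frequency check); forests at 200 trees; derivation checks at 5 repeats ×
100 trees on n = 600 cohorts. These sizes make the stochastic assertions
stable at 3-SD tolerances while keeping the default run fast.

## Known limitations

* The temperature calibration row is internally inconsistent at source
  (implied case margin 410 vs 336). Taken at face value, the simulated
  fever item is nearly as discriminative as CRP (expected root Gini gain
  0.113 vs 0.126), so in roughly half of the simulated cohorts at n = 463
  fever displaces CRP from the top two forest importances. The qualitative
  ordering that *is* stable — ultrasound first, CRP ahead of rebound
  tenderness and WBC — is asserted in the unit suite; the stricter
  "ultrasound and CRP top-two in ≥ 80% of seeds" reproduction is kept as
  an acceptance check and fails under these calibration conditions.
* Published importance magnitudes (0.37/0.25/0.21/0.08) are treated as
  qualitative ranking targets only; the underlying patient-level data is
  not available, so no numeric importance comparison is meaningful.
* Cohort-level sensitivities and AUCs of the reference study are not
  reproducible from published material; only the closed-form identities
  linking its printed cells are.
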