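# shapform

Construction of an abbreviated questionnaire from a long psychometric scale
by Shapley-value item ranking under repeated stratified cross-validation.

The pipeline operates on a 61-item Likert (0–4) instrument whose items
measure five correlated syndrome criteria (entrapment, affective
disturbance, loss of cognitive control, hyperarousal, social withdrawal),
with two binary outcomes derived from a 9-item yes/no screener (any yes on
items 1–5; item 6 alone). It:

1. **simulates** a cohort from a multidimensional graded-response model with
   correlated latent factors and logistically linked outcomes calibrated to
   target prevalences (≈19.1% and ≈2.3%), with total-score reliability
   α ≈ 0.98 at the default calibration;
2. **ranks** items by repeated stratified 4-fold cross-validation (default
   1,000 repetitions): each fold-model is a penalized logistic regression
   (from-scratch IRLS); per fold-model, closed-form linear Shapley
   attributions on the held-out rows are aggregated into a global importance
   (mean |φ|, log-odds scale), and the count of fold-model top-20
   appearances per item — with a ceiling of repetitions × folds = 4,000 —
   is the ranking statistic;
3. **compares** a ranking's top-10 criterion distribution to an existing
   8-item reference short form (similarity = 1 − L1/2);
4. **builds** the reduced instrument by a per-criterion quota rule
   (default 2 per criterion, 1 for social withdrawal ⇒ 9 items), filling
   any quota the primary ranking cannot satisfy from a fallback ranking.

The Shapley engine has three mutually validating routes: exact 2^p coalition
enumeration (oracle, p ≤ 14), the linear closed form (production path), and
a kernel weighted-least-squares approximation for black-box models. All
performance indices (accuracy, precision, recall, balanced accuracy, AUROC
with tie credit, step-wise average precision) and Cronbach's alpha are
implemented from scratch; scikit-learn appears only as a test reference and
behind the optional tree-ensemble adapter.

## CLI

```bash
shapform simulate --n 2000 --seed 0 --out sim/
shapform rank --responses sim/responses.csv --outcomes sim/outcomes.csv \
    --outcome SI --reps 50 --seed 0 --out ranking_si.csv
shapform compare --ranking ranking_si.csv --out overlap.json
shapform build --primary ranking_si.csv --out short_form
shapform run-all --n 2000 --reps 50 --seed 0 --out pipeline_out/
```

`run-all` executes every stage and writes a `manifest.json` capturing the
config, seeds, versions and stage timings; rerunning with the same config
and seed reproduces the artifacts byte-for-byte.

## Layout

| Module | Role |
| --- | --- |
| `shapform.instrument` | item bank / response / screener data model and CSV I/O |
| `shapform.synthetic` | graded-response cohort simulator with ground truth |
| `shapform.models` | IRLS logistic regression; sklearn ensemble adapter |
| `shapform.metrics` | classification indices and Cronbach's alpha |
| `shapform.shapley` | exact / linear / kernel Shapley attribution |
| `shapform.sfi` | repeated stratified CV and top-k count ranking |
| `shapform.shortform` | criterion-distribution comparison and quota assembly |
| `shapform.reference` | bundled default bank, comparator form, published rankings |
| `shapform.pipeline`, `shapform.cli` | orchestration, manifests, CLI |

Notes: attributions are additive on the log-odds (margin) scale, not on
probabilities. Reverse-coded items are mapped x → 4 − x exactly once (the
matrix records the application; a second application raises). Ranking ties
are broken by bank order everywhere, documented in the outputs.
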