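# Methods

## Model

The model is a discrete Bayesian network over 14 categorical clinical
variables: nine preoperative predictors (biopsy tumor grade; ER, PR, p53 and
L1CAM immunohistochemistry; Ca-125; thrombocyte count; lymphadenopathy on
imaging; cervical cytology), three intermediate postoperative nodes that
carry the tumor-progression structure (hysterectomy grade, myometrial
invasion, lymphovascular space invasion — present in the graph but never
supplied as prediction evidence), and two outcomes (lymph-node metastasis and
5-year disease-specific survival). The joint distribution factorizes over a
DAG; each node carries a conditional probability table (CPT) over its levels
given every configuration of its parents.

Variable encodings follow the standard preoperative cutoffs: Ca-125
dichotomized at 35 IU/ml, thrombocytes at 400×10⁹/l, ER/PR/L1CAM at 10%
stained tumor cells, p53 wild type vs aberrant, grade 1/2/3, imaging and
cytology binary. Values exactly at a cutoff map to the "≥" level. Myometrial
invasion is encoded with two levels (<50%, ≥50%) — the encoding the cohorts
being emulated actually record — rather than the three-level candidate
encoding. 5-year DSS is a binary node (survived/died within 5 years);
censoring before 5 years is out of scope for the generator and must be
resolved upstream in real data.

### Default topology

Only three arcs of the published graph are attested unambiguously in text:
MI → LNM, LVSI → LNM and LNM → DSS5. The remaining default arcs are an
explicit reconstruction, flagged as such and overridable through
configuration: tumor biology (postoperative grade) drives the biopsy markers
(preoperative grade, ER, PR, p53, L1CAM) and local invasion (MI, LVSI);
nodal disease drives the diagnostic findings (lymphadenopathy, thrombocytes,
Ca-125); LVSI drives cervical cytology; survival depends on nodal status and
the p53 class. Analyses and tests never rely on the reconstructed arcs being
the published ones. One deliberate deviation from a stated invariant: the
outcome LNM *does* have predictor children (the diagnostic-finding arcs
above), because that is the causal reading of lymphadenopathy, thrombocytosis
and Ca-125 elevation; the enforced structural invariants are instead that
DSS5 is terminal and that intermediate/outcome nodes are rejected as
prediction evidence.

## Inference

Posterior marginals are computed exactly by variable elimination: CPT factors
are reduced on the evidence, non-query variables are summed out in min-fill
order (declaration-order tie-break, so results are deterministic), and the
result is normalized. The normalization constant is P(evidence); when it is
zero an `ImpossibleEvidenceError` is raised rather than returning a zero
vector — silent zeros would be dangerous in a clinical tool. Factor
arithmetic stays in linear space with a per-step renormalization guard whose
accumulated log-scale keeps posteriors exact; at 14 nodes log-space and
junction trees are unnecessary. Exactness matters here because the model's
semantics are "probability distributions update when evidence is entered":
test suites hold variable elimination to within 1e-9 of exhaustive
enumeration on hundreds of random networks of up to 12 binary nodes.

## Parameter and structure learning

CPTs are fitted as Dirichlet-posterior means, `(count + ess/r) /
(row_total + ess)` with `r` the child cardinality; `ess = 0` gives raw
maximum-likelihood frequencies and makes unseen parent configurations an
error instead of silently producing undefined rows. The default `ess = 1` is
the usual mild symmetric prior.

Structure search is greedy over single-arc moves (add/delete/reverse) with
per-family score caching. The search score is BIC,
`loglik − (free parameters)·log(n)/2`: raw log-likelihood always prefers
denser graphs, so it is kept only for goodness-of-fit reporting, matching the
standard practice of the score-based structure-learning literature this
pipeline follows. Hill-climbing applies the best strictly improving move
until none exists; tabu search (default memory 10 moves, stall limit 15)
additionally accepts non-improving moves, forbids the inverses of recent
moves unless they beat the best score seen, and returns the best structure
visited — with memory 0 it returns the hill-climbing optimum. Both scan
candidate moves in a canonical order, so results are deterministic; the seed
argument affects nothing inside a single search.

Arc robustness is assessed by nonparametric bootstrap: rows are resampled
with replacement (resample size n), one structure is learned per resample
(500 by default; the scaled-down test protocol uses 100), and each edge's
**strength** is its undirected selection frequency, with a separate
direction-agreement fraction. The rationale: the inclusion rule concerns the
frequency of an *edge between two variables*, so presence is scored
undirected and the strictly-greater-than-0.7 threshold is applied to
presence, while direction is decided afterwards by majority agreement
(declaration-order tie-break). If the consensus set contains a
directed cycle, the weakest arc on the cycle (lowest strength, then lowest
direction agreement) is removed until acyclic. At threshold 1.0 the rule
keeps exactly the arcs present in every bootstrap structure.

The end-to-end development workflow is: expert whitelist → bootstrap arc
strengths on complete cases → threshold at 0.7 → merge with the whitelist →
initial CPT fit on complete cases → model-based imputation of the full
cohort → final CPT fit on the completed data → log-likelihood report against
the whitelist-only model. Every stage's seed is recorded in the run manifest.

## Imputation

Missing cells are filled per record from the exact joint posterior of the
record's missing variables given its observed cells (computed by the
inference module), from which 500 coherent samples are drawn by default.
"Averaging" the samples is realized, for categorical data, as the empirical
posterior vector per missing cell; the filled level is that vector's mode
(ties broken by level declaration order), and the vector is retained for
downstream use. Sampling from the exact joint rather than rejection-filtering
forward samples avoids pathologies under low-probability evidence, and
drawing jointly per record (not per cell) keeps each imputed record
internally coherent. Records sharing an observed-value pattern share one
posterior computation. Observed cells are never altered; at 5,000 samples
the empirical cell posteriors sit within 0.03 of the exact posteriors in the
test battery.

## Validation battery

Discrimination: AUC as all-pairs concordance with half credit for ties
(identical to trapezoidal ROC integration), 95% CI by DeLong's method (the
midrank formulation); a percentile-bootstrap CI is available as an option.
Overall accuracy: Brier score. Calibration: decile bins of the predicted
probabilities (merged when quantile boundaries coincide) with exact
Clopper–Pearson CIs per bin, plus the predicted/observed event ratio with a
2,000-resample percentile-bootstrap CI. Cutoff diagnostics use the
predicted-positive ⇔ probability ≥ cutoff convention (ties positive) and
report, besides sensitivity/specificity/PPV/NPV, the event rate among
predicted-negatives (the rule-out false-negative rate) and the non-event
fraction among predicted-positives. The latter is reported as *false
discovery* because that is what the corresponding published percentage
(149/197 ≈ 76% above the 5% boundary) numerically is — it is not
FP/(FP+TN) — and both quantities are exposed under unambiguous names.

Risk groups partition [0, 1] into five half-open intervals — <1%, 1–5%,
5–15%, 15–25%, ≥25% — with the low/intermediate boundary at 0.05 because the
pooled "<5% risk" claim sums exactly the first two printed groups. Decision
curves report net benefit `TP/n − (FP/n)·t/(1−t)` against treat-all
(`π − (1−π)·t/(1−t)`) and treat-none (≡ 0).

Validation predictions use each patient's available predictor evidence only —
no imputation at validation time, mirroring how such a network is used on
external cohorts with missing findings.

## Synthetic cohorts

The `endorisk14` preset is a hand-authored parameterization of the default
topology. Its CPTs were chosen so the implied marginals match the
development cohort's published baseline frequencies computed over recorded
cases (ER-negative ≈ 0.10, PR-negative ≈ 0.18, L1CAM-positive ≈ 0.11,
p53-aberrant ≈ 0.16, Ca-125 ≥ 35 ≈ 0.22, thrombocytosis ≈ 0.04,
lymphadenopathy ≈ 0.08, abnormal cytology ≈ 0.06, LVSI ≈ 0.18), with the
prior nodal risk near 0.10 — between the published 8.6% baseline estimate
and the 11.7% validation-cohort prevalence. Conditional effect sizes are
realistic but deliberately clear (e.g. Ca-125 elevation 17% vs 65% by nodal
status), so that recovery tests measure the machinery rather than fight
vanishing signals. The preset does **not** claim to equal the unpublished
fitted parameters of the clinical model; tests that need the published
worked-example point values would require the externally distributed network
file and instead assert the update mechanism.

Missingness injection supports MCAR at per-variable rates (defaults mirror
the development cohort's unknown fractions, e.g. 46.5% for Ca-125) and a
single-conditioner MAR mechanism in which the odds of a hole are multiplied
when the true value of one fully observed conditioning variable matches a
given level; a multiplier of 1 reduces exactly to MCAR. Richer missingness
models were deliberately not invented. What passing tests therefore show:
the pipeline recovers structure, parameters and missing cells when its
assumptions hold. What they do not show: performance under misspecified
topology, unmeasured confounding, measurement error in immunohistochemistry
scoring, informative (MNAR) missingness, or censoring — all realities of the
clinical data this generator only schematically emulates.

Smaller presets serve focused tests: `chain4` (four binary nodes in a chain,
uniform marginals, 85% persistence — strong enough coupling that posterior
imputation demonstrably beats the marginal-mode baseline) and `independent3`
(no arcs; the null case for structure learning).

## Numerical choices and problem sizes

- CPT rows must sum to 1 within 1e-9; file readers renormalize rows off by
  at most 1e-6 and reject anything worse.
- Level order is declaration order, canonical everywhere (CPT axes,
  tie-breaks, point-mass construction).
- Log-likelihood of data containing an impossible row is an explicit −inf
  sentinel, keeping model comparison total; missing cells raise instead,
  directing the caller to impute first.
- Score caching keys on (child, sorted parent set); search determinism comes
  from canonical move ordering, not seeding.
- Test and acceptance problem sizes — 200 oracle networks of ≤12 nodes,
  n = 20,000 for parameter recovery, n = 2,000 with B = 100 for the
  bootstrap-recovery analogue of the full B = 500 protocol, n = 1,000 with
  20% MCAR for imputation — are the package's chosen working points: large
  enough for the stated tolerances (TV < 0.05 on rows visited ≥ 100 times;
  ≥ 80% true-arc / ≤ 10% false-arc recovery; ≥ 5-point imputation margin),
  small enough to run routinely.

## Known limitations

- The published clinical CPTs are not distributed with the package; the
  bundled parameterization is synthetic, and clinical predictions require
  loading a fitted network file.
- Nodes are discrete only; no continuous/hybrid nodes, temporal dynamics, or
  do-calculus interventions.
- Inference is exact and intended for networks of this scale; no
  approximate engines are provided.
- Survival is a fixed-horizon binary node; no time-to-event or
  competing-risk modelling.
- Multiple imputation here means Monte-Carlo posterior averaging within one
  model — Rubin's-rules pooling across completed datasets and EM-style
  learning from incomplete data are out of scope.
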