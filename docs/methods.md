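# Methods

## Problem setting

The package targets a cohort-outcome problem from cardiology EMR data:
patients admitted (inpatient or emergency) with angina (ICD-10 I20)
between 2000-01-01 and 2016-12-31, with no prior myocardial infarction,
stroke or heart failure, are followed for five years from their earliest
qualifying admission; the prediction target is the binary composite
occurrence of death, MI, stroke or heart failure in that window. Five
years is encoded as 1826 days (365.25 × 5, rounded); an event on the
index day itself does not count as follow-up (follow-up is strictly
after the index), and any excluded-history event strictly before the
index removes the patient. The composite event set and the exclusion
set are both configurable on `CohortCriteria`; the default includes
stroke in the composite.

## Synthetic data generator

No public EMR extract of this shape exists, so all experiments run on a
generator that reproduces the cohort's statistical skeleton:

- **Admission structure.** Index admission dates are uniform on the
  2000–2016 window. A configurable fraction of patients
  (`fraction_outpatient_only`, default 0.15) receives its index diagnosis
  on an outpatient encounter only; another fraction
  (`fraction_prior_event`, default 0.10) gets an exclusion event 30 days
  to 10 years before the index. Both groups exist purely to give the
  cohort filters real work; the remainder is the eligible cohort.
- **Demographics and measurements.** Age at index is normal (mean 62,
  sd 11, clipped to 30–90). Laboratory (blood, glucose, creatinine,
  LDL), echocardiographic (EF, GLS, LVEDD) and physical (weight, height,
  SBP, DBP) values are Gaussian with clinically plausible centers; each
  measurement row is present with probability 0.85–0.95 so that
  missingness and latest-before-index aggregation are exercised.
  Diagnosis rows add a Zipf-weighted long tail of ~190 three-character
  ICD-10 codes so the top-146+other feature bucketing is meaningful.
- **Outcome model.** The event probability is logistic:
  `σ(c + 0.08·(age−62) + s·[0.35·z(SBP) + 0.30·z(blood) + 0.25·z(glucose)
  − 0.35·z(EF) + 0.25·smoke])`, with `s = signal_scale` (default 1). The
  intercept `c` is solved by root-finding so that the *mean* event
  probability among filter-surviving patients equals `event_prevalence`
  (default 1/12 — negatives outnumber positives more than tenfold, and
  the positive age effect makes event-positive patients older on
  average). Positives receive an event date uniform in (0, 1826] days
  after the index; 20% of negatives receive a late event in (1826, 2922]
  days so that beyond-horizon events occur.

What the generator does **not** emulate: longitudinal visit-by-visit
disease progression, realistic ICD-10 co-occurrence structure, informative
missingness, inter-measurement correlation, or censoring/competing risks.
Passing tests therefore demonstrate that the pipeline's mechanics and the
model's capacity to recover a feature-mediated logistic signal are
correct — not that any particular performance level transfers to real
EMR data.

## Property graph

One node per populated per-patient record group (not per raw row),
aggregated to the latest value at or before the index admission; record
counts (visits, distinct medications, distinct diagnosis codes) are kept
as node properties. An Event node per labeled patient stores the outcome,
and for positives the first post-index event type and the patient's
(integer) age at that event. Every non-person node hangs off exactly one
Person node — the star invariant is enforced at edge insertion, so no
query can ever traverse between two non-person nodes except through a
person. Relation labels are determined by the tail node's label
(HAS_DIAGNOSIS, HAS_LAB, HAS_ECHO, HAS_PHYSICAL, TAKES_MEDICATION,
UNDERWENT_SURGERY, HAS_VISIT, HAS_SMOKING_STATUS, EXPERIENCED_EVENT).

The Cypher exporter targets the bulk-import dialect: one uniqueness
constraint per node label, index statements on lookup attributes, and
per-label CSV chunks of at most `batch_size` rows, each loaded by its own
`USING PERIODIC COMMIT` transaction (so no single transaction exceeds the
batch size). Property types (int/float/str) are inferred per
label-property pair and encoded as `toInteger`/`toFloat` conversions in
the load statements; floats are written with `repr`, which round-trips
IEEE doubles exactly. `parse_cypher_export` parses exactly this dialect
back (anything else raises a parse error naming the file and line), which
gives a lossless export→parse identity that the test suite fuzzes. No
database server is involved; the in-memory engine answers journey and
conjunctive patient queries directly.

## Bipartite learning graph

Default patient features (12): age at index, sex, smoking level, three
laboratory values (blood, glucose, LDL), ejection fraction, systolic
blood pressure, weight, and medication/visit/distinct-diagnosis counts.
Continuous features are median-imputed (training-split medians) and
z-scored with training-split statistics; count-like and binary features
are left on their natural scale; optional missingness indicators can be
appended per feature. Diagnosis features (147): indicators over the 146
most frequent three-character codes (ties broken lexicographically,
always-zero padding columns if the data has fewer codes) plus one
"other" bucket.

In the default `per_patient` mode each patient links to its own
diagnosis-profile node — so N patients force 2N nodes and N edges, and
every node has degree 1. `shared_diagnosis` mode collapses identical
profiles into shared nodes, giving a true multigraph with varying
degrees. Node IDs carry `p_`/`d_` prefixes so raw IDs can never collide
across partitions. The outcome is stored as the edge's single attribute;
it is the training target and is never fed to the encoder as an input
feature.

## HinSAGE model

Two layers, type-specific weights. Hidden sizes default to (32, 32),
realized as 16 "self" + 16 "neighbor" concatenated units per layer;
neighbor sample counts default to (8, 4); the link head concatenates the
two endpoint embeddings (Hadamard is available). Defaults: Adam,
learning rate 1e-3, batch size 200, 30 epochs, 80/20 stratified split,
ReLU hidden activation, linear output, L2-normalized final embeddings,
0.5 probability cutoff for the accuracy series. These are explicit
package defaults, chosen as ordinary values for a model of this size;
nothing in the method depends on them being optimal.

Numerical choices: neighbor sampling is uniform, with replacement when
the degree is below the sample count and without replacement otherwise;
in the default per-patient graph every degree is 1, so sampling
deterministically repeats the single neighbor — documented, expected
behavior. Isolated nodes (possible only in `shared_diagnosis` mode)
aggregate a designated sentinel whose representation is exactly zero at
every layer — the layer-1 hidden state of the sentinel is forced to zero
rather than ReLU(bias), which makes the sampled forward pass agree
exactly with the dense "mean over the full (possibly empty) neighbor
multiset" recursion. Embedding normalization guards the norm with 1e-12;
cross-entropy is clamped with 1e-12. Gradients are hand-derived
(including through the L2 normalization and segment means) and verified
against central finite differences at 1e-6 tolerance; the exhaustive-mode
forward pass is verified against an independently coded dense recursive
aggregator on fuzzed multigraphs.

Training is fully seeded: weight initialization (Glorot uniform), epoch
shuffling, neighbor sampling and the validation pass all derive from the
configured seeds, so a run is bit-reproducible. A plain SGD optimizer is
available alongside Adam; in the small-step limit (lr 1e-4 on a fixed
batch) SGD training loss is non-increasing, which the suite checks over
the first ten steps.

## Evaluation

AUROC uses the Mann–Whitney convention (ties 1/2) and AUPRC is average
precision, both delegated to scikit-learn behind the module surface and
cross-checked in the tests against brute-force pairwise enumeration and
direct threshold-sweep average precision. Confidence intervals are
stratified percentile bootstraps (default 1000 resamples, α = 0.05):
positives and negatives are resampled separately, so a resample can
never lose a class; the suite checks ~95% empirical coverage against a
binormal score model with known AUROC. Baselines share the exact split
and seed with the GNN: random forest (500 trees), L2 logistic regression
on standardized inputs, and a (32, 32) ReLU multilayer perceptron. The
comparison report recomputes every table entry from the stored score
vectors and renders ROC curves and the true-vs-predicted outcome count
distribution at the 0.5 threshold.

## Problem sizes used in the checks

Structural counts are computed at the full 53,841-patient cohort size
(the bipartite construction is linear and takes seconds). Statistical
checks run at sizes chosen to make their tolerances meaningful on one
CPU: class-balance and prevalence calibration on 50,000 generated
patients (3 binomial standard errors), permutation-null and
signal-recovery training on 5,000-patient cohorts, bootstrap coverage
over 200 replicates of n=500. The signal-recovery check uses
`signal_scale=3` and prevalence 0.25 — a condition where the generator's
injected feature signal is strong enough that an oracle logistic
regression on the flattened features clears AUROC 0.80, so the same bar
for HinSAGE tests the model rather than the data.

## Known limitations

- The per-patient bipartite default makes HinSAGE's neighborhood trivial
  (degree 1); the graph machinery earns its keep only in
  `shared_diagnosis` mode or on richer schemas.
- The property-graph builder iterates patients in Python; it is meant
  for cohorts up to tens of thousands of patients, not millions.
- Only the emitted Cypher dialect is parsed back; arbitrary Cypher is
  out of scope, as is running a live graph database.
- The feature schema's 12/147 defaults are dimensionality stand-ins with
  sensible clinical content, not a validated variable selection.
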