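# emrgraph

Graph construction and graph representation learning for electronic
medical records (EMR), aimed at clinical-informatics researchers who want
to move per-patient relational tables into graph form and predict
outcomes on top of them.

The package builds two complementary graph views of an EMR extract:

1. **A patient-centric heterogeneous property graph** — ten typed node
   labels (Person plus Diagnosis, Laboratory, Echocardiography, Physical,
   Medication, Surgery, Visit, Smoke, Event) and nine typed relations, all
   radiating from the Person node in a star. It supports patient-journey
   and cross-sectional queries in memory, and exports Neo4j-style bulk
   import scripts (uniqueness constraints, lookup indexes, batched
   `LOAD CSV` transactions under `USING PERIODIC COMMIT`) as well as
   GraphML.
2. **A bipartite attributed learning graph** — patient nodes with
   12-dimensional feature vectors, diagnosis-profile nodes with
   147-dimensional multi-hot vectors, and one edge per patient carrying a
   single binary attribute: the five-year composite cardiovascular event
   outcome (death, myocardial infarction, stroke, or heart failure after
   an index angina admission).

On the bipartite graph, outcome prediction is posed as **supervised link
attribute inference** with a from-scratch two-layer **HinSAGE**
(heterogeneous GraphSAGE) model. For a node v of type t with sampled
neighbor multiset S(v):

    h_v^k = σ( W_self^{t,k} h_v^{k-1} ⊕ W_neigh^{t,k} · mean_{u∈S(v)} h_u^{k-1} + b^{t,k} )

with ⊕ concatenation, ReLU on the hidden layer, linear output, and
L2-normalized final embeddings; an edge (p, d) is scored by a logistic
link head `σ(w·[z_p ⊕ z_d] + b)` trained with minibatch Adam on binary
cross-entropy. Backpropagation is hand-derived in numpy (verified against
finite differences and a dense full-neighborhood oracle in the tests).
Random-forest, logistic-regression and neural-network baselines run on
the flattened 159-column feature matrix with identical splits, and
evaluation reports AUROC and AUPRC with stratified percentile-bootstrap
95% confidence intervals.

Real cardiology EMR extracts are access-restricted, so the package ships
a calibrated synthetic generator (`emrgraph.synthetic`): an angina (ICD-10
I20) admission cohort with inpatient/ER encounters in a 2000–2016 window,
eight auxiliary record tables per patient, and a logistic outcome model in
age and clinical covariates whose intercept is solved numerically so that
post-filter event prevalence hits a configurable target (default 1/12, so
negatives outnumber positives more than tenfold and positives are older
on average).

## Worked example

`examples/03_train_hinsage.py` generates 2,000 cohort patients, trains
HinSAGE for 15 epochs and compares it with the baselines:

```
bipartite graph: 4000 nodes, 2000 edges (12/147 features per partition)
after 15 epochs: train acc 0.914, val acc 0.915
| Model | AUROC (95% CI) | AUPRC (95% CI) |
|---|---|---|
| RF | 0.65 [0.56, 0.75] | 0.24 [0.14, 0.44] |
| ANN | 0.62 [0.51, 0.72] | 0.14 [0.11, 0.24] |
| HinSAGE | 0.69 [0.61, 0.78] | 0.19 [0.13, 0.37] |
| LR | 0.64 [0.55, 0.74] | 0.20 [0.12, 0.36] |
```

A cohort of N patients always yields 2N nodes and N edges (each patient
links to its own diagnosis-profile node), accuracies track the ~0.92
majority-class rate at 1/12 prevalence, and AUROC above 0.5 means the
model recovered the age/risk-factor signal the generator embeds in the
outcome. The other examples cover cohort selection
(`01_generate_and_select_cohort.py`), property-graph queries and the
lossless Cypher export→parse round-trip (`02_property_graph_queries.py`),
and the end-to-end pipeline with its hash manifest
(`04_full_pipeline.py`).

## Command line

A thin CLI wraps the library:

```bash
emrgraph generate --n-patients 5000 --seed 0 --outdir tables/
emrgraph cohort --in tables/ --out cohort.csv
emrgraph build-pg --tables tables/ --cohort cohort.csv --out pg/ --format both
emrgraph query --tables tables/ --cohort cohort.csv --medication statin
emrgraph build-bg --tables tables/ --cohort cohort.csv --out bg/
emrgraph train --graph bg/ --epochs 15 --out model.npz
emrgraph predict --graph bg/ --model model.npz --out predictions.csv
emrgraph evaluate --scores run/scores.csv --out report/
emrgraph run --config pipeline.yaml
```

`pipeline.yaml` keys mirror `emrgraph.pipeline.PipelineConfig`
(`n_patients`, `seed`, `event_prevalence`, `epochs`, `batch_size`,
`learning_rate`, `train_fraction`, `num_samples`, `n_boot`, `rf_trees`,
`bipartite_mode`, `property_graph_max_patients`, `outdir`). A single
global seed fans out to per-stage seeds, and `manifest.json` records
SHA-256 hashes of every artifact so reruns are verifiable.

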