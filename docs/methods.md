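# Methods

This note documents the statistical machinery behind `sensbn`, the choices
made where the procedure is genuinely open, and what the shipped tests do and
do not demonstrate.

## Endpoint and class definitions

The target is the LLNA-derived potency on the molar log scale,
`pEC3 = log10(Mw / 250 / EC3%)`, so larger pEC3 means more potent. Four
classes are cut at −1.9 / −1.1 / −0.35. The literature writes these as open
intervals without assigning the edges; we use left-closed/right-open
intervals with *strong* closed at −0.35 (deterministic, and edge values are
measure-zero in practice). For comparison with human potency gradings the
four classes collapse to three: *strong* stays, *moderate* and *weak* merge
into *weak*, *non* stays.

The fraction ionised is `|1 − 10^logD / 10^logKow|`. When logD > logKow this
exceeds 1; we record it unclamped and let discretisation absorb it. Whenever
both logD and logKow are present the stored `f_ion` column is recomputed from
them, so the value can never drift from its defining formula.

## Discretisation (CAIM)

Continuous inputs become discrete network states via greedy CAIM: candidate
boundaries are midpoints between consecutive distinct sorted training
values; boundaries are added one at a time maximising
`(1/n_intervals) · Σ_r max_c(n_rc)² / n_r`, with ties broken toward the
smallest boundary. Two stopping modes exist:

* default: force exactly four bins when enough distinct values exist — every
  discretised node then has a fixed cardinality of 4, matching how the
  networks are parameterised;
* `force_max_bins=False`: stop as soon as adding a boundary no longer
  increases the criterion. This mode is the one whose criterion value stays
  within 5% of exhaustive search on small instances (forcing a fourth
  interval can *lower* the criterion, because the criterion averages over
  intervals).

Schemes are fitted on training rows only, frozen, and applied to test /
external rows. A column with fewer than two distinct observed training
values cannot be discretised; its node is dropped from the network for that
fit (logged), which is also how an all-missing assay column degrades
gracefully.

## Latent nodes (latent class analysis)

Each latent node summarises one indicator group as a polytomous mixture:
class weights plus per-class, per-variable item-response tables, fitted by
EM under missing-at-random. Numerical choices: uniform initial weights,
item-response rows drawn from a flat Dirichlet; convergence at log-likelihood
gain < 1e-8 or 1000 iterations; a ridge of 1e-6 per cell in each M-step
prevents zero-probability lock-in; restart *r* of `n_rep` is seeded
`seed + r`, the best converged log-likelihood wins. The LCA is unsupervised —
the potency label is never among the indicators. Training rows receive their
modal latent class as an observed value; at prediction time the latent nodes
are left unobserved and inferred by the network. Label switching is handled
in validation by comparing partitions (adjusted Rand), never raw labels.

## Network structures and parameter learning

The bundled structures are top-down diagnostic networks: the potency class
is the root, parenting the latent nodes and the in silico node; each latent
node parents its indicators. This keeps every conditional table small (at
most 5 parent configurations), which matters with ~150 training compounds.
The adjacency ships as editable JSON (`sensbn/structures/*.json`) so
alternative wirings can be tried without code changes. The kDPRA nodes
(KMAX, KDPRA_CLASS) attach to CYSTEINE exactly like the DPRA cysteine
depletion; an ablation flag strips them to quantify their contribution.

CPTs are Dirichlet posterior means with a single per-state `pseudo_count`
(default 1, the K2 convention; 5 is the other published setting). Counting is
available-case per family: a row contributes to a node's table iff the node
and all its parents are observed in that row, so incomplete rows still
inform the families they cover. A never-observed parent configuration falls
back to the uniform distribution implied by the prior. We deliberately do
not run EM over missing *input* values: available-case counting keeps
learning deterministic and order-independent.

Inference is exact variable elimination (greedy smallest-product-factor
order), verified against brute-force joint enumeration on random small
networks to 1e-10.

## Prediction outputs

The training class distribution (smoothed by +1 per class so no class has
zero prior) is the reference for one-vs-rest Bayes factors; the largest BF
picks the class, with ties broken toward the more potent class
(conservative for safety assessment). Confidence bands are 3.2 / 10 / 32,
with BF = 32 assigned to *very strong* (the printed bands leave exactly 32
unassigned).

For the continuous pEC3, class posteriors spread uniformly over their pEC3
intervals; the outer intervals are closed with the training set's observed
pEC3 minimum/maximum (never narrower than −3.5 / 1.0). The q-th percentile
leaves upper-tail mass `1 − q/100` above the returned value, so the
percentile is monotone increasing in q and higher percentiles give more
potent, more conservative estimates; on a flat CDF region the potent edge is
returned. The 50th percentile is the central estimate; 70th/90th are
reporting options for conservative risk assessment.

## Evaluation protocols

Balanced accuracy is the mean per-class recall (scikit-learn's
`balanced_accuracy_score`), reported in percent. Confidence-stratified
tables use plain accuracy within each band. Cross-validation draws a seeded
uniform permutation chunked into k near-equal folds (unstratified, matching
a plain random split; a stratified option exists) and refits the *entire*
pipeline — schemes, LCA, CPTs — per fold. Grid search scans 3–5 classes per
latent node, 10/20/50 LCA restarts and pseudo-count 1 or 5 exhaustively,
maximising test balanced accuracy, ties toward fewer parameters. Whether the
original grid varied the pseudo-count is ambiguous in the literature; we
include it. External evaluation excludes rows without a SMILES or molecular
weight up-front (no molar conversion is possible) and counts them; the
human endpoint maps predicted 4-class labels through the 4→3 collapse before
scoring.

## Synthetic study conditions

The generator's defaults define the package's standard test conditions and
are deliberately not tuned per experiment: class mixture
(0.25, 0.30, 0.25, 0.20) over non/weak/moderate/strong (sensitiser-rich, as
curated potency datasets are); true pEC3 uniform within its class interval
with outer bounds −3.5 / 1.0; Mw log-uniform in [100, 500] g/mol with EC3%
back-derived so the pEC3 formula round-trips exactly. Assay links are simple
monotone functions of pEC3 on log/logit scales (depletions and Kmax
increase, effective concentrations decrease) with noise sd 0.4 and a shared
within-group factor (sd 0.3) so the latent-class stage has real structure to
find; the physico-chemical block is driven by an independent lipophilicity
latent and carries essentially no potency signal, as in real panels. The
kDPRA GHS call is thresholded at log10 Kmax ≥ −2 (the generator's own rule;
for real data the call is always consumed as a supplied column, since no
threshold is derived in-package). In silico calls are drawn from moderately
informative per-class confusion rows (diagonals ~0.55–0.8). Missingness is
per-column (2–15%, 30% for kDPRA, reflecting its sparser coverage).
`noiseless=True` zeroes noise, missingness and confusion, producing a
class-separable dataset on which the full pipeline must reach ≥ 95% balanced
accuracy — the end-to-end correctness check.

What passing on synthetic data shows: the pipeline recovers structure it is
designed for, every stage composes correctly, and confidence stratification
behaves (weak-confidence predictions are genuinely less accurate than
very-strong ones on every seed tested). What it does not show: accuracy on
real compounds. The generator's links are cleaner and more informative than
real assay–potency relationships, so synthetic accuracies (high 70s–80s
balanced accuracy) sit well above what heterogeneous real panels support;
reproducing published real-data figures requires the corresponding
compound-level tables transcribed into the CSV schema (see
`tests/test_acceptance.py`).

The acceptance script runs the study at sample sizes 147 (train), 60 (test)
and 128 (external, 6 structureless) — the sizes of the published split and
evaluation set — which a single CPU handles in minutes.

## Known limitations

* Compounds with continuous inputs near a discretisation cut can flip bins
  under small perturbations; inspect such cases, e.g. by re-predicting with
  slightly varied inputs.
* No molar conversion is possible without a defined structure and molecular
  weight; such compounds are excluded from evaluation rather than predicted.
* Latent assignments are hard (modal) at training time; soft assignment or
  structural EM might use the data slightly better at the cost of
  determinism.
* The Bayes-factor form (one-vs-rest posterior odds over prior odds) is the
  standard reading of the bias correction used in this model family; it is
  isolated behind a single function should another convention be needed.
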