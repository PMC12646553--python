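# Methods

## Problem setting

`csrec` recommends antihypertensive medications from longitudinal EHR
visit sequences.  A patient is an ordered list of visits; each visit
carries a set of diagnosis codes, a set of procedure codes, and the set of
medications prescribed at that visit.  For the t-th visit the model sees
the current diagnoses and procedures, the full visit history, and the
medications of visits 1..t−1, and emits a probability for every medication
in the vocabulary.  Medications whose probability exceeds a threshold
(default 0.5, strict inequality) form the recommended set.  The task is
multilabel classification; training minimises the binary cross-entropy
summed over visits and medications.

## Model

### Graph construction

Per prediction step the package builds:

* **A_mm** — symmetric medication co-occurrence counts: entry (i, j) is
  the number of historical visits in which medications i and j were
  co-prescribed.  By default the history is the *patient's own* previous
  visits (`cooccurrence_scope="patient"`); a cohort-global variant is
  available since the literature uses both conventions.
* **A_ddi** — binary symmetric contraindication matrix from a supplied
  pair list (the package never derives interactions itself).
* **G = clip(A_mm − λ·A_ddi, 0)** — the combined medication graph.  λ ≥ 0
  (default 1.0) trades collaboration signal against safety; negative
  entries are clipped to zero and the edge removed, because a negative
  edge weight has no interpretation in the attention layer that consumes
  the graph.
* Three complete bipartite graphs per visit: diagnosis–procedure within
  the visit, and previous-visit-medication–diagnosis /
  previous-visit-medication–procedure across visits.

### Neighbor-focused multi-head graph attention

Attention logits are LeakyReLU(a·[W h_i ∥ W h_j]) (negative slope 0.2),
normalised with a softmax over the neighborhood.  Unlike the standard
formulation the node's own feature is **excluded** from the aggregation:
the update for node i is an attention-weighted sum of *neighbor* values
only, so a diagnosis node is rebuilt from the procedures and medications
it co-occurs with.  The conventional self-inclusive neighborhood is
available behind `include_self=True` for comparison.  Nodes with no
neighbors (isolated medications, visits without procedures) keep their
linearly mapped feature unactivated.  Each of H heads (default 3) maps
into a subspace of dimension round(d/H); head outputs are concatenated,
so the effective model width is H·round(d/H) everywhere (embedding
tables included).  The aggregation nonlinearity is ELU (configurable);
the attention logits can optionally be multiplied by the combined-graph
edge weights (`use_edge_weight_prior`), which is off by default since the
attention is defined on node features alone.

Propagation runs in three ordered stages per prediction step: (1)
medication nodes over G; (2) diagnosis and procedure nodes over the
within-visit bipartite graph; (3) cross-updates over the
medication–diagnosis and medication–procedure graphs using the stage-1/2
outputs.  Stage 3 updates all three entity types; when a medication node
receives updates from both the diagnosis and the procedure side, the two
are averaged.  A GCN path (symmetric-degree-normalised convolution with
self-loops) replaces attention in the `GAT_GCN` ablation.

### Bidirectional temporal selection

Per entity type, per-visit node sets are mean-pooled to one vector per
visit.  A forward GRU over the visit sequence yields states g_j and
forward coefficients α_j = tanh(W_α g_j + b_α); a backward GRU over the
reversed sequence yields states h_j and backward coefficients
β_j = tanhshrink(W_β h_j + b_β), with tanhshrink(x) = x − tanh(x).  The
aggregated representation is Σ_j (α_j ⊙ β_j) ⊙ V_j.  Diagnoses,
procedures and medications use separate GRU/head parameters by default
(`share_temporal_weights` exists).  The medication sequence covers visits
1..t−1; with no history the medication representation is the zero vector.

Both coefficient nonlinearities are flat or annihilating at the origin —
tanhshrink has zero derivative at 0, and the α⊙β product kills the
gradient of either factor when the other is near zero.  With zero-centred
initialisation this freezes the whole selection path for many epochs.  The
coefficient-head biases are therefore initialised positive (b_α = 2,
b_β = 1), so training starts from an open-gate state (α ≈ 0.96,
β ≈ 0.24) in which the model behaves like a plain sum over the visit
history and then learns selectivity.  A `backward_nonlinearity="tanh"`
switch replaces tanhshrink for comparison.

### Prediction head and training

The three aggregated vectors are concatenated and mapped by a single
linear layer (3d → |M|) followed by a sigmoid; the published formulation
omits the dimension-matching map, which cannot be avoided, so one
learnable layer is the minimal completion.  Training uses Adam
(lr 1e-3 default, classic coupled L2 via `weight_decay`), one patient per
optimisation step (visit sequences are ragged), a training example per
visit, early stopping on validation Jaccard with parameter restore, and a
divergence abort on non-finite loss.  Everything is implemented over a
small reverse-mode autodiff engine on NumPy arrays (`csrec.autodiff`);
gradients are validated against central finite differences in the test
suite.  All randomness flows from explicit integer seeds; runs are
bit-reproducible single-threaded.

The embedding dimension, learning rate, batch discipline and patience are
not reported in the source formulation; the defaults above are standard
choices for this model family and are all exposed in `ModelConfig`.

## Evaluation metrics

Per-visit, macro-averaged over all visits of the evaluated patients:
Jaccard |y∩ŷ|/|y∪ŷ| (both-empty := 1), step-integrated PRAUC
(average-precision over the medication ranking, ties broken by ascending
index; visits with empty truth excluded), F1 with 0/0 := 0, and the DDI
rate — the fraction of unordered recommended pairs flagged in A_ddi,
with |ŷ| < 2 contributing 0.  Each metric has an independent brute-force
oracle in the test suite.

## Synthetic cohorts

Real extracts of this kind require credentialed access, so the package
ships a generator whose defaults emulate the visit-level shape of the two
ICU cohorts this model family is evaluated on: profile `mimic4_like`
(mean visits 2.8169, mean diagnoses 9.3666, mean procedures 2.5492) and
`mimic3_like` (2.3460 / 10.8927 / 4.0463), with desk-scale vocabularies
(|D| = 200, |P| = 100, |M| = 18).  Mechanisms:

* visits per patient ~ 2 + Poisson(mean_visits − 2) — every patient
  clears the ≥2-visit filter and the realized mean matches the target
  exactly in expectation;
* diagnoses per visit ~ max(1, Poisson(mean_diag)), composed of
  previous-visit codes that persist with probability 0.5 plus fresh
  uniform draws (chronic-code carry-over);
* procedures ~ Poisson(mean_proc), uniform;
* medications from planted rules: 12 chronic rules (once diagnosis d has
  ever appeared, medication m fires with probability 0.9 at every
  subsequent visit) and 4 escalation rules (d must have appeared in ≥2
  distinct visits — these medications are predictable only from the visit
  history, which is what gives the temporal-selection mechanism a genuine
  target); two 3-medication co-prescription clusters (co-members join
  with probability 0.5) each containing one planted contraindicated pair,
  so co-occurrence pressure and safety pressure compete; and Bernoulli
  noise at rate 0.01 per medication.

What the generator does **not** emulate: real code semantics and
ontologies, visit time stamps, demographic or laboratory covariates,
medication dosages, and the long-tailed code frequencies of real EHR
data.  Passing tests therefore demonstrate that the implementation is
correct and that the architecture can recover planted longitudinal
prescription structure at desk scale — not clinical performance.

## Numerical and protocol choices

* Attention softmax subtracts the row maximum before exponentiation.
* Probabilities are clipped to [1e-7, 1 − 1e-7] inside the loss.
* PRAUC tie-break: ascending medication index (deterministic).
* The medication-frequency filter runs before the ≥2-visit filter, making
  `filter_cohort` idempotent; the split is patient-level at 23:16:16 with
  the remainder assigned to training.
* Ablation semantics: WO_S replaces the selective sum with the last
  visit's pooled representation; WO_C bypasses all graph attention (raw
  pooled embeddings); WO_DM / WO_PM / WO_DP drop one bipartite graph;
  WO_MM drops both medication graphs from the model while the DDI metric
  still uses A_ddi; GAT_GCN swaps attention for graph convolution.
* Directional experiment checks (ablation ordering, λ→DDI monotonicity,
  head-count stability) run on cohorts of 200 patients with a 16-wide
  model, 14-epoch budget and patience 6 over 5 seeds; the learning check
  against the frequency baseline uses 2000 patients.  These sizes keep
  each check to a few minutes of one CPU while leaving the planted
  structure comfortably recoverable.

## Known limitations

* The neighbor-only attention discards a node's own content in the value
  sum; identity information survives only through attention logits and
  the isolated-node bypass.  This is faithful to the formulation it
  implements, but it measurably weakens the current-visit diagnosis
  signal relative to a self-inclusive GAT.
* Per-patient co-occurrence graphs are rebuilt per prediction step
  (O(T²) per patient); fine at desk scale, not tuned for large cohorts.
* The pure-NumPy engine favours exactness and inspectability over speed;
  throughput is roughly 25 patients/second/epoch for the 16-wide model.
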