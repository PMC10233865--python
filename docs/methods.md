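# Methods

## The network model

The object of study is an undirected simple graph whose nodes are
chemicals and protein targets and whose edges carry a layer label:

* **CTC** (chemical–target): direct activity evidence. These are the edges
  the analysis ultimately predicts.
* **CCC** (chemical–chemical): fingerprint Tanimoto similarity
  `|A∩B|/|A∪B| ≥ t`, default `t = 0.6`. Fingerprints enter as precomputed
  set-bit vectors, keeping the graph pipeline independent of any specific
  chemistry toolkit; an optional rdkit helper hashes SMILES into atom-pair
  bitsets.
* **PPI** (target–target): interaction confidence `≥ 0.9` on a [0, 1]
  scale. Symmetric duplicates merge keeping the maximum score; self-pairs
  are dropped.

All layers are treated as unweighted by the predictors; scores are kept as
edge metadata only. Layer role-typing is enforced at construction: a CTC
edge must join a chemical to a target, CCC chemical–chemical, PPI
target–target. The graph is simple: canonical (sorted) endpoint pairs
deduplicate symmetric inputs deterministically.

Chemicals carry origin tags from {DS, CX, drug}; a chemical found in both
herbs carries both herb tags. Targets inherit the union of the tags of
chemicals that bind them. A node enters an analysis group (DS-drug,
CX-drug, DS-CX-drug) iff its origin intersects the group's tags; targets
also enter through an incident CTC edge to a selected chemical. Isolated
nodes are retained in the graph (walk starts skip them); no silent
pruning.

## Link predictors

Three neighborhood indices score a pair directly from the training graph:
Adamic-Adar `Σ_{Z∈N(A)∩N(B)} 1/log|N(Z)|` (natural log — the base only
rescales scores and the evaluation metrics are rank-based), Jaccard
`|N(A)∩N(B)|/|N(A)∪N(B)|` with the 0/0 → 0 convention, and preferential
attachment `|N(A)|·|N(B)|`.

node2vec samples second-order biased walks: after stepping t → v, the next
node x has unnormalized weight 1/p if x = t, 1 if x is adjacent to t, and
1/q otherwise, normalized over N(v). Walks (default 10 per node, length
80) feed a skip-gram-with-negative-sampling trainer (built-in, vectorized
numpy: unigram^0.75 negative table, 5 negatives, linearly decaying
learning rate from 0.025, one epoch by default — the original node2vec
training settings; dims 128, window 10). Edge features are Hadamard
products of endpoint vectors by default (average, |Δ| and Δ² are
available), classified by logistic regression with feature
standardization. The spectral predictor replaces the embedding source
with the k = 16 eigenvectors of the symmetric normalized Laplacian with
smallest eigenvalues (dense eigendecomposition; eigenvector signs fixed by
making the largest-magnitude entry positive), using the same logistic
head so the comparison isolates the embedding. Walks and the Laplacian are
taken on the merged graph ignoring layer labels.

The raw indices suffice for AUROC/AP. Where probabilities are required
(the ≥ 0.5 prediction-value filter) an index passes through a one-feature
logistic calibration fitted on labeled training pairs, so "prediction
value" means the same thing for every algorithm.

## Evaluation protocol

"Tenfold cross validation" of a 6:3:1 split cannot be a classical 10-fold
partition; the protocol here is ten independently reseeded 6:3:1
resampling rounds, which preserves both stated facts. Per round: edges are
partitioned 6:3:1 by largest-remainder apportionment (exact when the
fractions divide the edge count); negatives are sampled uniformly from
non-edges of the full graph, 1:1 with positives, disjoint across
partitions (an option restricts the negative universe to chemical–target
pairs); the training graph keeps all nodes but only train edges; the model
is fitted on labeled train pairs and scored on test pairs. The validation
partition is reserved for hyperparameter selection (p, q, edge operator)
and never refits the final classifier. Positives whose endpoints are both
isolated in the training graph trigger a warning and receive
uninformative scores rather than an error.

AUROC is the ties-half Mann–Whitney probability that a random positive
outranks a random negative; AP is the step-sum Σ(Rₙ−Rₙ₋₁)Pₙ over the
descending-score threshold sweep. Both are computed via scikit-learn,
which implements exactly these definitions; the test suite checks them
against independent brute-force pair-counting and sweep oracles. Master
seeds fan out to per-round seeds through `numpy.random.SeedSequence`
(values kept below 2³¹), and the whole pipeline is byte-reproducible
single-threaded.

## Expansion accounting

For extraction the selected model is refitted on 100% of the dataset
graph (a CV fold's model would waste a tenth of the evidence; the choice
is deliberate and recorded here). All chemical–target non-edges within
the group's node set are scored and pairs with prediction value ≥ 0.5
retained; an unrestricted variant counts retained non-edges of any type
for the total-edges row. Records are filtered to herbal chemical →
drug-target pairs. Expansion percentage = round(100 × expanded/original,
2) per category (total edges, herbal-chemical–drug-target edges, total
chemical nodes, herbal chemical nodes); a zero original count is an
error, not a 0. The published study's downstream manual filters (drug
indication review, bioassay literature, PDB availability) are external
curation calls and are out of scope; a user-supplied keep-list can stand
in for them.

## Synthetic generator

A planted-block model supplies test data with the statistical structure
the analysis assumes: chemicals and targets are assigned uniformly to
`n_blocks = 8` latent communities; CTC edges are Bernoulli(0.08) within a
block and Bernoulli(0.002) across (≈ 4.7k expected edges at the default
400 × 1000 scale); each block owns 40 random signature bits of a 256-bit
fingerprint and a chemical's fingerprint is its block signature with 5%
per-bit flip noise, so Tanimoto ≥ 0.6 edges concentrate within blocks;
PPI scores are clipped Normal(0.92, 0.05) for within-block target pairs
and Normal(0.40, 0.05) for an equal number of sampled between-block pairs
(scoring *all* pairs would let PPI swamp the network), so the 0.9 cut
keeps almost only intra-block pairs. 10% of chemicals are herbal (DS or
CX, a few both), the rest drug chemicals. A `TINY_PROFILE`
(40 chemicals × 100 targets, 4 blocks, rates 0.30/0.02 → ≈ 350 CTC edges)
keeps tests fast; the higher rates are needed because the full-scale
rates would leave a 40 × 100 network nearly edgeless.

What the generator does *not* emulate: real chemistry (no valid SMILES),
scale-free PPI topology, herb-specific pharmacology, or the degree
heterogeneity of curated databases. A green test on synthetic data
therefore establishes that the pipeline recovers planted structure under
its own assumptions — not that any particular published metric value is
reproduced; the curated network behind those values is not deposited.

## Numerical choices and edge cases

* Tanimoto of two empty fingerprints is an error; empty fingerprints are
  flagged on construction and skipped (with a warning) in CCC building.
* AA cannot divide by log 1: a common neighbor has degree ≥ 2.
* AUROC ties count ½; AP ties are grouped per distinct threshold with a
  stable descending sort — both deterministic.
* Logistic heads standardize features first (spectral eigenvector entries
  are O(n^-1/2) and stall the solver unscaled) and cap iterations at 2000.
* Nodes without embeddings (isolated in a training graph) get zero feature
  vectors with a warning.
* Expected-edge-count sanity check: a generator config whose expected CTC
  count is below 10 is rejected.

## Known limitations

* The skip-gram trainer is minibatch SGD with exact scatter-adds: slower
  than hogwild C implementations, but deterministic; full-scale graphs
  (~1.5k nodes) train in minutes, not seconds.
* AA and Jaccard are degenerate on a strictly bipartite CTC-only graph
  (chemicals and targets share no neighbors), scoring every candidate 0.
  This is intrinsic to the indices, and is precisely the argument for the
  similarity layers.
* Statistical comparison between algorithms (significance tests,
  precision@k, calibration curves) is out of scope.
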