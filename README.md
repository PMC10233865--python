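# herblink

Link prediction on layered chemical–target networks, for expanding the
known protein targets of herbal chemicals from herb–drug interaction
context. The motivating use case is traditional-medicine pharmacology:
compounds from *Salvia miltiorrhiza* (Danshen, DS) and *Ligusticum
chuanxiong* (Chuanxiong, CX) share a pharmacological context with approved
cardiovascular drugs, and edges predicted between herbal chemicals and
drug targets are candidate interactions worth experimental follow-up.

## The model

The data form an undirected heterogeneous graph with two node roles
(chemical, target) and three evidence layers:

* **CTC** — chemical–target activity edges from curated bioassay records;
* **CCC** — chemical–chemical edges where fingerprint Tanimoto similarity
  `|A∩B| / |A∪B| ≥ 0.6`;
* **PPI** — target–target edges with interaction confidence `≥ 0.9`
  (STRING-style scores).

Datasets are assembled per analysis group (DS-drug, CX-drug, DS-CX-drug)
in three increasing layer sets: `{CTC}`, `{CTC, CCC}`, `{CTC, CCC, PPI}`.
Five link-prediction algorithms are benchmarked on each dataset:

| algorithm | score for a pair (A, B) |
|-----------|--------------------------|
| node2vec  | logistic regression on Hadamard products of skip-gram embeddings of p/q-biased random walks |
| Adamic-Adar (AA) | Σ<sub>Z∈N(A)∩N(B)</sub> 1 / log\|N(Z)\| |
| Jaccard (JS) | \|N(A)∩N(B)\| / \|N(A)∪N(B)\| |
| preferential attachment (PA) | \|N(A)\| × \|N(B)\| |
| spectral (SC) | same logistic head over eigenvectors of the symmetric normalized Laplacian |

Evaluation holds out edges in ten independently reseeded 6:3:1
train/validation/test splits, samples 1:1 negative non-edges, and reports
mean AUROC and average precision (AP = Σ(Rₙ−Rₙ₋₁)Pₙ). After model
selection the chosen predictor is refitted on the full graph, every
chemical–target non-edge is scored, pairs with prediction value ≥ 0.5 are
retained, filtered to herbal-chemical → drug-target pairs, and summarized
as expansion percentages (new items / original items × 100).

Because no curated network is publicly deposited, the package ships a
seeded synthetic generator: a planted-block model in which chemicals and
targets share latent activity communities, fingerprints are noisy block
signatures, and PPI confidence is higher within blocks — exactly the
premise (structurally similar chemicals share targets; interacting
proteins share ligands) that makes the similarity layers informative.

## Worked example

```python
import herblink as hb

net = hb.generate(hb.TINY_PROFILE)          # ~40 chemicals, ~100 targets
layers = net.build_layers()                  # CTC / CCC (Tanimoto>=0.6) / PPI (>=0.9)
spec = hb.DatasetSpec("DS-CX-drug", frozenset({"CTC", "CCC", "PPI"}))
graph = hb.assemble_dataset(spec, layers, net.meta)

pred = hb.make_predictor("node2vec",
                         params=hb.Node2vecParams(dims=64, walk_length=40,
                                                  walks_per_node=5, window=5, epochs=2))
res = hb.cross_validate(graph, pred, hb.SplitSpec(folds=3, seed=1))
print(round(res.mean_auroc, 3), round(res.mean_ap, 3))
```

prints `0.926 0.905` (seed 1): on the full-layer synthetic network
node2vec ranks held-out edges above sampled non-edges with mean AUROC
0.926 across three resampling rounds. The same call on the CTC-only
dataset gives 0.580 — the similarity layers carry most of the signal,
which is the layering effect the analysis is designed to show. The same
pipeline is scriptable from the shell:

```sh
herblink simulate --outdir data --seed 1
herblink evaluate --config config.yaml --outdir results --seed 1
herblink predict  --config config.yaml --outdir results --seed 1
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch at the tiny synthetic profile:
network generation, dataset assembly for the CTC-only and full-layer
sets, cross-validation of all five algorithms on both, and full-graph
expansion reporting with the 0.5 prediction-value filter, printing each
stage's metrics along the way.
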