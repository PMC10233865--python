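"""Link-prediction models: node2vec, three neighborhood indices, spectral.

Each algorithm is a model class whose ``fit(graph, ...)`` returns a fitted
results object exposing ``scores(pairs)`` (raw index values or classifier
probabilities) and ``predict_proba(pairs)`` (always calibrated to [0, 1]).

* Adamic-Adar:             AA(A,B)  = sum_{Z in N(A) ∩ N(B)} 1 / log|N(Z)|
* Jaccard:                 JS(A,B)  = |N(A) ∩ N(B)| / |N(A) ∪ N(B)|
* Preferential attachment: PA(A,B)  = |N(A)| x |N(B)|
* node2vec:                biased walks -> skip-gram embedding -> logistic
                           regression on Hadamard edge features
* Spectral (SC):           eigenvectors of the symmetric normalized
                           Laplacian as node features, same logistic head

The natural logarithm is used in AA (the base only rescales scores, and the
ranking metrics are scale-invariant). The raw indices suffice for AUROC/AP;
when probabilities are needed (the prediction-value >= 0.5 filter) the
scalar index passes through a one-feature logistic calibration fitted on
labeled training pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, LookupError_
from .sgns import train_sgns
from .walks import biased_walks

logger = logging.getLogger(__name__)

ALGORITHMS = ("node2vec", "AA", "JS", "PA", "SC")

EDGE_OPERATORS = ("hadamard", "average", "l1", "l2")


# -- neighborhood indices ----------------------------------------------------


def aa_index(graph, u: str, v: str) -> float:
    """Adamic-Adar: common neighbors weighted by 1/log(degree)."""
    common = graph.neighbors(u) & graph.neighbors(v)
    # a common neighbor is adjacent to both u and v, hence degree >= 2
    return sum(1.0 / math.log(graph.degree(z)) for z in common)


def jaccard_index(graph, u: str, v: str) -> float:
    """Jaccard coefficient of the neighbor sets; 0/0 -> 0 by convention."""
    nu, nv = graph.neighbors(u), graph.neighbors(v)
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def pa_index(graph, u: str, v: str) -> float:
    """Preferential attachment: product of degrees."""
    return float(graph.degree(u) * graph.degree(v))


_INDEX_FN = {"AA": aa_index, "JS": jaccard_index, "PA": pa_index}


def _logistic_head(seed):
    """Standardized logistic regression; scaling keeps the solver stable on
    the tiny-magnitude features of spectral eigenvectors."""
    return make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
    )


# -- parameters --------------------------------------------------------------


@dataclass(frozen=True)
class Node2vecParams:
    """Walk and training hyperparameters (original node2vec defaults)."""

    p: float = 1.0
    q: float = 1.0
    dims: int = 128
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ConfigError("node2vec p and q must be positive")
        for name in ("dims", "walk_length", "walks_per_node", "window", "epochs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"node2vec {name} must be a positive integer")


@dataclass(frozen=True)
class SpectralParams:
    """Number of Laplacian eigenvectors used as node features."""

    k: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("spectral k must be a positive integer")


@dataclass
class EmbeddingMatrix:
    """Per-node real vectors with an ordered id list."""

    node_ids: List[str]
    vectors: np.ndarray
    _index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.node_ids) != len(self.vectors):
            raise ValueError("node_ids and vectors length mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dims(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node_id) -> bool:
        return node_id in self._index

    def lookup(self, node_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node_id]]
        except KeyError:
            raise LookupError_(f"no embedding for node {node_id!r}") from None


def edge_features(
    emb: EmbeddingMatrix,
    pairs: Sequence[Tuple[str, str]],
    operator: str = "hadamard",
    missing: str = "error",
) -> np.ndarray:
    """Combine endpoint embeddings into one vector per candidate edge.

    ``missing="zero"`` substitutes a zero vector for nodes absent from the
    embedding (isolated in the training graph) with a warning instead of
    raising; their features carry no information, which is the honest
    statement about such nodes.
    """
    if operator not in EDGE_OPERATORS:
        raise ConfigError(f"unknown edge operator {operator!r}; valid: {EDGE_OPERATORS}")
    zero = np.zeros(emb.dims)
    n_missing = 0

    def vec(n):
        nonlocal n_missing
        if n in emb:
            return emb.lookup(n)
        if missing == "zero":
            n_missing += 1
            return zero
        return emb.lookup(n)  # raises with the node name

    X = np.empty((len(pairs), emb.dims))
    for i, (u, v) in enumerate(pairs):
        a, b = vec(u), vec(v)
        if operator == "hadamard":
            X[i] = a * b
        elif operator == "average":
            X[i] = (a + b) / 2.0
        elif operator == "l1":
            X[i] = np.abs(a - b)
        else:  # l2
            X[i] = (a - b) ** 2
    if n_missing:
        warnings.warn(f"{n_missing} endpoints had no embedding; zero features used")
    return X


def spectral_embed(graph, params: SpectralParams) -> EmbeddingMatrix:
    """Rows of the k lowest eigenvectors of the symmetric normalized Laplacian.

    Isolated nodes (degree 0) are excluded, matching the embedding contract
    of the walk-based route. On a disconnected graph the zero eigenvalue has
    multiplicity equal to the number of components; this is allowed and
    logged.
    """
    import networkx as nx

    nodes = sorted(n for n in graph.node_ids if graph.degree(n) > 0)
    n = len(nodes)
    if params.k >= n:
        raise ConfigError(f"spectral k={params.k} must be < number of embedded nodes {n}")
    L = nx.normalized_laplacian_matrix(graph.g.subgraph(nodes), nodelist=nodes)
    evals, evecs = np.linalg.eigh(L.toarray())
    k = params.k
    n_zero = int(np.sum(evals < 1e-8))
    if n_zero > 1:
        logger.info("normalized Laplacian has %d (near-)zero eigenvalues", n_zero)
    V = evecs[:, :k].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return EmbeddingMatrix(nodes, V)


def train_embeddings(walks, params: Node2vecParams) -> EmbeddingMatrix:
    """Skip-gram-with-negative-sampling embedding of a walk corpus."""
    vocab, W = train_sgns(
        walks,
        dims=params.dims,
        window=params.window,
        epochs=params.epochs,
        seed=params.seed,
    )
    return EmbeddingMatrix(vocab, W)


# -- model / results classes -------------------------------------------------


def _sample_negative_pairs(graph, n: int, rng: np.random.Generator) -> list:
    """Uniform non-edges of the graph (any node-role pair)."""
    nodes = sorted(graph.node_ids)
    out, seen = [], set()
    max_tries = 100 * n + 1000
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        i, j = rng.integers(len(nodes), size=2)
        if i == j:
            continue
        u, v = nodes[i], nodes[j]
        key = (u, v) if u <= v else (v, u)
        if key in seen or graph.has_edge(u, v):
            continue
        seen.add(key)
        out.append(key)
    return out


class FittedLinkPredictor:
    """Results object: scores for candidate pairs from one fitted model."""

    def __init__(self, model, graph, raw_fn, proba_fn=None):
        self.model = model
        self.graph = graph
        self._raw = raw_fn
        self._proba = proba_fn

    @property
    def algorithm(self) -> str:
        return self.model.name

    def scores(self, pairs) -> np.ndarray:
        self._check(pairs)
        return self._raw(pairs)

    def predict_proba(self, pairs) -> np.ndarray:
        self._check(pairs)
        if self._proba is None:
            raise ConfigError(
                f"{self.algorithm}: no probability calibration was fitted "
                "(fit with labeled training pairs)"
            )
        return self._proba(pairs)

    def _check(self, pairs):
        for u, v in pairs:
            if u not in self.graph.meta or v not in self.graph.meta:
                raise LookupError_(f"pair endpoint outside graph: ({u!r}, {v!r})")

    def summary(self) -> str:
        lines = [
            f"Fitted link predictor: {self.algorithm}",
            f"  training graph: {self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges",
            f"  probability calibration: {'yes' if self._proba else 'no'}",
        ]
        return "\n".join(lines)


class LinkPredictor:
    """Base model; subclasses implement ``fit``."""

    name: str

    def fit(self, graph, train_pairs=None, train_labels=None, seed: int = 0):
        raise NotImplementedError

    @staticmethod
    def _auto_training_set(graph, seed):
        """Positives = all edges; negatives = equally many sampled non-edges."""
        rng = np.random.default_rng(seed)
        pos = sorted(e.key for e in graph.edges())
        neg = _sample_negative_pairs(graph, len(pos), rng)
        pairs = pos + neg
        labels = np.array([1] * len(pos) + [0] * len(neg))
        return pairs, labels


class _IndexPredictor(LinkPredictor):
    """Neighborhood index scored on the training graph; optional logistic
    calibration of the scalar index into a probability."""

    def fit(self, graph, train_pairs=None, train_labels=None, seed: int = 0):
        fn = _INDEX_FN[self.name]

        def raw(pairs):
            return np.array([fn(graph, u, v) for u, v in pairs])

        proba = None
        if train_pairs is None and train_labels is None:
            train_pairs, train_labels = self._auto_training_set(graph, seed)
        if train_pairs is not None:
            x = raw(train_pairs).reshape(-1, 1)
            clf = _logistic_head(seed)
            clf.fit(x, np.asarray(train_labels))
            proba = lambda pairs: clf.predict_proba(raw(pairs).reshape(-1, 1))[:, 1]
        return FittedLinkPredictor(self, graph, raw, proba)


class AdamicAdarPredictor(_IndexPredictor):
    name = "AA"


class JaccardPredictor(_IndexPredictor):
    name = "JS"


class PreferentialAttachmentPredictor(_IndexPredictor):
    name = "PA"


class _EmbeddingPredictor(LinkPredictor):
    """Embedding + logistic regression on edge features; the classifier
    probability is both the score and the prediction value."""

    operator = "hadamard"

    def _embed(self, graph, seed) -> EmbeddingMatrix:
        raise NotImplementedError

    def fit(self, graph, train_pairs=None, train_labels=None, seed: int = 0):
        emb = self._embed(graph, seed)
        if train_pairs is None:
            train_pairs, train_labels = self._auto_training_set(graph, seed)
        X = edge_features(emb, train_pairs, self.operator, missing="zero")
        clf = _logistic_head(seed)
        clf.fit(X, np.asarray(train_labels))

        def proba(pairs):
            F = edge_features(emb, pairs, self.operator, missing="zero")
            return clf.predict_proba(F)[:, 1]

        fitted = FittedLinkPredictor(self, graph, proba, proba)
        fitted.embedding = emb
        fitted.classifier = clf
        return fitted


class Node2vecPredictor(_EmbeddingPredictor):
    name = "node2vec"

    def __init__(self, params: Node2vecParams = Node2vecParams(), operator: str = "hadamard"):
        if operator not in EDGE_OPERATORS:
            raise ConfigError(f"unknown edge operator {operator!r}")
        self.params = params
        self.operator = operator

    def _embed(self, graph, seed):
        params = replace(self.params, seed=seed)
        walks = biased_walks(graph, params)
        return train_embeddings(walks, params)


class SpectralPredictor(_EmbeddingPredictor):
    name = "SC"

    def __init__(self, params: SpectralParams = SpectralParams(), operator: str = "hadamard"):
        if operator not in EDGE_OPERATORS:
            raise ConfigError(f"unknown edge operator {operator!r}")
        self.params = params
        self.operator = operator

    def _embed(self, graph, seed):
        return spectral_embed(graph, self.params)


class RandomPredictor(LinkPredictor):
    """Seeded random scores; the null control for metric calibration."""

    name = "random"

    def fit(self, graph, train_pairs=None, train_labels=None, seed: int = 0):
        def raw(pairs):
            return np.random.default_rng(seed).random(len(pairs))

        return FittedLinkPredictor(self, graph, raw, raw)


def make_predictor(name: str, **kwargs) -> LinkPredictor:
    """Factory by algorithm name; raises ConfigError listing valid names."""
    if name == "node2vec":
        params = kwargs.pop("params", None) or Node2vecParams(**kwargs.pop("n2v", {}))
        return Node2vecPredictor(params, **kwargs)
    if name == "SC":
        params = kwargs.pop("params", None) or SpectralParams(**kwargs.pop("sc", {}))
        return SpectralPredictor(params, **kwargs)
    if name == "AA":
        return AdamicAdarPredictor()
    if name == "JS":
        return JaccardPredictor()
    if name == "PA":
        return PreferentialAttachmentPredictor()
    if name == "random":
        return RandomPredictor()
    raise ConfigError(f"unknown algorithm {name!r}; valid names: {', '.join(ALGORITHMS)}")


def score_pairs(graph, algorithm: str, fitted: FittedLinkPredictor, pairs) -> list:
    """Functional wrapper: one (u, v, score, algorithm) record per pair."""
    s = fitted.scores(pairs)
    return [(u, v, float(x), algorithm) for (u, v), x in zip(pairs, s)]
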