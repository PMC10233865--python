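"""Edge splitting, negative sampling, repeated 6:3:1 validation, AP/AUROC.

Evaluation protocol: edges are split 6:3:1 into train/validation/test,
uniformly at random. "Tenfold cross validation" over a 6:3:1 split cannot
be a classical 10-fold partition, so the two printed facts are reconciled
as ten independently reseeded 6:3:1 resampling rounds; "fold" below means
one such round. Negatives are uniform non-edges of the full graph, sampled
1:1 with positives per partition and disjoint across partitions.

Metrics follow the standard definitions: AP is the step-sum
``sum_n (R_n - R_{n-1}) P_n`` over the ranked threshold sweep, and AUROC is
the probability that a uniformly drawn positive outranks a uniformly drawn
negative, ties counted one half (computed via scikit-learn, whose
implementations realize exactly these definitions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import ConfigError, DataError, UndefinedMetricError
from .network import HetGraph
from .predictors import LinkPredictor, make_predictor


@dataclass(frozen=True)
class SplitSpec:
    """Split fractions, number of resampling rounds, negative-sampling rule."""

    train_frac: float = 0.6
    val_frac: float = 0.3
    test_frac: float = 0.1
    folds: int = 10
    neg_ratio: float = 1.0
    seed: int = 0
    negative_universe: str = "all"  # "all" | "chem-target"

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("split fractions must be positive and sum to 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.neg_ratio <= 0:
            raise ConfigError("neg_ratio must be positive")
        if self.negative_universe not in ("all", "chem-target"):
            raise ConfigError("negative_universe must be 'all' or 'chem-target'")


@dataclass
class LabeledPairSet:
    pairs: List[Tuple[str, str]]
    labels: np.ndarray
    partition: str

    @property
    def positives(self) -> list:
        return [p for p, l in zip(self.pairs, self.labels) if l == 1]


def _partition_counts(n: int, fracs: Sequence[float]) -> list:
    """Largest-remainder apportionment; exact when n*frac are integral."""
    exact = [n * f for f in fracs]
    base = [math.floor(x) for x in exact]
    short = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _sample_negatives(graph, n: int, rng, universe: str, forbidden: set) -> list:
    if universe == "chem-target":
        left = sorted(graph.chemicals())
        right = sorted(graph.targets())
    else:
        left = right = sorted(graph.node_ids)
    if not left or not right:
        raise DataError("cannot sample negatives: empty node universe")
    out = []
    tries, max_tries = 0, 200 * n + 1000
    while len(out) < n and tries < max_tries:
        tries += 1
        u = left[rng.integers(len(left))]
        v = right[rng.integers(len(right))]
        if u == v:
            continue
        key = (u, v) if u <= v else (v, u)
        if key in forbidden or graph.has_edge(*key):
            continue
        forbidden.add(key)
        out.append(key)
    if len(out) < n:
        warnings.warn(f"only {len(out)}/{n} negatives could be sampled")
    return out


def split_edges(graph: HetGraph, spec: SplitSpec, seed: Optional[int] = None):
    """One 6:3:1 resampling round.

    Returns ``(train_graph, {"train": ..., "val": ..., "test": ...})``. The
    training graph retains all nodes but only the train-partition edges;
    negatives are verified non-edges of the *full* graph, disjoint across
    partitions.
    """
    edges = sorted(e.key for e in graph.edges())
    if len(edges) < 10:
        raise DataError("graph must have at least 10 edges to split 6:3:1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    order = rng.permutation(len(edges))
    counts = _partition_counts(
        len(edges), (spec.train_frac, spec.val_frac, spec.test_frac)
    )
    parts: Dict[str, list] = {}
    lo = 0
    for name, c in zip(("train", "val", "test"), counts):
        parts[name] = [edges[i] for i in order[lo : lo + c]]
        lo += c

    forbidden: set = set()
    labeled = {}
    for name in ("train", "val", "test"):
        pos = parts[name]
        n_neg = round(len(pos) * spec.neg_ratio)
        neg = _sample_negatives(graph, n_neg, rng, spec.negative_universe, forbidden)
        labeled[name] = LabeledPairSet(
            pos + neg, np.array([1] * len(pos) + [0] * len(neg)), name
        )
    train_graph = graph.subgraph_without_edges(parts["val"] + parts["test"])

    # positives whose endpoints are isolated in the training graph get
    # uninformative scores from every algorithm; warn, don't fail
    for name in ("val", "test"):
        dead = sum(
            1
            for u, v in parts[name]
            if train_graph.degree(u) == 0 and train_graph.degree(v) == 0
        )
        if dead:
            warnings.warn(
                f"{dead} {name} positives have both endpoints isolated in the "
                "training graph"
            )
    return train_graph, labeled


# -- metrics -----------------------------------------------------------------


def _check_labels(labels, need_both: bool):
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("metric undefined without positive labels")
    if need_both and labels.sum() == len(labels):
        raise UndefinedMetricError("metric undefined without negative labels")
    return labels


def average_precision(scores, labels) -> float:
    """AP = sum over the ranked sweep of (R_n - R_{n-1}) * P_n."""
    labels = _check_labels(labels, need_both=False)
    return float(_skm.average_precision_score(labels, np.asarray(scores)))


def auroc(scores, labels) -> float:
    """Pr(random positive outranks random negative), ties counted half."""
    labels = _check_labels(labels, need_both=True)
    return float(_skm.roc_auc_score(labels, np.asarray(scores)))


def roc_curve(scores, labels) -> List[Tuple[float, float]]:
    """(FPR, TPR) points of the full threshold sweep, (0,0) to (1,1)."""
    labels = _check_labels(labels, need_both=True)
    fpr, tpr, _ = _skm.roc_curve(labels, np.asarray(scores), drop_intermediate=False)
    if fpr[0] != 0.0 or tpr[0] != 0.0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return list(zip(fpr.tolist(), tpr.tolist()))


# -- cross-validation --------------------------------------------------------


@dataclass
class EvalResult:
    """Per-round and mean AUROC/AP for one (dataset, algorithm) cell."""

    algorithm: str
    dataset: str
    per_fold_auroc: List[float]
    per_fold_ap: List[float]
    roc_points: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.per_fold_auroc))

    @property
    def mean_ap(self) -> float:
        return float(np.mean(self.per_fold_ap))

    def summary(self) -> pd.DataFrame:
        n = len(self.per_fold_auroc)
        return pd.DataFrame(
            {
                "dataset": [self.dataset] * n + [self.dataset],
                "algorithm": [self.algorithm] * n + [self.algorithm],
                "fold": list(range(n)) + ["mean"],
                "auroc": self.per_fold_auroc + [self.mean_auroc],
                "ap": self.per_fold_ap + [self.mean_ap],
            }
        )


def fold_seed(master_seed: int, fold: int) -> int:
    """Stable per-round seed fan-out, kept below 2**31."""
    return int(np.random.SeedSequence([master_seed, fold]).generate_state(1)[0] % (2**31))


def cross_validate(
    graph: HetGraph,
    algorithm,
    spec: SplitSpec = SplitSpec(),
    dataset_name: str = "dataset",
    predictor_kwargs: Optional[dict] = None,
) -> EvalResult:
    """Repeated 6:3:1 evaluation of one algorithm on one dataset graph.

    ``algorithm`` is an algorithm name or a :class:`LinkPredictor` instance.
    Per round: fit on the training graph (labeled train pairs feed the
    classifier or calibration), score the held-out test pairs, record
    AUROC and AP. The validation partition is reserved for hyperparameter
    selection and never used to fit the final classifier. Deterministic
    under the master seed with single-threaded execution.
    """
    if isinstance(algorithm, LinkPredictor):
        predictor = algorithm
    else:
        predictor = make_predictor(algorithm, **(predictor_kwargs or {}))

    aurocs, aps = [], []
    pooled_scores, pooled_labels = [], []
    for f in range(spec.folds):
        fseed = fold_seed(spec.seed, f)
        try:
            train_graph, labeled = split_edges(graph, spec, seed=fseed)
            fitted = predictor.fit(
                train_graph,
                train_pairs=labeled["train"].pairs,
                train_labels=labeled["train"].labels,
                seed=fseed,
            )
            test = labeled["test"]
            s = fitted.scores(test.pairs)
            aurocs.append(auroc(s, test.labels))
            aps.append(average_precision(s, test.labels))
            pooled_scores.append(np.asarray(s))
            pooled_labels.append(test.labels)
        except UndefinedMetricError as exc:
            raise UndefinedMetricError(f"fold {f}: {exc}") from exc
    roc = roc_curve(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvalResult(
        algorithm=predictor.name,
        dataset=dataset_name,
        per_fold_auroc=aurocs,
        per_fold_ap=aps,
        roc_points=roc,
    )


def results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """One row per (dataset, algorithm, fold) plus mean rows."""
    return pd.concat([r.summary() for r in results], ignore_index=True)


def summary_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Mean AUROC/AP per (dataset, algorithm) cell."""
    rows = [
        {
            "dataset": r.dataset,
            "algorithm": r.algorithm,
            "mean_auroc": r.mean_auroc,
            "mean_ap": r.mean_ap,
            "folds": len(r.per_fold_auroc),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
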