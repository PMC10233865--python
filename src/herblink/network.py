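"""Layered heterogeneous chemical-target network: types, layer builders, assembly.

The network has two node roles (chemical, target) and three edge layers:

* CTC — chemical-target activity edges, taken directly from curated records;
* CCC — chemical-chemical edges where fingerprint Tanimoto similarity meets a
  threshold (0.6 by default);
* PPI — target-target edges with interaction confidence >= 0.9 (STRING-style).

Chemicals carry origin tags: ``DS`` (*Salvia miltiorrhiza*, Danshen), ``CX``
(*Ligusticum chuanxiong*, Chuanxiong) and/or ``drug`` (approved-drug
chemical). Targets carry the provenance of the chemicals that bind them.
Origin tags drive group selection (DS-drug, CX-drug, DS-CX-drug) and the
herbal-chemical -> drug-target edge filter downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import (
    InputError,
    InvalidSpecError,
    RoleViolationError,
    UndefinedSimilarityError,
)

logger = logging.getLogger(__name__)

LAYERS = ("CTC", "CCC", "PPI")
ORIGINS = ("DS", "CX", "drug")
HERB_TAGS = frozenset({"DS", "CX"})

#: node-origin tags admitted by each analysis group
GROUP_TAGS: Mapping[str, frozenset] = {
    "DS-drug": frozenset({"DS", "drug"}),
    "CX-drug": frozenset({"CX", "drug"}),
    "DS-CX-drug": frozenset({"DS", "CX", "drug"}),
}

#: the three valid layer sets, in increasing evidence order
VALID_LAYER_SETS = (
    frozenset({"CTC"}),
    frozenset({"CTC", "CCC"}),
    frozenset({"CTC", "CCC", "PPI"}),
)

#: which (sorted) role pair each layer is allowed to connect
_LAYER_ROLES = {
    "CTC": ("chemical", "target"),
    "CCC": ("chemical", "chemical"),
    "PPI": ("target", "target"),
}


@dataclass(frozen=True)
class NodeMeta:
    """Role and origin annotation for one node."""

    node_id: str
    role: str  # "chemical" | "target"
    origin: frozenset = frozenset()
    display_name: Optional[str] = None

    def __post_init__(self):
        if self.role not in ("chemical", "target"):
            raise InputError(f"unknown role {self.role!r} for node {self.node_id}")
        bad = set(self.origin) - set(ORIGINS)
        if bad:
            raise InputError(f"unknown origin tags {sorted(bad)} for node {self.node_id}")
        if not self.origin:
            raise InputError(f"empty origin set for node {self.node_id}")

    @property
    def is_herbal(self) -> bool:
        return bool(self.origin & HERB_TAGS)

    @property
    def is_drug(self) -> bool:
        return "drug" in self.origin


@dataclass(frozen=True)
class Fingerprint:
    """Set-bit representation of a binary chemical fingerprint."""

    chemical_id: str
    bits: frozenset

    def __post_init__(self):
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))
        if any(b < 0 for b in self.bits):
            raise InputError(f"negative bit index in fingerprint {self.chemical_id}")
        if not self.bits:
            warnings.warn(f"empty fingerprint for chemical {self.chemical_id}")


def _canon(u: str, v: str):
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class LayeredEdge:
    """Undirected edge with a layer label and optional evidence score."""

    u: str
    v: str
    layer: str
    score: Optional[float] = None

    def __post_init__(self):
        if self.u == self.v:
            raise InputError(f"self-loop {self.u!r} not allowed")
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}")
        cu, cv = _canon(self.u, self.v)
        object.__setattr__(self, "u", cu)
        object.__setattr__(self, "v", cv)

    @property
    def key(self):
        return (self.u, self.v)


@dataclass(frozen=True)
class DatasetSpec:
    """One cell of the group x layer-set grid."""

    group: str
    layers: frozenset

    def __post_init__(self):
        if self.group not in GROUP_TAGS:
            raise InvalidSpecError(f"unknown group {self.group!r}")
        object.__setattr__(self, "layers", frozenset(self.layers))
        if self.layers not in VALID_LAYER_SETS:
            raise InvalidSpecError(
                f"layer set {sorted(self.layers)} is not one of "
                "{CTC}, {CTC,CCC}, {CTC,CCC,PPI}"
            )

    @property
    def name(self) -> str:
        order = [l for l in LAYERS if l in self.layers]
        return f"{self.group}/{'&'.join(order)}"


class HetGraph:
    """Simple undirected graph over chemical and target nodes.

    Thin wrapper around :class:`networkx.Graph` that enforces layer role
    typing and keeps per-node :class:`NodeMeta`. The neighbor view ignores
    layer labels, as the embedding and index algorithms do.
    """

    def __init__(self, meta: Iterable[NodeMeta] = (), edges: Iterable[LayeredEdge] = ()):
        self.g = nx.Graph()
        self.meta: dict = {}
        for m in meta:
            self.add_node(m)
        for e in edges:
            self.add_edge(e)

    def add_node(self, m: NodeMeta):
        if m.node_id in self.meta and self.meta[m.node_id].role != m.role:
            raise InputError(f"node {m.node_id} re-declared with a different role")
        self.meta[m.node_id] = m
        self.g.add_node(m.node_id)

    def add_edge(self, e: LayeredEdge):
        for x in (e.u, e.v):
            if x not in self.meta:
                raise InputError(f"edge endpoint {x!r} has no metadata")
        roles = tuple(sorted((self.meta[e.u].role, self.meta[e.v].role)))
        if roles != _LAYER_ROLES[e.layer]:
            raise RoleViolationError(
                f"{e.layer} edge {e.u}-{e.v} connects roles {roles}"
            )
        self.g.add_edge(e.u, e.v, layer=e.layer, score=e.score)

    # -- views ---------------------------------------------------------------

    def neighbors(self, x: str) -> set:
        return set(self.g.neighbors(x))

    def degree(self, x: str) -> int:
        return self.g.degree(x)

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    @property
    def node_ids(self) -> list:
        return list(self.g.nodes)

    def edges(self) -> list:
        return [
            LayeredEdge(u, v, d["layer"], d.get("score"))
            for u, v, d in self.g.edges(data=True)
        ]

    def chemicals(self) -> list:
        return [n for n in self.g.nodes if self.meta[n].role == "chemical"]

    def targets(self) -> list:
        return [n for n in self.g.nodes if self.meta[n].role == "target"]

    def number_of_edges(self, layer: Optional[str] = None) -> int:
        if layer is None:
            return self.g.number_of_edges()
        return sum(1 for _, _, d in self.g.edges(data=True) if d["layer"] == layer)

    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def subgraph_without_edges(self, drop: Iterable) -> "HetGraph":
        """Copy with the given (u, v) pairs removed; all nodes retained."""
        dropset = {_canon(u, v) for u, v in drop}
        out = HetGraph(self.meta.values())
        for e in self.edges():
            if e.key not in dropset:
                out.add_edge(e)
        return out

    def copy(self) -> "HetGraph":
        return HetGraph(self.meta.values(), self.edges())


# -- layer construction ------------------------------------------------------


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on set-bit fingerprints."""
    if not a.bits and not b.bits:
        raise UndefinedSimilarityError(
            f"Tanimoto undefined for two empty fingerprints ({a.chemical_id}, {b.chemical_id})"
        )
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def build_ccc_layer(fps: Sequence[Fingerprint], threshold: float = 0.6) -> set:
    """Chemical-chemical similarity edges at Tanimoto >= ``threshold``.

    Vectorized over a dense bit matrix; equivalent to the all-pairs scan.
    """
    if not 0 < threshold <= 1:
        raise InputError(f"threshold {threshold} outside (0, 1]")
    ids = [fp.chemical_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate chemical_id in fingerprint list")
    nonempty = [fp for fp in fps if fp.bits]
    if len(nonempty) < len(fps):
        logger.warning("%d empty fingerprints skipped", len(fps) - len(nonempty))
    if len(nonempty) < 2:
        return set()
    nbits = max(max(fp.bits) for fp in nonempty) + 1
    M = np.zeros((len(nonempty), nbits), dtype=np.float64)
    for i, fp in enumerate(nonempty):
        M[i, sorted(fp.bits)] = 1.0
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    sim = inter / union
    edges = set()
    ii, jj = np.where(np.triu(sim >= threshold, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        edges.add(
            LayeredEdge(nonempty[i].chemical_id, nonempty[j].chemical_id, "CCC",
                        float(sim[i, j]))
        )
    return edges


def build_ppi_layer(
    pairs: Iterable, threshold: float = 0.9, meta: Optional[Mapping] = None
) -> set:
    """Target-target edges with confidence >= ``threshold``.

    Drops self-pairs; symmetric duplicates are merged keeping the max score.
    """
    best: dict = {}
    for u, v, score in pairs:
        score = float(score)
        if not 0 <= score <= 1:
            raise InputError(f"PPI score {score} outside [0, 1] for {u}-{v}")
        if u == v:
            continue
        if meta is not None:
            for x in (u, v):
                if x not in meta or meta[x].role != "target":
                    raise RoleViolationError(f"PPI endpoint {x!r} is not a target")
        key = _canon(u, v)
        if score > best.get(key, -1.0):
            best[key] = score
    return {
        LayeredEdge(u, v, "PPI", s) for (u, v), s in best.items() if s >= threshold
    }


def build_ctc_layer(records: Iterable, meta: Optional[Mapping] = None) -> set:
    """Deduplicated chemical-target edges from activity records."""
    edges = set()
    for chem, targ in records:
        if meta is not None:
            if chem not in meta or targ not in meta:
                raise RoleViolationError(f"unknown endpoint in record ({chem}, {targ})")
            if meta[chem].role != "chemical" or meta[targ].role != "target":
                raise RoleViolationError(
                    f"CTC record ({chem}, {targ}) violates chemical-target roles"
                )
        edges.add(LayeredEdge(chem, targ, "CTC"))
    return edges


# -- dataset assembly --------------------------------------------------------


def assemble_dataset(
    spec: DatasetSpec,
    layers: Mapping[str, Iterable],
    meta: Mapping[str, NodeMeta],
) -> HetGraph:
    """Build the graph for one (group, layer-set) dataset.

    A chemical enters the group iff its origin set intersects the group's
    tags; a target enters via an incident CTC edge to a selected chemical or
    via its own origin tags. Only edges with both endpoints selected are
    kept. Isolated selected nodes are retained (they are excluded from walk
    starts downstream, never silently pruned).
    """
    missing = spec.layers - set(layers)
    if "CTC" not in layers:
        raise InvalidSpecError("CTC layer is required but missing")
    if missing:
        raise InvalidSpecError(f"requested layers missing from input: {sorted(missing)}")

    tags = GROUP_TAGS[spec.group]
    chems = {
        n for n, m in meta.items() if m.role == "chemical" and m.origin & tags
    }
    targs = {
        n for n, m in meta.items() if m.role == "target" and m.origin & tags
    }
    for e in layers["CTC"]:
        cu, cv = e.u, e.v
        chem, targ = (cu, cv) if meta[cu].role == "chemical" else (cv, cu)
        if chem in chems:
            targs.add(targ)

    selected = chems | targs
    graph = HetGraph(meta[n] for n in selected)
    kept = {layer: 0 for layer in LAYERS}
    for layer in sorted(spec.layers):
        for e in layers[layer]:
            if e.u in selected and e.v in selected:
                graph.add_edge(e)
                kept[layer] += 1
    logger.info(
        "dataset %s: %d chemicals, %d targets, edges %s",
        spec.name, len(chems), len(targs),
        {l: k for l, k in kept.items() if l in spec.layers},
    )
    return graph


def summarize(graph: HetGraph) -> dict:
    """Node counts by role and edge counts by layer."""
    by_layer = {layer: graph.number_of_edges(layer) for layer in LAYERS}
    n_chem = len(graph.chemicals())
    n_targ = len(graph.targets())
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_chemicals": n_chem,
        "n_targets": n_targ,
        "n_edges": graph.number_of_edges(),
        "edges_by_layer": by_layer,
    }
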