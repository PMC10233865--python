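"""Full-graph prediction of new edges and expansion accounting.

After the benchmark selects a model, it is refitted on 100% of the dataset
graph and every chemical-target non-edge is scored; candidates with
prediction value >= 0.5 are "new edges". The records are then narrowed to
herbal-chemical -> drug-target pairs (the pharmacologically interesting
direction) and summarized as expansion counts and percentages per category:
newly predicted items divided by original items, x100, rounded to two
decimals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .errors import ConfigError, DataError, LookupError_
from .network import HERB_TAGS, HetGraph


@dataclass(frozen=True)
class PredictionRecord:
    """One retained chemical-target prediction."""

    chemical_id: str
    target_id: str
    prediction_value: float
    group: str


@dataclass(frozen=True)
class ExpansionRow:
    original: int
    expanded: int

    @property
    def pct(self) -> float:
        if self.original == 0:
            raise DataError("expansion percentage undefined for zero original count")
        return round(100.0 * self.expanded / self.original, 2)


#: category order mirrors the published expansion table
CATEGORIES = (
    "total_edges",
    "herbal_drugtarget_edges",
    "total_chemical_nodes",
    "herbal_chemical_nodes",
)


@dataclass
class ExpansionReport:
    group: str
    rows: Dict[str, ExpansionRow]

    @classmethod
    def from_counts(cls, group: str, counts: Mapping[str, tuple]) -> "ExpansionReport":
        """Build from {category: (original, expanded)} count pairs."""
        return cls(group, {c: ExpansionRow(*counts[c]) for c in counts})

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "categories": {
                name: {
                    "original": row.original,
                    "expanded": row.expanded,
                    "expansion_pct": row.pct,
                }
                for name, row in self.rows.items()
            },
        }


def _candidate_nonedges(graph: HetGraph, universe: str):
    """Non-edges of the graph: chemical-target only, or all node pairs."""
    if universe == "ctc":
        for c, t in itertools.product(sorted(graph.chemicals()), sorted(graph.targets())):
            if not graph.has_edge(c, t):
                yield (c, t)
    elif universe == "all":
        nodes = sorted(graph.node_ids)
        for u, v in itertools.combinations(nodes, 2):
            if not graph.has_edge(u, v):
                yield (u, v)
    else:
        raise ConfigError(f"unknown candidate universe {universe!r}")


def predict_new_edges(
    graph: HetGraph,
    fitted,
    threshold: float = 0.5,
    group: str = "DS-CX-drug",
    batch: int = 16384,
) -> List[PredictionRecord]:
    """Score all chemical-target non-edges; keep prediction value >= threshold.

    ``fitted`` is a results object from a predictor fitted on the full
    dataset graph; deterministic given the fitted model.
    """
    if not 0 < threshold < 1:
        raise ConfigError(f"prediction threshold {threshold} outside (0, 1)")
    records = []
    cands = list(_candidate_nonedges(graph, "ctc"))
    for lo in range(0, len(cands), batch):
        chunk = cands[lo : lo + batch]
        probs = fitted.predict_proba(chunk)
        for (c, t), p in zip(chunk, probs):
            if p >= threshold:
                records.append(PredictionRecord(c, t, float(p), group))
    return records


def count_new_edges_all_types(
    graph: HetGraph, fitted, threshold: float = 0.5, batch: int = 16384
) -> int:
    """Retained non-edges of *any* type (the total-edge expansion row)."""
    if not 0 < threshold < 1:
        raise ConfigError(f"prediction threshold {threshold} outside (0, 1)")
    n = 0
    cands = list(_candidate_nonedges(graph, "all"))
    for lo in range(0, len(cands), batch):
        chunk = cands[lo : lo + batch]
        probs = fitted.predict_proba(chunk)
        n += int((probs >= threshold).sum())
    return n


def filter_herbal_to_drugtarget(
    records: Sequence[PredictionRecord], meta: Mapping
) -> List[PredictionRecord]:
    """Keep records whose chemical is herbal (DS/CX) and target is a drug target."""
    out = []
    for r in records:
        if r.chemical_id not in meta:
            raise LookupError_(f"unknown chemical {r.chemical_id!r} in predictions")
        if r.target_id not in meta:
            raise LookupError_(f"unknown target {r.target_id!r} in predictions")
        if meta[r.chemical_id].origin & HERB_TAGS and "drug" in meta[r.target_id].origin:
            out.append(r)
    return out


def _original_herbal_drugtarget_edges(graph: HetGraph, meta) -> int:
    n = 0
    for e in graph.edges():
        if e.layer != "CTC":
            continue
        chem, targ = (e.u, e.v) if meta[e.u].role == "chemical" else (e.v, e.u)
        if meta[chem].origin & HERB_TAGS and "drug" in meta[targ].origin:
            n += 1
    return n


def expansion_report(
    graph: HetGraph,
    predictions: Sequence[PredictionRecord],
    meta: Mapping,
    group: str = "DS-CX-drug",
    n_total_new: Optional[int] = None,
) -> ExpansionReport:
    """Expansion counts and percentages for one group.

    ``predictions`` are retained chemical-target records (threshold already
    applied); ``n_total_new`` optionally supplies the any-type new-edge count
    for the total-edges row (defaults to the chemical-target count).
    """
    filtered = filter_herbal_to_drugtarget(predictions, meta)
    chems = set(graph.chemicals())
    herbal = {c for c in chems if meta[c].origin & HERB_TAGS}
    pred_chems = {r.chemical_id for r in predictions} & chems
    pred_herbal = {r.chemical_id for r in filtered} & herbal
    rows = {
        "total_edges": ExpansionRow(
            graph.number_of_edges(),
            len(predictions) if n_total_new is None else n_total_new,
        ),
        "herbal_drugtarget_edges": ExpansionRow(
            _original_herbal_drugtarget_edges(graph, meta), len(filtered)
        ),
        "total_chemical_nodes": ExpansionRow(len(chems), len(pred_chems)),
        "herbal_chemical_nodes": ExpansionRow(len(herbal), len(pred_herbal)),
    }
    return ExpansionReport(group, rows)


def write_predictions_tsv(path, records: Sequence[PredictionRecord], header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# chemical_id\ttarget_id\tprediction_value\tgroup\n")
        for r in sorted(records, key=lambda r: (-r.prediction_value, r.chemical_id, r.target_id)):
            fh.write(f"{r.chemical_id}\t{r.target_id}\t{r.prediction_value:.4f}\t{r.group}\n")
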