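"""New-edge extraction, herbal->drug-target filtering, expansion accounting."""

import numpy as np
import pytest

import herblink as hb
from herblink.errors import ConfigError, DataError, LookupError_
from herblink.expansion import (
    ExpansionReport,
    ExpansionRow,
    PredictionRecord,
    count_new_edges_all_types,
    expansion_report,
    filter_herbal_to_drugtarget,
    predict_new_edges,
)
from herblink.network import NodeMeta


class StubFitted:
    """Deterministic stand-in for a fitted model: score by lookup."""

    def __init__(self, table, default=0.0):
        self.table = {tuple(sorted(k)): v for k, v in table.items()}
        self.default = default

    def predict_proba(self, pairs):
        return np.array(
            [self.table.get(tuple(sorted(p)), self.default) for p in pairs]
        )


def mini_graph():
    meta = {
        "c_ds": NodeMeta("c_ds", "chemical", frozenset({"DS"})),
        "c_cx": NodeMeta("c_cx", "chemical", frozenset({"CX"})),
        "c_dr": NodeMeta("c_dr", "chemical", frozenset({"drug"})),
        "t_dr": NodeMeta("t_dr", "target", frozenset({"drug"})),
        "t_h": NodeMeta("t_h", "target", frozenset({"DS"})),
    }
    layers = {"CTC": hb.build_ctc_layer([("c_ds", "t_dr"), ("c_dr", "t_h")], meta)}
    g = hb.assemble_dataset(hb.DatasetSpec("DS-CX-drug", frozenset({"CTC"})), layers, meta)
    return g, meta


class TestPredictNewEdges:
    def test_threshold_bounds_enforced(self):
        g, _ = mini_graph()
        for bad in (1.01, 0.0, -0.2, 1.0):
            with pytest.raises(ConfigError):
                predict_new_edges(g, StubFitted({}), threshold=bad)

    def test_zero_scores_give_empty_set(self):
        g, _ = mini_graph()
        assert predict_new_edges(g, StubFitted({}, default=0.0)) == []

    def test_candidates_are_chemical_target_nonedges(self):
        g, meta = mini_graph()
        recs = predict_new_edges(g, StubFitted({}, default=0.9))
        for r in recs:
            assert meta[r.chemical_id].role == "chemical"
            assert meta[r.target_id].role == "target"
            assert not g.has_edge(r.chemical_id, r.target_id)
        # 3 chemicals x 2 targets minus 2 existing edges
        assert len(recs) == 4

    def test_threshold_monotonicity(self):
        g, _ = mini_graph()
        rng = np.random.default_rng(0)
        fitted = StubFitted({}, default=0.0)
        fitted.predict_proba = lambda pairs: np.linspace(0.1, 0.9, len(pairs))
        counts = [
            len(predict_new_edges(g, fitted, threshold=t)) for t in (0.2, 0.5, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFilter:
    def test_hand_labeled_fixture(self):
        _, meta = mini_graph()
        records = [
            PredictionRecord("c_ds", "t_dr", 0.9, "DS-CX-drug"),  # herbal -> drug target
            PredictionRecord("c_ds", "t_h", 0.9, "DS-CX-drug"),   # herbal -> herb target
            PredictionRecord("c_dr", "t_dr", 0.9, "DS-CX-drug"),  # drug chem -> drug target
            PredictionRecord("c_cx", "t_dr", 0.7, "DS-CX-drug"),  # herbal -> drug target
        ]
        kept = filter_herbal_to_drugtarget(records, meta)
        assert [(r.chemical_id, r.target_id) for r in kept] == [
            ("c_ds", "t_dr"),
            ("c_cx", "t_dr"),
        ]

    def test_unknown_node_raises(self):
        _, meta = mini_graph()
        with pytest.raises(LookupError_):
            filter_herbal_to_drugtarget(
                [PredictionRecord("ghost", "t_dr", 0.9, "DS-drug")], meta
            )


class TestReport:
    def test_percentage_arithmetic(self):
        assert ExpansionRow(236, 43).pct == 18.22
        assert ExpansionRow(40, 20).pct == 50.00

    def test_zero_original_undefined(self):
        with pytest.raises(DataError):
            ExpansionRow(0, 5).pct

    def test_no_predictions_all_zero(self):
        g, meta = mini_graph()
        rep = expansion_report(g, [], meta, "DS-CX-drug")
        assert all(row.pct == 0.0 for row in rep.rows.values())

    def test_counts_against_recount_oracle(self):
        g, meta = mini_graph()
        records = [
            PredictionRecord("c_ds", "t_h", 0.8, "DS-CX-drug"),
            PredictionRecord("c_cx", "t_dr", 0.8, "DS-CX-drug"),
            PredictionRecord("c_dr", "t_h", 0.8, "DS-CX-drug"),
        ]
        rep = expansion_report(g, records, meta, "DS-CX-drug")
        assert rep.rows["total_edges"].original == g.number_of_edges()
        assert rep.rows["total_edges"].expanded == 3
        # herbal->drug-target: original edge c_ds-t_dr; new: c_cx-t_dr only
        assert rep.rows["herbal_drugtarget_edges"] == ExpansionRow(1, 1)
        assert rep.rows["total_chemical_nodes"] == ExpansionRow(3, 3)
        assert rep.rows["herbal_chemical_nodes"] == ExpansionRow(2, 1)
        payload = rep.to_dict()
        assert payload["categories"]["herbal_chemical_nodes"]["expansion_pct"] == 50.0

    def test_from_counts(self):
        rep = ExpansionReport.from_counts("all", {"total_edges": (236, 43)})
        assert rep.rows["total_edges"].pct == 18.22


def test_heldout_planted_edges_enriched_in_retained_predictions(tiny_net, tiny_layers):
    """Recovery: held-out within-block CTC edges are retained at a much
    higher rate than background candidate non-edges."""
    spec = hb.DatasetSpec("DS-CX-drug", frozenset({"CTC", "CCC", "PPI"}))
    g = hb.assemble_dataset(spec, tiny_layers, tiny_net.meta)
    rng = np.random.default_rng(1)
    intra = [
        e.key
        for e in g.edges()
        if e.layer == "CTC" and tiny_net.blocks[e.u] == tiny_net.blocks[e.v]
    ]
    held = [intra[i] for i in rng.choice(len(intra), 10, replace=False)]
    g2 = g.subgraph_without_edges(held)
    fitted = hb.make_predictor("AA").fit(g2, seed=1)
    recs = predict_new_edges(g2, fitted, threshold=0.5, group="DS-CX-drug")
    retained = {tuple(sorted((r.chemical_id, r.target_id))) for r in recs}
    n_cand = len(g2.chemicals()) * len(g2.targets()) - g2.number_of_edges("CTC")
    held_rate = sum(1 for h in held if tuple(sorted(h)) in retained) / len(held)
    background_rate = len(retained) / n_cand
    assert held_rate > 2 * background_rate
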