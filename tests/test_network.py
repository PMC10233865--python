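"""Layer construction, dataset assembly and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herblink.io as hio
from herblink.errors import (
    InputError,
    InvalidSpecError,
    RoleViolationError,
    UndefinedSimilarityError,
)
from herblink.network import (
    DatasetSpec,
    Fingerprint,
    HetGraph,
    LayeredEdge,
    NodeMeta,
    assemble_dataset,
    build_ccc_layer,
    build_ctc_layer,
    build_ppi_layer,
    summarize,
    tanimoto,
)

bitsets = st.frozensets(st.integers(0, 63), min_size=1, max_size=32)


def fp(cid, bits):
    return Fingerprint(cid, frozenset(bits))


class TestTanimoto:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert tanimoto(fp("a", a), fp("b", b)) == expected

    @settings(deadline=None)
    @given(bitsets, bitsets)
    def test_symmetric_bounded_identity(self, a, b):
        t = tanimoto(fp("a", a), fp("b", b))
        assert t == tanimoto(fp("b", b), fp("a", a))
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == (a == b)

    def test_both_empty_undefined(self):
        with pytest.warns(UserWarning):
            ea, eb = fp("a", set()), fp("b", set())
        with pytest.raises(UndefinedSimilarityError):
            tanimoto(ea, eb)

    def test_one_empty_is_zero(self):
        with pytest.warns(UserWarning):
            e = fp("a", set())
        assert tanimoto(e, fp("b", {1})) == 0.0


class TestCCCLayer:
    def test_identical_fingerprints_form_triangle(self):
        fps = [fp(c, {1, 5, 9}) for c in "abc"]
        edges = build_ccc_layer(fps)
        assert len(edges) == 3
        assert all(e.layer == "CCC" and e.score == 1.0 for e in edges)

    def test_all_below_threshold_empty(self):
        fps = [fp("a", {1, 2, 3, 4}), fp("b", {5, 6, 7, 8}), fp("c", {9, 10, 11, 1})]
        assert build_ccc_layer(fps, 0.6) == set()

    def test_matches_bruteforce_pair_scan(self):
        rng = np.random.default_rng(7)
        fps = [
            fp(f"c{i}", set(rng.choice(64, size=rng.integers(5, 30), replace=False).tolist()))
            for i in range(20)
        ]
        edges = {(e.u, e.v) for e in build_ccc_layer(fps, 0.35)}
        expected = set()
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                if tanimoto(fps[i], fps[j]) >= 0.35:
                    expected.add(tuple(sorted((fps[i].chemical_id, fps[j].chemical_id))))
        assert edges == expected

    def test_duplicate_id_rejected(self):
        with pytest.raises(InputError):
            build_ccc_layer([fp("a", {1}), fp("a", {2})])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        fps = [
            fp(f"c{i}", set(rng.choice(32, size=10, replace=False).tolist()))
            for i in range(15)
        ]
        prev = None
        for thr in (0.9, 0.6, 0.3, 0.1):
            cur = {(e.u, e.v) for e in build_ccc_layer(fps, thr)}
            if prev is not None:
                assert prev <= cur
            prev = cur


class TestPPILayer:
    META = {
        t: NodeMeta(t, "target", frozenset({"drug"})) for t in ("A", "B", "C")
    }

    def test_threshold_cut(self):
        edges = build_ppi_layer([("A", "B", 0.95), ("B", "C", 0.2)], meta=self.META)
        assert {(e.u, e.v) for e in edges} == {("A", "B")}

    def test_boundary_inclusive(self):
        edges = build_ppi_layer([("A", "B", 0.9)], meta=self.META)
        assert len(edges) == 1

    def test_self_pair_dropped(self):
        assert build_ppi_layer([("A", "A", 0.99)], meta=self.META) == set()

    def test_symmetric_duplicates_keep_max(self):
        edges = build_ppi_layer([("A", "B", 0.91), ("B", "A", 0.97)], meta=self.META)
        (e,) = edges
        assert e.score == 0.97

    def test_role_violation(self):
        meta = dict(self.META)
        meta["X"] = NodeMeta("X", "chemical", frozenset({"drug"}))
        with pytest.raises(RoleViolationError):
            build_ppi_layer([("A", "X", 0.95)], meta=meta)


class TestCTCLayer:
    META = {
        "c1": NodeMeta("c1", "chemical", frozenset({"DS"})),
        "c2": NodeMeta("c2", "chemical", frozenset({"drug"})),
        "t1": NodeMeta("t1", "target", frozenset({"drug"})),
        "t2": NodeMeta("t2", "target", frozenset({"drug"})),
    }

    def test_deduplicates(self):
        assert len(build_ctc_layer([("c1", "t1"), ("c1", "t1")], self.META)) == 1

    def test_empty(self):
        assert build_ctc_layer([], self.META) == set()

    def test_distinct_pair_count(self):
        rng = np.random.default_rng(0)
        chems, targs = ["c1", "c2"], ["t1", "t2"]
        records = [
            (chems[rng.integers(2)], targs[rng.integers(2)]) for _ in range(50)
        ]
        assert len(build_ctc_layer(records, self.META)) == len(set(records))

    def test_role_violation(self):
        with pytest.raises(RoleViolationError):
            build_ctc_layer([("c1", "c2")], self.META)


def _mini_inputs():
    meta = {
        "c_ds": NodeMeta("c_ds", "chemical", frozenset({"DS"})),
        "c_cx": NodeMeta("c_cx", "chemical", frozenset({"CX"})),
        "c_dr": NodeMeta("c_dr", "chemical", frozenset({"drug"})),
        "t1": NodeMeta("t1", "target", frozenset({"drug"})),
        "t2": NodeMeta("t2", "target", frozenset({"DS"})),
    }
    layers = {
        "CTC": build_ctc_layer(
            [("c_ds", "t1"), ("c_cx", "t2"), ("c_dr", "t1")], meta
        ),
        "CCC": {LayeredEdge("c_ds", "c_dr", "CCC", 0.7)},
        "PPI": {LayeredEdge("t1", "t2", "PPI", 0.95)},
    }
    return meta, layers


class TestAssemble:
    def test_group_filter_excludes_foreign_herb(self):
        meta, layers = _mini_inputs()
        g = assemble_dataset(DatasetSpec("DS-drug", frozenset({"CTC"})), layers, meta)
        assert "c_cx" not in g.meta
        assert {e.key for e in g.edges()} == {("c_ds", "t1"), ("c_dr", "t1")}

    def test_all_layers_edge_count_is_sum(self):
        meta, layers = _mini_inputs()
        g = assemble_dataset(
            DatasetSpec("DS-CX-drug", frozenset({"CTC", "CCC", "PPI"})), layers, meta
        )
        assert g.number_of_edges() == sum(len(v) for v in layers.values())

    def test_missing_ctc_is_invalid(self):
        meta, layers = _mini_inputs()
        with pytest.raises(InvalidSpecError):
            assemble_dataset(
                DatasetSpec("DS-drug", frozenset({"CTC"})), {"CCC": layers["CCC"]}, meta
            )

    def test_invalid_layer_set_rejected(self):
        with pytest.raises(InvalidSpecError):
            DatasetSpec("DS-drug", frozenset({"CTC", "PPI"}))

    def test_layer_role_typing_enforced(self, tiny_graph_full):
        roles = {"CTC": {"chemical", "target"}, "CCC": {"chemical"}, "PPI": {"target"}}
        for e in tiny_graph_full.edges():
            got = {tiny_graph_full.meta[e.u].role, tiny_graph_full.meta[e.v].role}
            assert got == roles[e.layer]


class TestSummarize:
    def test_empty_graph(self):
        s = summarize(HetGraph())
        assert s["n_nodes"] == s["n_edges"] == 0

    def test_recount_oracle(self, tiny_graph_full):
        s = summarize(tiny_graph_full)
        chems = sum(1 for m in tiny_graph_full.meta.values() if m.role == "chemical")
        assert s["n_chemicals"] == chems
        assert s["n_nodes"] == s["n_chemicals"] + s["n_targets"]
        assert s["n_edges"] == sum(s["edges_by_layer"].values())


class TestIO:
    def test_roundtrips(self, tmp_path, tiny_net, tiny_layers):
        edge_path = tmp_path / "ctc.tsv"
        hio.write_edge_tsv(edge_path, tiny_layers["CTC"])
        assert hio.read_edge_tsv(edge_path) == tiny_layers["CTC"]

        meta_path = tmp_path / "nodes.tsv"
        hio.write_node_meta(meta_path, tiny_net.meta)
        back = hio.read_node_meta(meta_path)
        assert {k: (m.role, m.origin) for k, m in back.items()} == {
            k: (m.role, m.origin) for k, m in tiny_net.meta.items()
        }

        fp_path = tmp_path / "fp.tsv"
        hio.write_fingerprints(fp_path, tiny_net.fingerprints)
        back_fp = hio.read_fingerprints(fp_path)
        assert {f.chemical_id: f.bits for f in back_fp} == {
            f.chemical_id: f.bits for f in tiny_net.fingerprints
        }
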