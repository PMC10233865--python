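"""TSV readers and writers for the network file dialects.

Formats (all tab-separated, ``#`` comment lines allowed):

* edge list:      ``u  v  layer  [score]``
* node metadata:  ``node_id  role  origins`` (origins ``;``-separated)
* fingerprints:   ``chemical_id  b1,b2,b3,...`` (comma-separated bit indices)
* embeddings:     ``node_id  v1 ... v_dims``
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import InputError
from .network import Fingerprint, LayeredEdge, NodeMeta


def _data_lines(path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_edge_tsv(path) -> set:
    edges = set()
    for parts in _data_lines(path):
        if len(parts) not in (3, 4):
            raise InputError(f"bad edge line in {path}: {parts!r}")
        u, v, layer = parts[:3]
        score = None
        if len(parts) == 4 and parts[3] not in ("", "NA"):
            score = float(parts[3])
        edges.add(LayeredEdge(u, v, layer, score))
    return edges


def write_edge_tsv(path, edges: Iterable[LayeredEdge], header: Optional[str] = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# u\tv\tlayer\tscore\n")
        for e in sorted(edges, key=lambda e: (e.layer, e.u, e.v)):
            score = "" if e.score is None else f"{e.score:.6g}"
            fh.write(f"{e.u}\t{e.v}\t{e.layer}\t{score}\n")


def read_node_meta(path) -> dict:
    meta = {}
    for parts in _data_lines(path):
        if len(parts) < 3:
            raise InputError(f"bad node-meta line in {path}: {parts!r}")
        node_id, role, origins = parts[:3]
        display = parts[3] if len(parts) > 3 else None
        if node_id in meta:
            raise InputError(f"duplicate node_id {node_id!r} in {path}")
        meta[node_id] = NodeMeta(
            node_id, role, frozenset(origins.split(";")), display
        )
    return meta


def write_node_meta(path, meta: Mapping[str, NodeMeta], header: Optional[str] = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# node_id\trole\torigins\n")
        for node_id in sorted(meta):
            m = meta[node_id]
            fh.write(f"{node_id}\t{m.role}\t{';'.join(sorted(m.origin))}\n")


def read_fingerprints(path) -> list:
    fps = []
    seen = set()
    for parts in _data_lines(path):
        if len(parts) != 2:
            raise InputError(f"bad fingerprint line in {path}: {parts!r}")
        cid, bits = parts
        if cid in seen:
            raise InputError(f"duplicate chemical_id {cid!r} in {path}")
        seen.add(cid)
        bitset = frozenset(int(b) for b in bits.split(",") if b != "")
        fps.append(Fingerprint(cid, bitset))
    return fps


def write_fingerprints(path, fps: Iterable[Fingerprint], header: Optional[str] = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# chemical_id\tbits\n")
        for fp in sorted(fps, key=lambda f: f.chemical_id):
            fh.write(f"{fp.chemical_id}\t{','.join(str(b) for b in sorted(fp.bits))}\n")


def write_embeddings(path, node_ids, vectors: np.ndarray, header: Optional[str] = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for nid, vec in zip(node_ids, vectors):
            fh.write(nid + "\t" + "\t".join(f"{x:.6g}" for x in vec) + "\n")


def write_walk_corpus(path, walks):
    """word2vec text-corpus dialect: one space-separated walk per line."""
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


def ensure_dir(path):
    os.makedirs(path, exist_ok=True)
    return path
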