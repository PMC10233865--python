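"""Synthetic layered chemical-target networks with planted block structure.

The generator emulates the statistical premise of the analysis: chemicals
and targets belong to latent activity communities ("blocks"); structurally
similar chemicals share targets, and interacting proteins share ligands.
Concretely:

* CTC edges are Bernoulli(``ctc_p_in``) within a block, ``ctc_p_out``
  across blocks (a bipartite planted-partition model);
* each block owns a random signature of ``fp_block_bits`` fingerprint bits;
  a chemical's fingerprint is its block signature with independent per-bit
  flip noise ``fp_noise``, so Tanimoto-thresholded CCC edges concentrate
  within blocks;
* PPI confidence scores are clipped Normal(``ppi_mu_in``, 0.05) for
  within-block target pairs and Normal(``ppi_mu_out``, 0.05) for an equal
  number of sampled between-block pairs, so the 0.9 confidence cut keeps
  mostly intra-block pairs;
* a fraction of chemicals carries herbal origin tags (DS and/or CX), the
  rest are drug chemicals; targets inherit origin tags from the chemicals
  that bind them.

Everything is driven by one seed; generated files are byte-identical
across reruns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as hio
from .errors import ConfigError
from .network import (
    Fingerprint,
    HetGraph,
    LayeredEdge,
    NodeMeta,
    build_ccc_layer,
    build_ctc_layer,
    build_ppi_layer,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_chem: int = 400
    n_targ: int = 1000
    n_blocks: int = 8
    ctc_p_in: float = 0.08
    ctc_p_out: float = 0.002
    fp_len: int = 256
    fp_block_bits: int = 40
    fp_noise: float = 0.05
    ppi_mu_in: float = 0.92
    ppi_mu_out: float = 0.4
    herb_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.ctc_p_in > self.ctc_p_out:
            raise ConfigError("ctc_p_in must exceed ctc_p_out")
        if not self.ppi_mu_in > self.ppi_mu_out:
            raise ConfigError("ppi_mu_in must exceed ppi_mu_out")
        for name in ("ctc_p_in", "ctc_p_out", "fp_noise", "herb_fraction",
                     "ppi_mu_in", "ppi_mu_out"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.fp_block_bits > self.fp_len:
            raise ConfigError("fp_block_bits cannot exceed fp_len")
        # expected CTC edge count given random block assignment
        pairs = self.n_chem * self.n_targ
        p_same = 1.0 / self.n_blocks
        expected = pairs * (p_same * self.ctc_p_in + (1 - p_same) * self.ctc_p_out)
        if expected < 10:
            raise ConfigError(
                f"expected CTC edge count {expected:.1f} < 10; increase sizes or rates"
            )


#: small network for fast tests: ~40 chemicals, ~100 targets, ~350 CTC edges
TINY_PROFILE = GeneratorConfig(
    n_chem=40,
    n_targ=100,
    n_blocks=4,
    ctc_p_in=0.3,
    ctc_p_out=0.02,
    fp_len=128,
    fp_block_bits=30,
    herb_fraction=0.25,
)


@dataclass
class SyntheticNetwork:
    """In-memory generated network plus the latent ground truth."""

    config: GeneratorConfig
    meta: Dict[str, NodeMeta]
    ctc_records: List[Tuple[str, str]]
    ppi_pairs: List[Tuple[str, str, float]]
    fingerprints: List[Fingerprint]
    blocks: Dict[str, int]

    def build_layers(self, ccc_threshold: float = 0.6, ppi_threshold: float = 0.9):
        """The three evidence layers at the standard thresholds."""
        return {
            "CTC": build_ctc_layer(self.ctc_records, self.meta),
            "CCC": build_ccc_layer(self.fingerprints, ccc_threshold),
            "PPI": build_ppi_layer(self.ppi_pairs, ppi_threshold, self.meta),
        }

    def write(self, outdir: str) -> dict:
        """Emit the TSV files; returns the path map."""
        hio.ensure_dir(outdir)
        tag = f"herblink synthetic network, seed={self.config.seed}"
        paths = {
            "nodes": os.path.join(outdir, "nodes.tsv"),
            "ctc": os.path.join(outdir, "ctc.tsv"),
            "ppi_scores": os.path.join(outdir, "ppi_scores.tsv"),
            "fingerprints": os.path.join(outdir, "fingerprints.tsv"),
            "truth_blocks": os.path.join(outdir, "truth_blocks.tsv"),
        }
        hio.write_node_meta(paths["nodes"], self.meta, header=tag)
        hio.write_edge_tsv(
            paths["ctc"], build_ctc_layer(self.ctc_records, self.meta), header=tag
        )
        with open(paths["ppi_scores"], "w") as fh:
            fh.write(f"# {tag}\n# target_a\ttarget_b\tscore\n")
            for u, v, s in sorted(self.ppi_pairs):
                fh.write(f"{u}\t{v}\t{s:.4f}\n")
        hio.write_fingerprints(paths["fingerprints"], self.fingerprints, header=tag)
        with open(paths["truth_blocks"], "w") as fh:
            fh.write(f"# {tag}\n# node_id\tblock\n")
            for n in sorted(self.blocks):
                fh.write(f"{n}\t{self.blocks[n]}\n")
        return paths


def generate(config: GeneratorConfig = GeneratorConfig(), outdir: Optional[str] = None) -> SyntheticNetwork:
    """Draw one network from the planted-block model; optionally write files."""
    rng = np.random.default_rng(config.seed)
    chems = [f"C{i:04d}" for i in range(config.n_chem)]
    targs = [f"T{i:04d}" for i in range(config.n_targ)]

    chem_block = rng.integers(config.n_blocks, size=config.n_chem)
    targ_block = rng.integers(config.n_blocks, size=config.n_targ)
    blocks = {c: int(b) for c, b in zip(chems, chem_block)}
    blocks.update({t: int(b) for t, b in zip(targs, targ_block)})

    # chemical origins: herb_fraction herbal (DS or CX, a few both), rest drug
    n_herb = round(config.herb_fraction * config.n_chem)
    herb_idx = set(rng.choice(config.n_chem, size=n_herb, replace=False).tolist())
    chem_origin = {}
    for i, c in enumerate(chems):
        if i in herb_idx:
            r = rng.random()
            if r < 0.1:
                chem_origin[c] = frozenset({"DS", "CX"})  # shared chemicals
            elif r < 0.55:
                chem_origin[c] = frozenset({"DS"})
            else:
                chem_origin[c] = frozenset({"CX"})
        else:
            chem_origin[c] = frozenset({"drug"})

    # CTC: Bernoulli planted-partition over the chemical x target biadjacency
    same = chem_block[:, None] == targ_block[None, :]
    P = np.where(same, config.ctc_p_in, config.ctc_p_out)
    hits = rng.random((config.n_chem, config.n_targ)) < P
    ctc_records = [
        (chems[i], targs[j]) for i, j in zip(*np.nonzero(hits))
    ]

    # targets inherit origin tags from their bound chemicals
    targ_origin = {t: set() for t in targs}
    for c, t in ctc_records:
        targ_origin[t] |= chem_origin[c]
    meta: Dict[str, NodeMeta] = {}
    for c in chems:
        meta[c] = NodeMeta(c, "chemical", chem_origin[c])
    for t in targs:
        origin = frozenset(targ_origin[t]) or frozenset({"drug"})
        meta[t] = NodeMeta(t, "target", origin)

    # fingerprints: block signature bits XOR per-bit flip noise
    signatures = [
        rng.choice(config.fp_len, size=config.fp_block_bits, replace=False)
        for _ in range(config.n_blocks)
    ]
    fingerprints = []
    for i, c in enumerate(chems):
        fp = np.zeros(config.fp_len, dtype=bool)
        fp[signatures[chem_block[i]]] = True
        flips = rng.random(config.fp_len) < config.fp_noise
        fp ^= flips
        fingerprints.append(Fingerprint(c, frozenset(np.nonzero(fp)[0].tolist())))

    # PPI: all within-block target pairs + equally many between-block pairs
    intra = [
        (targs[i], targs[j])
        for i in range(config.n_targ)
        for j in range(i + 1, config.n_targ)
        if targ_block[i] == targ_block[j]
    ]
    ppi_pairs = [
        (u, v, float(np.clip(rng.normal(config.ppi_mu_in, 0.05), 0, 1)))
        for u, v in intra
    ]
    n_inter = len(intra)
    made = 0
    tries = 0
    seen = set(intra)
    while made < n_inter and tries < 50 * n_inter + 1000:
        tries += 1
        i, j = rng.integers(config.n_targ, size=2)
        if i == j or targ_block[i] == targ_block[j]:
            continue
        key = (targs[min(i, j)], targs[max(i, j)])
        if key in seen:
            continue
        seen.add(key)
        ppi_pairs.append(
            (key[0], key[1], float(np.clip(rng.normal(config.ppi_mu_out, 0.05), 0, 1)))
        )
        made += 1

    net = SyntheticNetwork(config, meta, ctc_records, ppi_pairs, fingerprints, blocks)
    if outdir is not None:
        net.write(outdir)
    return net


def expected_ctc_edges(config: GeneratorConfig) -> float:
    """Pair-weighted binomial expectation of the realized CTC edge count."""
    pairs = config.n_chem * config.n_targ
    p_same = 1.0 / config.n_blocks
    return pairs * (p_same * config.ctc_p_in + (1 - p_same) * config.ctc_p_out)
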