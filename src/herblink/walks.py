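"""Second-order biased random walks (node2vec sampling).

The walk interpolates breadth-first and depth-first exploration through the
return parameter ``p`` and the in-out parameter ``q``: having stepped
``t -> v``, the unnormalized weight of the candidate next node ``x`` is

* ``1/p``  if ``x == t`` (returning),
* ``1``    if ``x`` is adjacent to ``t`` (staying near the previous node),
* ``1/q``  otherwise (moving outward),

normalized over the neighbors of ``v``. ``p = q = 1`` recovers the uniform
first-order walk. Walks start from every non-isolated node; a node whose
walk reaches a dead end is recorded shorter.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np


def _adjacency(graph) -> Dict[str, list]:
    return {n: sorted(graph.neighbors(n)) for n in sorted(graph.node_ids)}


def step_probabilities(
    adj: Dict[str, list], t: str, v: str, p: float, q: float
) -> np.ndarray:
    """Transition distribution over ``adj[v]`` given the previous node ``t``."""
    nbrs = adj[v]
    t_nbrs = set(adj[t])
    w = np.empty(len(nbrs))
    for i, x in enumerate(nbrs):
        if x == t:
            w[i] = 1.0 / p
        elif x in t_nbrs:
            w[i] = 1.0
        else:
            w[i] = 1.0 / q
    return w / w.sum()


def biased_walks(graph, params, rng: np.random.Generator | None = None) -> List[List[str]]:
    """Sample ``walks_per_node`` walks of ``walk_length`` nodes from every
    non-isolated node; seeded and reproducible."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    adj = _adjacency(graph)
    starts = [n for n in adj if adj[n]]
    walks: List[List[str]] = []
    p, q = params.p, params.q
    uniform = p == 1.0 and q == 1.0
    for _ in range(params.walks_per_node):
        for start in starts:
            walk = [start]
            while len(walk) < params.walk_length:
                v = walk[-1]
                nbrs = adj[v]
                if not nbrs:
                    break
                if len(walk) == 1 or uniform:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    probs = step_probabilities(adj, walk[-2], v, p, q)
                    nxt = nbrs[rng.choice(len(nbrs), p=probs)]
                walk.append(nxt)
            walks.append(walk)
    return walks
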