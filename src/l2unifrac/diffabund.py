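"""Signed per-edge differential-abundance (flow) vectors.

The flow vector between profiles P and Q is the entrywise difference of
their p=2 aggregated vectors: its entry at a node is the sqrt-branch-
length-scaled difference in subtree mass, read as the flux across the
edge above that node when moving mass from P to match Q. Its Euclidean
norm is exactly the L2-UniFrac distance, so differential abundance comes
for free with the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metric import aggregate
from .profiles import ProfileVector
from .tree import Tree, TreeError

__all__ = ["FlowVector", "differential_abundance", "top_taxa_at_rank"]


@dataclass
class FlowVector:
    """Edge-scaled flow between two profiles; positive where the source
    side carries more subtree mass."""

    values: np.ndarray
    source: str
    target: str
    tree: Tree

    @property
    def l2_norm(self) -> float:
        return float(np.linalg.norm(self.values))


def differential_abundance(P: ProfileVector, Q: ProfileVector, tree: Tree) -> FlowVector:
    """Flow vector aggregate(P, 2) - aggregate(Q, 2).

    The root entry is the difference of total masses, i.e. 0 for valid
    profiles (conservation); the vector is antisymmetric in (P, Q).
    """
    a = aggregate(P, tree, p=2).values
    b = aggregate(Q, tree, p=2).values
    return FlowVector(a - b, P.sample_id, Q.sample_id, tree)


def top_taxa_at_rank(
    flow: FlowVector, tree: Tree, rank: str, k: int, scaled: bool = False
) -> list[tuple[str, float, str]]:
    """Top-k differentially abundant nodes at a taxonomic rank.

    By default magnitudes are the unscaled subtree-mass differences
    (flow entry divided by sqrt(branch length)) so they read as
    abundances; pass ``scaled=True`` to keep the metric-space scaling.
    Returns (node_id, signed difference, dominant side) sorted by
    absolute value descending, ties broken by node id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tree.ranks is None:
        raise TreeError("tree carries no rank annotations")
    nodes = [i for i, nid in enumerate(tree.node_ids) if tree.ranks.get(nid) == rank]
    if not nodes:
        raise TreeError(f"rank {rank!r} not present in tree annotations")

    entries = []
    for i in nodes:
        v = flow.values[i]
        if not scaled and i != tree.n_nodes - 1:
            v = v / np.sqrt(tree.lengths[i])
        side = flow.source if v > 0 else (flow.target if v < 0 else "none")
        entries.append((tree.node_ids[i], float(v), side))
    entries.sort(key=lambda e: (-abs(e[1]), e[0]))
    return entries[:k]
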