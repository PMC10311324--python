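"""Synthetic trees and environment-structured cohorts.

Everything downstream is testable offline: random bifurcating trees with
exponential branch lengths, and cohorts drawn per environment from a
Dirichlet centered on a sparse base profile. One global seed feeds
explicit per-component RNG streams, so adding a generator never perturbs
existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .profiles import LabeledCohort, ProfileVector, write_labels, write_profile_table
from .tree import Tree, write_newick

__all__ = ["SyntheticSpec", "random_tree", "sample_cohort", "write_fixture"]

_MIN_BRANCH = 1e-6
_EPS = 1e-3  # pseudocount against degenerate zero-concentration draws

# fixed stream offsets for the global-seed split
_TREE_STREAM = 0
_COHORT_STREAM = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generator; same spec + seed gives
    bit-identical output."""

    n_leaves: int = 64
    n_environments: int = 4
    samples_per_env: int = 50
    alpha: float = 100.0
    sparsity: float = 0.25
    bl_mean: float = 1.0
    internal_mass_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1 or self.n_environments < 1 or self.samples_per_env < 1:
            raise ValueError("counts must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if not 0 <= self.internal_mass_fraction < 1:
            raise ValueError("internal_mass_fraction must be in [0, 1)")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def random_tree(spec: SyntheticSpec) -> Tree:
    """Random bifurcating rooted tree via sequential leaf attachment.

    ``n_leaves`` leaves give 2n-1 nodes (2 for a single leaf). Branch
    lengths are i.i.d. exponential with mean ``bl_mean``, truncated below
    at 1e-6.
    """
    rng = _stream(spec.seed, _TREE_STREAM)
    n = spec.n_leaves
    children: dict[str, list[str]] = {}
    if n == 1:
        children["root"] = ["L1"]
    else:
        children["root"] = ["L1", "L2"]
        parent = {"L1": "root", "L2": "root"}
        attachable = ["L1", "L2"]
        for k in range(3, n + 1):
            v = attachable[int(rng.integers(len(attachable)))]
            new_int, new_leaf = f"I{k - 2}", f"L{k}"
            p = parent[v]
            children[p][children[p].index(v)] = new_int
            children[new_int] = [v, new_leaf]
            parent[v] = new_int
            parent[new_int] = p
            parent[new_leaf] = new_int
            attachable.extend([new_int, new_leaf])

    # iterative post-order to avoid recursion limits on comb-like trees
    order: list[str] = []
    stack: list[tuple[str, bool]] = [("root", False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children.get(node, [])):
                stack.append((c, False))
    pos = {nid: i for i, nid in enumerate(order)}
    node_ids = order
    parent_map = {c: p for p, cs in children.items() for c in cs}
    parent_idx = [pos[parent_map[nid]] if nid in parent_map else -1 for nid in node_ids]
    lengths = [
        max(float(rng.exponential(spec.bl_mean)), _MIN_BRANCH) if nid in parent_map else np.nan
        for nid in node_ids
    ]
    return Tree(node_ids, parent_idx, lengths)


def sample_cohort(tree: Tree, spec: SyntheticSpec) -> LabeledCohort:
    """Draw an environment-labeled cohort on ``tree``.

    Each environment gets a random leaf support set of size
    ``round(sparsity * n_leaves)`` with a uniform base profile on it;
    samples are Dirichlet(alpha * base + eps) draws restricted to the
    support. ``internal_mass_fraction`` > 0 moves that fraction of each
    sample's mass onto a per-environment random set of internal nodes,
    exercising the taxonomic/WGS pathway.
    """
    rng = _stream(spec.seed, _COHORT_STREAM)
    leaves = tree.leaf_indices()
    internals = tree.internal_indices()
    support_size = max(1, int(round(spec.sparsity * leaves.size)))

    profiles: list[ProfileVector] = []
    labels: dict[str, str] = {}
    for e in range(spec.n_environments):
        env = f"env{e + 1}"
        support = np.sort(rng.choice(leaves, size=support_size, replace=False))
        params = np.full(support_size, spec.alpha / support_size + _EPS)
        if spec.internal_mass_fraction > 0 and internals.size > 0:
            n_int = min(3, internals.size)
            int_nodes = np.sort(rng.choice(internals, size=n_int, replace=False))
        for j in range(spec.samples_per_env):
            v = np.zeros(tree.n_nodes)
            v[support] = rng.dirichlet(params)
            if spec.internal_mass_fraction > 0 and internals.size > 0:
                f = spec.internal_mass_fraction
                v *= 1.0 - f
                v[int_nodes] += f * rng.dirichlet(np.ones(int_nodes.size))
            sid = f"{env}_s{j + 1}"
            profiles.append(ProfileVector(sid, v))
            labels[sid] = env
    return LabeledCohort(tree, profiles, labels)


def write_fixture(tree: Tree, cohort: LabeledCohort, out_dir) -> dict[str, Path]:
    """Write tree.nwk, profiles.tsv, labels.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "profiles": out / "profiles.tsv",
        "labels": out / "labels.tsv",
    }
    write_newick(tree, paths["tree"])
    write_profile_table(cohort, paths["profiles"])
    write_labels(cohort.labels, paths["labels"])
    return paths
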