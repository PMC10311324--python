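"""Rooted trees with branch lengths and their subtree-indicator matrices.

A :class:`Tree` stores nodes in a fixed post-order (every child precedes
its ancestor, root last), which is the traversal order used by the
streaming aggregation transform. The explicit (scaled) subtree-indicator
matrix built by :func:`build_indicator_matrix` is the dense linear-algebra
view of the same transform and serves as its brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "NewickParseError",
    "IndicatorMatrix",
    "parse_newick",
    "read_newick",
    "write_newick",
    "taxonomic_tree_from_lineages",
    "read_lineage_table",
    "read_rank_map",
    "reciprocal_branch_length",
]


class TreeError(ValueError):
    """Invalid tree structure, branch lengths, or node lookup."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


def reciprocal_branch_length(depth: int, node_id: str | None = None) -> float:
    """Default taxonomic branch-length rule: 1/depth, root children at depth 1."""
    return 1.0 / depth


class Tree:
    """A rooted tree with positive branch lengths and a fixed post-order.

    Parameters
    ----------
    node_ids
        Unique string identifiers, listed in post-order (root last).
    parent
        For each node, the index of its ancestor in ``node_ids``;
        ``-1`` for the root. Post-order requires ``parent[i] > i``.
    lengths
        Branch length from each node to its ancestor; the root entry is
        ignored (stored as NaN). All non-root lengths must be > 0.
    ranks
        Optional mapping node id -> rank annotation (e.g. "phylum").
    """

    def __init__(
        self,
        node_ids: Sequence[str],
        parent: Sequence[int],
        lengths: Sequence[float],
        ranks: Mapping[str, str] | None = None,
    ) -> None:
        self.node_ids: list[str] = [str(x) for x in node_ids]
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.ranks: dict[str, str] | None = dict(ranks) if ranks is not None else None
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        self._children: list[list[int]] | None = None
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        n = len(self.node_ids)
        if n == 0:
            raise TreeError("tree must have at least one node")
        if len(self._index) != n:
            seen: set[str] = set()
            dup = next(x for x in self.node_ids if x in seen or seen.add(x))
            raise TreeError(f"duplicate node id: {dup!r}")
        if self.parent.shape != (n,) or self.lengths.shape != (n,):
            raise TreeError("parent/lengths arrays must match node count")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1 or roots[0] != n - 1:
            raise TreeError("exactly one root is required and it must be last in post-order")
        for i in range(n - 1):
            p = int(self.parent[i])
            if not (i < p < n):
                raise TreeError(
                    f"node {self.node_ids[i]!r}: ancestor must come after it in post-order"
                )
            l = self.lengths[i]
            if not np.isfinite(l) or l <= 0:
                raise TreeError(
                    f"node {self.node_ids[i]!r}: branch length must be positive, got {l}"
                )
        self.lengths[n - 1] = np.nan  # root has no branch

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root(self) -> str:
        return self.node_ids[-1]

    def index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"unknown node id: {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def children(self) -> list[list[int]]:
        """Child indices per node, in post-order of the children."""
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i in range(self.n_nodes - 1):
                ch[int(self.parent[i])].append(i)
            self._children = ch
        return self._children

    def is_leaf(self, i: int) -> bool:
        return not self.children()[i]

    def leaf_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if self.is_leaf(i)], dtype=np.int64)

    def internal_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.is_leaf(i)], dtype=np.int64)

    def ancestors(self, i: int) -> list[int]:
        """Indices of strict ancestors of node ``i``, nearest first."""
        out = []
        j = int(self.parent[i])
        while j != -1:
            out.append(j)
            j = int(self.parent[j])
        return out

    def depths(self) -> np.ndarray:
        """Edge-count depth of every node (root depth 0)."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i in range(self.n_nodes - 2, -1, -1):
            d[i] = d[int(self.parent[i])] + 1
        return d

    def subtree_indicator(self, j: int) -> np.ndarray:
        """Unscaled 0/1 row: 1 at every node in the subtree rooted at j."""
        w = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            k = i
            while k != -1:
                if k == j:
                    w[i] = 1.0
                    break
                k = int(self.parent[k])
        return w

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with full float precision on branch lengths."""
        ch = self.children()

        def fmt(i: int) -> str:
            label = self.node_ids[i]
            sub = ""
            if ch[i]:
                sub = "(" + ",".join(fmt(c) for c in ch[i]) + ")"
            if i == self.n_nodes - 1:
                return f"{sub}{label}"
            return f"{sub}{label}:{self.lengths[i]:.17g}"

        return fmt(self.n_nodes - 1) + ";"

    def __repr__(self) -> str:
        return f"Tree(n_nodes={self.n_nodes}, root={self.root!r})"


@dataclass(frozen=True)
class IndicatorMatrix:
    """Dense (scaled) subtree-indicator matrix.

    Row j of :attr:`values` is the subtree indicator of node j scaled by
    ``l(j)**(1/p)`` for non-root j; the root row is the unscaled all-ones
    indicator (its entry in any product is the total profile mass).
    """

    p: int
    values: np.ndarray
    node_ids: tuple[str, ...]


def build_indicator_matrix(tree: Tree, p: int) -> IndicatorMatrix:
    """Build the N x N matrix view of the order-``p`` aggregation transform.

    This is the brute-force oracle for the streaming aggregation: for any
    profile ``P`` aligned to ``tree``, ``values @ P`` equals the aggregated
    vector.
    """
    if p not in (1, 2):
        raise TreeError(f"order p must be 1 or 2, got {p!r}")
    n = tree.n_nodes
    m = np.zeros((n, n))
    # node i contributes to the row of every ancestor-or-self
    for i in range(n):
        m[i, i] = 1.0
        for j in tree.ancestors(i):
            m[j, i] = 1.0
    scale = tree.lengths ** (1.0 / p)
    m[:-1, :] *= scale[:-1, None]
    return IndicatorMatrix(p=p, values=m, node_ids=tuple(tree.node_ids))


# ---------------------------------------------------------------------
# Newick input/output
# ---------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Every non-root edge must carry a positive branch length; a length on
    the root edge is ignored. A redundant unary root above an internal
    node is collapsed; unnamed nodes receive deterministic synthetic ids
    derived from their post-order index.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    seed = dtree.seed_node
    if seed is None:
        raise NewickParseError("malformed Newick: empty tree")
    # collapse wrapper roots: a unary chain above an internal node carries
    # no information for the metric (leaves must stay leaves, so a unary
    # root over a single leaf is kept)
    while len(seed.child_nodes()) == 1 and seed.child_nodes()[0].child_nodes():
        seed = seed.child_nodes()[0]

    nodes = list(seed.postorder_iter())
    pos = {id(nd): i for i, nd in enumerate(nodes)}
    node_ids: list[str] = []
    parent: list[int] = []
    lengths: list[float] = []
    for i, nd in enumerate(nodes):
        label = nd.taxon.label if nd.taxon is not None else nd.label
        node_ids.append(label if label else f"_node{i}")
        if nd is seed:
            parent.append(-1)
            lengths.append(np.nan)
        else:
            parent.append(pos[id(nd.parent_node)])
            l = nd.edge.length
            if l is None:
                raise TreeError(f"node {node_ids[-1]!r}: missing branch length")
            lengths.append(float(l))
    return Tree(node_ids, parent, lengths)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------
# Taxonomic trees from lineage tables
# ---------------------------------------------------------------------


def taxonomic_tree_from_lineages(
    lineages: Iterable[Sequence[str] | str],
    delimiter: str = ";",
    branch_length: Callable[[int, str], float] | None = None,
    rank_names: Sequence[str] | None = None,
) -> Tree:
    """Build a tree from root-to-leaf lineage paths.

    Each lineage is a sequence of node ids starting at the (shared) root.
    Node ids are global: a node appearing in two lineages must have the
    same parent in both. Branch lengths default to the reciprocal rule
    ``l = 1/depth`` with root children at depth 1; pass ``branch_length``
    to substitute another convention.

    ``rank_names[d-1]`` annotates nodes at depth ``d`` (e.g.
    ``["phylum", "genus"]``); the root is left unranked.
    """
    if branch_length is None:
        branch_length = reciprocal_branch_length

    parent_of: dict[str, str] = {}
    child_order: dict[str, list[str]] = {}
    root: str | None = None
    for row in lineages:
        path = [x.strip() for x in (row.split(delimiter) if isinstance(row, str) else row)]
        path = [x for x in path if x]
        if not path:
            continue
        if root is None:
            root = path[0]
        elif path[0] != root:
            raise TreeError(f"lineages disagree on the root: {root!r} vs {path[0]!r}")
        for par, child in zip(path, path[1:]):
            if child in parent_of:
                if parent_of[child] != par:
                    raise TreeError(
                        f"conflicting parentage for node {child!r}: "
                        f"{parent_of[child]!r} vs {par!r}"
                    )
            else:
                parent_of[child] = par
                child_order.setdefault(par, []).append(child)
    if root is None:
        raise TreeError("no lineages provided")
    if root in parent_of:
        raise TreeError(f"root {root!r} also appears as a child")

    node_ids: list[str] = []
    parent_ids: list[str | None] = []
    depths: list[int] = []

    def visit(node: str, depth: int, par: str | None) -> None:
        for c in child_order.get(node, []):
            visit(c, depth + 1, node)
        node_ids.append(node)
        parent_ids.append(par)
        depths.append(depth)

    visit(root, 0, None)
    pos = {nid: i for i, nid in enumerate(node_ids)}
    parent = [pos[p] if p is not None else -1 for p in parent_ids]
    lengths = [
        branch_length(d, nid) if p is not None else np.nan
        for nid, p, d in zip(node_ids, parent_ids, depths)
    ]
    ranks = None
    if rank_names is not None:
        ranks = {
            nid: rank_names[d - 1]
            for nid, d in zip(node_ids, depths)
            if 1 <= d <= len(rank_names)
        }
    return Tree(node_ids, parent, lengths, ranks=ranks)


def read_lineage_table(path, delimiter: str = ";", **kwargs) -> Tree:
    """Read a text file with one lineage per line (see
    :func:`taxonomic_tree_from_lineages`)."""
    with open(path) as fh:
        rows = [line.strip() for line in fh if line.strip()]
    return taxonomic_tree_from_lineages(rows, delimiter=delimiter, **kwargs)


def read_rank_map(path) -> dict[str, str]:
    """Read a two-column TSV ``node_id<TAB>rank`` into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TreeError(f"rank map line must have 2 columns: {line!r}")
            out[fields[0]] = fields[1]
    return out
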