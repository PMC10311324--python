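"""Streaming aggregation transform, its exact inverse, and the UniFrac metrics.

The order-``p`` aggregation pushes abundance mass rootward in a single
post-order pass, scaling each node's entry by ``l(node)**(1/p)`` once its
subtree mass is complete; the root entry stays unscaled and equals the
total mass. For ``p=2`` the Euclidean norm of the difference of two
aggregated vectors is the L2-UniFrac distance; for ``p=1`` the L1 norm
gives the classical UniFrac, i.e. 1-Wasserstein on the tree.

The streaming pass is O(N) per profile; the dense matrix route in
:mod:`l2unifrac.tree` exists only as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .profiles import LabeledCohort, ProfileVector
from .tree import Tree, TreeError

__all__ = [
    "AggregatedVector",
    "InverseResult",
    "DistanceMatrix",
    "aggregate",
    "aggregate_matrix",
    "inverse_aggregate",
    "inverse_aggregate_matrix",
    "l1_unifrac",
    "l2_unifrac",
    "pairwise_distances",
    "reset_counters",
    "get_counters",
]

NEG_TOL = 1e-12

# operation counters used by the complexity probes: the aggregated-space
# clustering route must do O(M) aggregations and zero pairwise norms
_counters = {"aggregations": 0, "pairwise_norms": 0}


def reset_counters() -> None:
    _counters["aggregations"] = 0
    _counters["pairwise_norms"] = 0


def get_counters() -> dict[str, int]:
    return dict(_counters)


def _check_p(p: int) -> None:
    if p not in (1, 2):
        raise ValueError(f"order p must be 1 or 2, got {p!r}")


@dataclass
class AggregatedVector:
    """A profile's image in order-``p`` UniFrac space."""

    sample_id: str
    values: np.ndarray
    p: int
    tree: Tree

    @property
    def total_mass(self) -> float:
        """Root entry: the total mass of the source profile."""
        return float(self.values[-1])


@dataclass
class InverseResult:
    """Result of the inverse aggregation.

    For inputs in the image of ``aggregate`` this is the original
    profile; for arbitrary vectors it may contain negative entries,
    which are returned unclamped with ``n_negative`` counting entries
    below ``-1e-12``.
    """

    values: np.ndarray
    n_negative: int


def _aggregate_rows(x: np.ndarray, tree: Tree, p: int) -> np.ndarray:
    """One post-order pass over the columns of an (M, N) array."""
    x = np.array(x, dtype=float)
    par = tree.parent
    scale = tree.lengths ** (1.0 / p)
    for i in range(tree.n_nodes - 1):
        x[:, par[i]] += x[:, i]  # push subtree mass to the ancestor
        x[:, i] *= scale[i]
    return x


def _inverse_rows(a: np.ndarray, tree: Tree, p: int) -> np.ndarray:
    """Exact algebraic inverse of :func:`_aggregate_rows`.

    Unscale every non-root entry back to its subtree mass, then remove
    each child's subtree mass from its ancestor's entry, leaving each
    node's own mass.
    """
    a = np.array(a, dtype=float)
    par = tree.parent
    scale = tree.lengths ** (1.0 / p)
    a[:, :-1] /= scale[:-1]
    # reverse post-order: a node's entry is still its full subtree mass
    # when it is removed from the ancestor, and only afterwards is it
    # itself reduced by its children
    for i in range(tree.n_nodes - 2, -1, -1):
        a[:, par[i]] -= a[:, i]
    return a


def aggregate(profile: ProfileVector, tree: Tree, p: int = 2) -> AggregatedVector:
    """Map a profile into order-``p`` UniFrac space (single linear pass).

    Equals the product of the explicit indicator matrix with the profile;
    the transform is linear and exactly invertible.
    """
    _check_p(p)
    if profile.values.shape != (tree.n_nodes,):
        raise TreeError(
            f"profile length {profile.values.size} does not match tree "
            f"node count {tree.n_nodes}"
        )
    _counters["aggregations"] += 1
    out = _aggregate_rows(profile.values[None, :], tree, p)[0]
    return AggregatedVector(profile.sample_id, out, p, tree)


def aggregate_matrix(x: np.ndarray, tree: Tree, p: int = 2) -> np.ndarray:
    """Aggregate every row of an (M, N) profile matrix at once."""
    _check_p(p)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != tree.n_nodes:
        raise TreeError(f"profile matrix has {x.shape[1]} columns, tree has {tree.n_nodes} nodes")
    _counters["aggregations"] += x.shape[0]
    return _aggregate_rows(x, tree, p)


def inverse_aggregate(
    agg: AggregatedVector, tree: Tree | None = None, p: int | None = None
) -> InverseResult:
    """Invert the aggregation transform.

    ``tree``/``p``, if given, must match the ones the vector was
    aggregated with. Round-trips exactly:
    ``inverse_aggregate(aggregate(P)) == P`` to within 1e-10.
    """
    if tree is not None and tree is not agg.tree and tree.node_ids != agg.tree.node_ids:
        raise TreeError("aggregated vector was produced on a different tree")
    if p is not None and p != agg.p:
        raise ValueError(f"aggregated vector has p={agg.p}, requested p={p}")
    values = _inverse_rows(agg.values[None, :], agg.tree, agg.p)[0]
    return InverseResult(values, int(np.sum(values < -NEG_TOL)))


def inverse_aggregate_matrix(a: np.ndarray, tree: Tree, p: int = 2) -> np.ndarray:
    _check_p(p)
    return _inverse_rows(np.atleast_2d(np.asarray(a, dtype=float)), tree, p)


def _pair_distance(P: ProfileVector, Q: ProfileVector, tree: Tree, p: int) -> float:
    a = aggregate(P, tree, p).values
    b = aggregate(Q, tree, p).values
    _counters["pairwise_norms"] += 1
    diff = a - b
    return float(np.linalg.norm(diff, ord=p))


def l2_unifrac(P: ProfileVector, Q: ProfileVector, tree: Tree) -> float:
    """L2-UniFrac distance: Euclidean norm of the aggregated difference."""
    return _pair_distance(P, Q, tree, 2)


def l1_unifrac(P: ProfileVector, Q: ProfileVector, tree: Tree) -> float:
    """Classical (L1) UniFrac distance; equals the 1-Wasserstein
    (earth mover's) distance between the profiles on the tree metric."""
    return _pair_distance(P, Q, tree, 1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distance matrix must be non-negative")

    def to_tsv(self, path, phylip: bool = False) -> None:
        with open(path, "w") as fh:
            if phylip:
                fh.write(f"{len(self.sample_ids)}\n")
                for sid, row in zip(self.sample_ids, self.values):
                    fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
            else:
                fh.write("sample_id\t" + "\t".join(self.sample_ids) + "\n")
                for sid, row in zip(self.sample_ids, self.values):
                    fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric)


def pairwise_distances(
    cohort: LabeledCohort, metric: str = "l2", tree: Tree | None = None
) -> DistanceMatrix:
    """All-pairs UniFrac distances (aggregation done once per sample)."""
    if metric not in ("l1", "l2"):
        raise ValueError(f"metric must be 'l1' or 'l2', got {metric!r}")
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    t = tree if tree is not None else cohort.tree
    p = 1 if metric == "l1" else 2
    agg = aggregate_matrix(cohort.matrix(), t, p)
    m = cohort.n_samples
    _counters["pairwise_norms"] += m * (m - 1) // 2
    condensed = pdist(agg, metric="cityblock" if p == 1 else "euclidean")
    return DistanceMatrix(cohort.sample_ids, squareform(condensed), metric)
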