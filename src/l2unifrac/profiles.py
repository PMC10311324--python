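"""Per-sample abundance profiles aligned to a tree's node order."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Tree, TreeError

__all__ = [
    "ProfileVector",
    "LabeledCohort",
    "ProfileError",
    "profile_from_values",
    "push_to_nodes",
    "read_profile_table",
    "write_profile_table",
    "read_labels",
    "write_labels",
]

SUM_TOL = 1e-8
UNLABELED = "unassigned"


class ProfileError(ValueError):
    """Invalid abundance profile."""


@dataclass
class ProfileVector:
    """A relative-abundance probability vector over tree nodes.

    ``values`` is indexed by the tree's post-order; mass on internal
    nodes is allowed (taxonomic/WGS profiles use it).
    """

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, tree: Tree) -> "ProfileVector":
        if self.values.shape != (tree.n_nodes,):
            raise ProfileError(
                f"sample {self.sample_id!r}: profile length {self.values.size} "
                f"does not match tree node count {tree.n_nodes}"
            )
        if np.any(self.values < 0):
            raise ProfileError(f"sample {self.sample_id!r}: negative abundance")
        if abs(self.values.sum() - 1.0) > SUM_TOL:
            raise ProfileError(
                f"sample {self.sample_id!r}: abundances sum to {self.values.sum():.6g}, not 1"
            )
        return self


def profile_from_values(
    tree: Tree,
    values: Sequence[float],
    sample_id: str = "sample",
    renormalize: bool = False,
) -> ProfileVector:
    """Wrap raw values as a validated :class:`ProfileVector`."""
    v = np.asarray(values, dtype=float)
    if v.shape != (tree.n_nodes,):
        raise ProfileError(
            f"sample {sample_id!r}: profile length {v.size} does not match "
            f"tree node count {tree.n_nodes}"
        )
    if np.any(v < 0):
        raise ProfileError(f"sample {sample_id!r}: negative abundance")
    total = v.sum()
    if renormalize:
        if total <= 0:
            raise ProfileError(f"sample {sample_id!r}: all-zero profile")
        v = v / total
    return ProfileVector(sample_id, v).validate(tree)


@dataclass
class LabeledCohort:
    """A set of profiles on one tree, with environment labels."""

    tree: Tree
    profiles: list[ProfileVector]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.profiles:
            p.validate(self.tree)
            self.labels.setdefault(p.sample_id, UNLABELED)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    @property
    def n_samples(self) -> int:
        return len(self.profiles)

    def matrix(self) -> np.ndarray:
        """Stack profiles as an (n_samples, n_nodes) array."""
        return np.array([p.values for p in self.profiles])

    def environments(self) -> list[str]:
        return sorted({self.labels[s] for s in self.sample_ids})

    def by_environment(self) -> dict[str, list[ProfileVector]]:
        out: dict[str, list[ProfileVector]] = {}
        for p in self.profiles:
            out.setdefault(self.labels[p.sample_id], []).append(p)
        return out

    def subset(self, sample_ids: Iterable[str]) -> "LabeledCohort":
        wanted = list(sample_ids)
        by_id = {p.sample_id: p for p in self.profiles}
        return LabeledCohort(
            self.tree,
            [by_id[s] for s in wanted],
            {s: self.labels[s] for s in wanted},
        )


def push_to_nodes(
    assignments: Mapping[str, float], tree: Tree, sample_id: str = "sample"
) -> ProfileVector:
    """Place masses directly on named nodes (internal or leaf) and normalize.

    No redistribution to leaves is performed: mass assigned to an internal
    node stays there.
    """
    v = np.zeros(tree.n_nodes)
    for node_id, mass in assignments.items():
        if mass < 0:
            raise ProfileError(f"negative mass {mass} for node {node_id!r}")
        v[tree.index(node_id)] += mass
    return profile_from_values(tree, v, sample_id, renormalize=True)


# ---------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------


def read_profile_table(
    path,
    tree: Tree,
    labels: Mapping[str, str] | None = None,
    renormalize: bool = False,
    on_unknown: str = "error",
) -> LabeledCohort:
    """Read a sample x feature TSV into a cohort aligned to ``tree``.

    The first column holds sample ids; remaining columns are tree node
    ids. Features absent from the table are zero. ``on_unknown`` is
    ``"error"`` (default) or ``"drop"`` for feature ids not in the tree.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in tree]
    if unknown:
        if on_unknown == "error":
            raise ProfileError(f"feature ids not in tree: {unknown}")
        if on_unknown != "drop":
            raise ValueError(f"on_unknown must be 'error' or 'drop', got {on_unknown!r}")
        import warnings

        warnings.warn(f"dropping {len(unknown)} unknown feature ids: {unknown[:5]}...")
        df = df.drop(columns=unknown)

    cols = np.array([tree.index(c) for c in df.columns], dtype=np.int64)
    profiles = []
    for sample_id, row in zip(df.index, df.to_numpy(dtype=float)):
        v = np.zeros(tree.n_nodes)
        np.add.at(v, cols, row)
        if v.sum() <= 0:
            raise ProfileError(f"sample {sample_id!r}: all-zero profile")
        profiles.append(profile_from_values(tree, v, str(sample_id), renormalize=renormalize))
    lbl = dict(labels) if labels is not None else {}
    return LabeledCohort(tree, profiles, lbl)


def write_profile_table(cohort: LabeledCohort, path) -> None:
    """Write a cohort as a sample x node TSV (all tree nodes as columns)."""
    df = pd.DataFrame(
        cohort.matrix(), index=cohort.sample_ids, columns=cohort.tree.node_ids
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, environment); header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "environment"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tenvironment\n")
        for sid, env in labels.items():
            fh.write(f"{sid}\t{env}\n")
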