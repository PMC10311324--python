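"""Environment representatives: the L2 barycenter and the failing L1 analog.

The L2 barycenter of a cohort — the minimizer of the sum of squared
L2-UniFrac distances — is computed by aggregating, taking the
component-wise mean in aggregated space, and inverting. By linearity of
the transform this equals the component-wise mean of the raw profiles,
so the result always lies on the probability simplex. The analogous
median construction under the L1 metric does not: projecting the
component-wise median of L1-aggregated vectors back to profile space can
produce negative abundances, which :func:`l1_median_demo` surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metric import (
    aggregate_matrix,
    inverse_aggregate_matrix,
    l2_unifrac,
    NEG_TOL,
)
from .profiles import ProfileVector
from .tree import Tree

__all__ = [
    "RepresentativeSample",
    "l2_barycenter",
    "l1_median_demo",
    "barycenter_distance",
    "environment_representatives",
]


@dataclass
class RepresentativeSample:
    """An environment's representative profile.

    ``method`` is ``"l2_mean"`` (valid profile, simplex-guaranteed) or
    ``"l1_median"`` (no simplex guarantee; negativity recorded).
    """

    profile: ProfileVector
    environment: str
    n_samples: int
    method: str


def l2_barycenter(
    profiles: Sequence[ProfileVector], tree: Tree, environment: str = ""
) -> RepresentativeSample:
    """Barycenter of a profile collection under squared L2-UniFrac.

    Computed via aggregate -> component-wise mean -> inverse, then
    verified at runtime to coincide with the component-wise mean of the
    raw profiles (to within 1e-10), which certifies simplex membership.
    """
    if len(profiles) == 0:
        raise ValueError("cannot take the barycenter of an empty collection")
    x = np.array([p.values for p in profiles])
    agg = aggregate_matrix(x, tree, p=2)
    center = inverse_aggregate_matrix(agg.mean(axis=0), tree, p=2)[0]
    direct_mean = x.mean(axis=0)
    err = np.max(np.abs(center - direct_mean))
    if err > 1e-10:
        raise RuntimeError(
            f"aggregate->mean->inverse deviates from the component-wise mean "
            f"by {err:.3g}; the tree or profiles are inconsistent"
        )
    # float noise from the inverse route can leave entries at ~-1e-16
    center = np.clip(center, 0.0, None)
    center = center / center.sum()
    sid = f"{environment}_representative" if environment else "representative"
    prof = ProfileVector(sid, center).validate(tree)
    return RepresentativeSample(prof, environment, len(profiles), "l2_mean")


def l1_median_demo(
    profiles: Sequence[ProfileVector], tree: Tree
) -> tuple[np.ndarray, int]:
    """Component-wise median in L1-aggregated space, projected back.

    Demonstrates why the L1 analog of the barycenter fails: the returned
    vector is unclamped and may contain negative entries; the count of
    entries below -1e-12 is returned alongside. Not a usable average.

    For even cohort sizes the lower of the two middle values is taken
    (any point between them is a valid L1 median; a deterministic choice
    is needed for reproducibility).
    """
    if len(profiles) < 2:
        raise ValueError("median demo needs at least 2 profiles")
    x = np.array([p.values for p in profiles])
    agg = aggregate_matrix(x, tree, p=1)
    med = np.sort(agg, axis=0)[(len(profiles) - 1) // 2]
    values = inverse_aggregate_matrix(med, tree, p=1)[0]
    return values, int(np.sum(values < -NEG_TOL))


def barycenter_distance(
    env_a: RepresentativeSample, env_b: RepresentativeSample, tree: Tree
) -> float:
    """L2-UniFrac distance between two l2_mean representatives — the
    single computation that replaces averaging all cross-environment
    pairwise distances."""
    for r in (env_a, env_b):
        if r.method != "l2_mean":
            raise ValueError(f"representative {r.environment!r} has method {r.method!r}; "
                             "barycenter_distance requires l2_mean")
    return l2_unifrac(env_a.profile, env_b.profile, tree)


def environment_representatives(cohort, method: str = "l2_mean") -> dict:
    """One representative per environment of a labeled cohort.

    For ``method="l1_median"`` the values are ``(vector, n_negative)``
    tuples from :func:`l1_median_demo` instead of
    :class:`RepresentativeSample` objects.
    """
    groups = cohort.by_environment()
    if method == "l2_mean":
        return {
            env: l2_barycenter(profs, cohort.tree, environment=env)
            for env, profs in sorted(groups.items())
        }
    if method == "l1_median":
        return {
            env: l1_median_demo(profs, cohort.tree)
            for env, profs in sorted(groups.items())
        }
    raise ValueError(f"unknown method {method!r}")
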