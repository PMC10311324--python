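"""Clustering in aggregated space, clustering evaluation, and
nearest-representative classification.

Two clustering routes are compared: k-means directly on p=2 aggregated
vectors (where the Euclidean norm IS the L2-UniFrac distance, so no
pairwise matrix is ever materialized) and PAM k-medoids on a precomputed
distance matrix. Classification assigns each test sample to the
environment whose barycenter is nearest in L2-UniFrac.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .barycenter import l2_barycenter
from .metric import DistanceMatrix, aggregate_matrix
from .profiles import LabeledCohort, ProfileVector
from .tree import Tree

__all__ = [
    "ClusteringResult",
    "ClassificationResult",
    "cluster_in_l2_space",
    "cluster_on_distance_matrix",
    "fowlkes_mallows",
    "classify_nearest_representative",
    "train_test_split_cohort",
    "majority_vote_report",
]


@dataclass
class ClusteringResult:
    assignment: dict[str, int]
    method: str
    k: int
    seed: int
    centers: np.ndarray | None = None
    inertia: float | None = None


@dataclass
class ClassificationResult:
    predictions: dict[str, str]
    truth: dict[str, str]
    accuracy: float
    per_class: dict[str, dict[str, int]] = field(default_factory=dict)
    scores: dict[str, dict[str, float]] = field(default_factory=dict)


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")


def cluster_in_l2_space(
    cohort: LabeledCohort, k: int, seed: int, tree: Tree | None = None
) -> ClusteringResult:
    """Lloyd's k-means (k-means++ init, 10 restarts) on aggregated vectors.

    Euclidean geometry in the aggregated space coincides with L2-UniFrac,
    so this clusters under the metric while doing only O(M) aggregations
    and no pairwise distance computations.
    """
    _check_k(k, cohort.n_samples)
    t = tree if tree is not None else cohort.tree
    agg = aggregate_matrix(cohort.matrix(), t, p=2)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed, max_iter=300)
    labels = km.fit_predict(agg)
    return ClusteringResult(
        assignment=dict(zip(cohort.sample_ids, map(int, labels))),
        method="kmeans_l2_space",
        k=k,
        seed=seed,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def cluster_on_distance_matrix(dmat: DistanceMatrix, k: int, seed: int) -> ClusteringResult:
    """PAM k-medoids (greedy BUILD + best-improvement SWAP) on a
    precomputed distance matrix. Deterministic for a fixed input."""
    d = np.asarray(dmat.values, dtype=float)
    n = d.shape[0]
    _check_k(k, n)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < -1e-12):
        raise ValueError("distance matrix must be non-negative")

    # BUILD: start from the most central point, then greedily add the
    # medoid that lowers total assignment cost the most
    medoids = [int(np.argmin(d.sum(axis=0)))]
    mind = d[:, medoids[0]].copy()
    while len(medoids) < k:
        cands = [i for i in range(n) if i not in medoids]
        costs = np.minimum(mind[:, None], d[:, cands]).sum(axis=0)
        best = cands[int(np.argmin(costs))]
        medoids.append(best)
        mind = np.minimum(mind, d[:, best])

    # SWAP: replace (medoid, candidate) pairs while total cost improves
    def total_cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    improved = True
    it = 0
    while improved and it < 100:
        improved = False
        it += 1
        best_swap, best_cost = None, cost
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                c = total_cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            cost = best_cost
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    for ci, m in enumerate(medoids):  # a medoid belongs to its own cluster
        labels[m] = ci
    return ClusteringResult(
        assignment=dict(zip(dmat.sample_ids, map(int, labels))),
        method="kmedoids_pam",
        k=k,
        seed=seed,
        inertia=cost,
    )


def fowlkes_mallows(assignment: Mapping[str, int], truth: Mapping[str, object]) -> float:
    """Pair-counting Fowlkes-Mallows score TP/sqrt((TP+FP)(TP+FN)).

    TP counts sample pairs co-clustered in both partitions, FP pairs
    co-clustered only in ``assignment``, FN only in ``truth``. Identical
    partitions score 1; score 0 when either partition has no co-clustered
    pair.
    """
    if set(assignment) != set(truth):
        raise ValueError("assignment and truth must cover the same samples")
    samples = sorted(assignment)
    pred = [assignment[s] for s in samples]
    true = [truth[s] for s in samples]
    n = len(samples)
    pi = {c: i for i, c in enumerate(dict.fromkeys(pred))}
    ti = {c: i for i, c in enumerate(dict.fromkeys(true))}
    cont = np.zeros((len(ti), len(pi)), dtype=np.int64)
    for p, t in zip(pred, true):
        cont[ti[t], pi[p]] += 1
    tk = float((cont**2).sum() - n)  # 2*TP
    pk = float((cont.sum(axis=0) ** 2).sum() - n)  # 2*(TP+FP)
    qk = float((cont.sum(axis=1) ** 2).sum() - n)  # 2*(TP+FN)
    if pk == 0 or qk == 0:
        return 0.0
    return float(tk / np.sqrt(pk * qk))


def train_test_split_cohort(
    cohort: LabeledCohort, fraction: float, seed: int
) -> tuple[LabeledCohort, LabeledCohort]:
    """Stratified train/test split by environment, deterministic per seed."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for env, profs in sorted(cohort.by_environment().items()):
        ids = [p.sample_id for p in profs]
        if len(ids) < 2:
            raise ValueError(f"environment {env!r} has fewer than 2 samples; cannot stratify")
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[i] for i in perm[:n_train])
        test_ids.extend(ids[i] for i in perm[n_train:])
    return cohort.subset(train_ids), cohort.subset(test_ids)


def classify_nearest_representative(
    train: LabeledCohort,
    test_profiles: Sequence[ProfileVector],
    tree: Tree | None = None,
    test_truth: Mapping[str, str] | None = None,
) -> ClassificationResult:
    """Assign each test sample to the environment with the nearest
    (L2-UniFrac) training barycenter; ties go to the alphabetically
    first environment."""
    t = tree if tree is not None else train.tree
    groups = train.by_environment()
    envs = sorted(groups)
    if not envs:
        raise ValueError("training cohort is empty")
    for env, profs in groups.items():
        if len(profs) == 0:
            raise ValueError(f"environment {env!r} has no training samples")
    reps = np.array(
        [l2_barycenter(groups[e], t, environment=e).profile.values for e in envs]
    )
    rep_agg = aggregate_matrix(reps, t, p=2)
    test_agg = aggregate_matrix(np.array([p.values for p in test_profiles]), t, p=2)
    dists = np.linalg.norm(test_agg[:, None, :] - rep_agg[None, :, :], axis=2)
    picks = np.argmin(dists, axis=1)  # first minimum = alphabetical tie-break
    predictions = {p.sample_id: envs[i] for p, i in zip(test_profiles, picks)}

    truth = dict(test_truth) if test_truth is not None else {}
    correct = sum(1 for s, e in predictions.items() if truth.get(s) == e)
    accuracy = correct / len(predictions) if truth else float("nan")

    per_class: dict[str, dict[str, int]] = {}
    scores: dict[str, dict[str, float]] = {}
    if truth:
        for env in sorted(set(truth.values()) | set(envs)):
            tp = sum(1 for s in predictions if truth.get(s) == env and predictions[s] == env)
            fp = sum(1 for s in predictions if truth.get(s) != env and predictions[s] == env)
            fn = sum(1 for s in predictions if truth.get(s) == env and predictions[s] != env)
            per_class[env] = {"tp": tp, "fp": fp, "fn": fn}
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            scores[env] = {"precision": prec, "recall": rec, "f1": f1}
    return ClassificationResult(predictions, truth, accuracy, per_class, scores)


def majority_vote_report(
    clustering: ClusteringResult, truth: Mapping[str, str]
) -> dict:
    """Label clusters by majority vote against ``truth`` — the baseline
    comparison harness. Reports label collisions (two clusters voting the
    same environment) and environments left without a cluster instead of
    hiding them."""
    votes: dict[int, dict[str, int]] = {}
    for sid, c in clustering.assignment.items():
        votes.setdefault(c, {})[truth[sid]] = votes.setdefault(c, {}).get(truth[sid], 0) + 1
    cluster_label = {
        c: max(sorted(v), key=lambda e: v[e]) for c, v in votes.items()
    }
    labels = list(cluster_label.values())
    collisions = sorted({l for l in labels if labels.count(l) > 1})
    missing = sorted(set(truth.values()) - set(labels))
    predictions = {sid: cluster_label[c] for sid, c in clustering.assignment.items()}
    correct = sum(1 for s in predictions if predictions[s] == truth[s])
    return {
        "predictions": predictions,
        "accuracy": correct / len(predictions),
        "cluster_labels": cluster_label,
        "label_collisions": collisions,
        "unrepresented_environments": missing,
    }
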