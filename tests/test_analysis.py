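import numpy as np
import pytest
from sklearn.metrics import fowlkes_mallows_score

from l2unifrac import (
    LabeledCohort,
    ProfileVector,
    classify_nearest_representative,
    cluster_in_l2_space,
    cluster_on_distance_matrix,
    fowlkes_mallows,
    l2_barycenter,
    majority_vote_report,
    pairwise_distances,
    train_test_split_cohort,
)
from l2unifrac.metric import DistanceMatrix, get_counters, reset_counters
from l2unifrac.synthetic import SyntheticSpec, random_tree, sample_cohort

from _oracles import fowlkes_mallows_by_pair_enumeration
from conftest import make_tree


@pytest.fixture(scope="module")
def fixture_cohort():
    spec = SyntheticSpec()  # 4 environments x 50 samples, seed 0
    tree = random_tree(spec)
    return tree, sample_cohort(tree, spec)


def duplicated_cohort(t0):
    """Two zero-variance point clouds on the toy tree."""
    profs, labels = [], {}
    for i in range(4):
        profs.append(ProfileVector(f"a{i}", [1.0, 0.0, 0.0]))
        labels[f"a{i}"] = "envA"
        profs.append(ProfileVector(f"b{i}", [0.0, 1.0, 0.0]))
        labels[f"b{i}"] = "envB"
    return LabeledCohort(t0, profs, labels)


class TestClusterInL2Space:
    def test_duplicated_profiles_perfect_separation(self, t0):
        cohort = duplicated_cohort(t0)
        result = cluster_in_l2_space(cohort, 2, seed=0)
        assert fowlkes_mallows(result.assignment, cohort.labels) == 1.0

    def test_k1_single_cluster(self, t0):
        cohort = duplicated_cohort(t0)
        result = cluster_in_l2_space(cohort, 1, seed=0)
        assert set(result.assignment.values()) == {0}

    def test_k_out_of_range(self, t0):
        cohort = duplicated_cohort(t0)
        with pytest.raises(ValueError, match="k must be"):
            cluster_in_l2_space(cohort, 9, seed=0)

    def test_seed_determinism(self, fixture_cohort):
        tree, cohort = fixture_cohort
        a = cluster_in_l2_space(cohort, 4, seed=3)
        b = cluster_in_l2_space(cohort, 4, seed=3)
        assert a.assignment == b.assignment

    def test_fixture_separation(self, fixture_cohort):
        tree, cohort = fixture_cohort
        result = cluster_in_l2_space(cohort, 4, seed=0)
        assert fowlkes_mallows(result.assignment, cohort.labels) >= 0.9


class TestClusterOnDistanceMatrix:
    def test_duplicated_profiles_perfect_separation(self, t0):
        cohort = duplicated_cohort(t0)
        dmat = pairwise_distances(cohort, "l2")
        result = cluster_on_distance_matrix(dmat, 2, seed=0)
        assert fowlkes_mallows(result.assignment, cohort.labels) == 1.0

    def test_k_equals_n(self, t0):
        cohort = duplicated_cohort(t0)
        dmat = pairwise_distances(cohort, "l2")
        result = cluster_on_distance_matrix(dmat, cohort.n_samples, seed=0)
        # every sample its own medoid cluster
        assert len(set(result.assignment.values())) == cohort.n_samples

    def test_asymmetric_matrix_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "l2")
        d.values = np.array([[0.0, 1.0], [2.0, 0.0]])  # corrupt after validation
        with pytest.raises(ValueError, match="symmetric"):
            cluster_on_distance_matrix(d, 1, seed=0)

    def test_agrees_with_l2_space_on_fixture(self, fixture_cohort):
        tree, cohort = fixture_cohort
        fm_kmeans = fowlkes_mallows(
            cluster_in_l2_space(cohort, 4, seed=0).assignment, cohort.labels
        )
        dmat = pairwise_distances(cohort, "l2")
        fm_kmedoids = fowlkes_mallows(
            cluster_on_distance_matrix(dmat, 4, seed=0).assignment, cohort.labels
        )
        assert abs(fm_kmeans - fm_kmedoids) <= 0.15


class TestFowlkesMallows:
    def test_identical_partitions(self):
        a = {"s1": 0, "s2": 0, "s3": 1}
        assert fowlkes_mallows(a, a) == 1.0

    def test_orthogonal_partitions(self):
        truth = {"1": "x", "2": "x", "3": "y", "4": "y"}
        pred = {"1": 0, "3": 0, "2": 1, "4": 1}
        assert fowlkes_mallows(pred, truth) == 0.0

    def test_hand_computed_example(self):
        truth = {"1": "a", "2": "a", "3": "a", "4": "b"}
        pred = {"1": 0, "2": 0, "3": 1, "4": 1}
        # TP=1, FP=1, FN=2 by pair enumeration
        assert fowlkes_mallows(pred, truth) == pytest.approx(1 / np.sqrt(6), abs=1e-12)

    def test_label_set_mismatch(self):
        with pytest.raises(ValueError, match="same samples"):
            fowlkes_mallows({"a": 0}, {"b": 0})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(20)]
        pred = {s: int(rng.integers(3)) for s in samples}
        truth = {s: int(rng.integers(4)) for s in samples}
        ours = fowlkes_mallows(pred, truth)
        assert ours == pytest.approx(
            fowlkes_mallows_by_pair_enumeration(pred, truth), abs=1e-12
        )
        skl = fowlkes_mallows_score(
            [truth[s] for s in samples], [pred[s] for s in samples]
        )
        assert ours == pytest.approx(skl, abs=1e-12)


class TestTrainTestSplit:
    def _cohort(self, t0, per_env=10):
        rng = np.random.default_rng(0)
        profs, labels = [], {}
        for env in ("a", "b"):
            for i in range(per_env):
                sid = f"{env}{i}"
                profs.append(ProfileVector(sid, rng.dirichlet(np.ones(3))))
                labels[sid] = env
        return LabeledCohort(t0, profs, labels)

    def test_80_20_counts(self, t0):
        cohort = self._cohort(t0)
        train, test = train_test_split_cohort(cohort, 0.8, seed=0)
        for env in ("a", "b"):
            assert sum(1 for s in train.sample_ids if train.labels[s] == env) == 8
            assert sum(1 for s in test.sample_ids if test.labels[s] == env) == 2

    def test_seed_determinism(self, t0):
        cohort = self._cohort(t0)
        t1 = train_test_split_cohort(cohort, 0.8, seed=5)
        t2 = train_test_split_cohort(cohort, 0.8, seed=5)
        assert t1[0].sample_ids == t2[0].sample_ids
        assert t1[1].sample_ids == t2[1].sample_ids

    def test_fraction_bounds(self, t0):
        cohort = self._cohort(t0)
        with pytest.raises(ValueError, match="fraction"):
            train_test_split_cohort(cohort, 1.0, seed=0)

    def test_small_class_rejected(self, t0):
        cohort = LabeledCohort(
            t0,
            [ProfileVector("s1", [1.0, 0, 0]), ProfileVector("s2", [0, 1.0, 0])],
            {"s1": "a", "s2": "b"},
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            train_test_split_cohort(cohort, 0.8, seed=0)


class TestClassification:
    def test_representative_classified_to_own_environment(self, fixture_cohort):
        tree, cohort = fixture_cohort
        groups = cohort.by_environment()
        reps = {
            env: l2_barycenter(profs, tree, environment=env)
            for env, profs in groups.items()
        }
        test_profiles = [r.profile for r in reps.values()]
        result = classify_nearest_representative(cohort, test_profiles, tree)
        for env, rep in reps.items():
            assert result.predictions[rep.profile.sample_id] == env

    def test_fixture_accuracy(self, fixture_cohort):
        tree, cohort = fixture_cohort
        train, test = train_test_split_cohort(cohort, 0.8, seed=0)
        result = classify_nearest_representative(
            train, test.profiles, tree, test_truth=test.labels
        )
        assert result.accuracy >= 0.9
        assert set(result.scores) >= set(cohort.environments())

    def test_equidistant_tie_breaks_alphabetically(self, t0):
        train = LabeledCohort(
            t0,
            [ProfileVector("x1", [1.0, 0, 0]), ProfileVector("y1", [0, 0, 1.0])],
            {"x1": "beta", "y1": "alpha"},
        )
        # symmetric construction: equidistant from both representatives
        # (d(mid, eA) = d(mid, eR) on the toy tree along the A edge)
        mid = ProfileVector("mid", [0.5, 0.0, 0.5])
        result = classify_nearest_representative(train, [mid], t0)
        assert result.predictions["mid"] == "alpha"

    def test_empty_training_rejected(self, t0):
        cohort = LabeledCohort(t0, [], {})
        with pytest.raises(ValueError, match="empty"):
            classify_nearest_representative(cohort, [ProfileVector("m", [1, 0, 0])], t0)


class TestComplexityProbe:
    def test_l2_route_never_materializes_pairwise(self, fixture_cohort):
        tree, cohort = fixture_cohort
        m = cohort.n_samples
        reset_counters()
        cluster_in_l2_space(cohort, 4, seed=0)
        c = get_counters()
        assert c["aggregations"] == m
        assert c["pairwise_norms"] == 0

        reset_counters()
        dmat = pairwise_distances(cohort, "l2")
        cluster_on_distance_matrix(dmat, 4, seed=0)
        c = get_counters()
        assert c["aggregations"] == m
        assert c["pairwise_norms"] == m * (m - 1) // 2


class TestMajorityVote:
    def test_collision_surfaced(self):
        from l2unifrac.analysis import ClusteringResult

        truth = {"s1": "a", "s2": "a", "s3": "a", "s4": "b"}
        clustering = ClusteringResult(
            {"s1": 0, "s2": 0, "s3": 1, "s4": 1}, "kmeans", 2, 0
        )
        report = majority_vote_report(clustering, truth)
        assert report["label_collisions"] == ["a"]
        assert report["unrepresented_environments"] == ["b"]

    def test_clean_vote(self):
        from l2unifrac.analysis import ClusteringResult

        truth = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
        clustering = ClusteringResult(
            {"s1": 0, "s2": 0, "s3": 1, "s4": 1}, "kmeans", 2, 0
        )
        report = majority_vote_report(clustering, truth)
        assert report["accuracy"] == 1.0
        assert report["label_collisions"] == []


def test_kmeans_objective_nonincreasing(fixture_cohort):
    # inertia of the kept run must not exceed a single-restart run
    tree, cohort = fixture_cohort
    best = cluster_in_l2_space(cohort, 4, seed=0)
    from l2unifrac.metric import aggregate_matrix
    from sklearn.cluster import KMeans

    agg = aggregate_matrix(cohort.matrix(), tree, 2)
    single = KMeans(n_clusters=4, n_init=1, random_state=0, max_iter=300).fit(agg)
    assert best.inertia <= single.inertia_ + 1e-9
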