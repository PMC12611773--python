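import numpy as np
import pytest
from scipy.stats import special_ortho_group

from softalign.evaluation import (
    RELATION_LEVELS,
    bootstrap_ci,
    distance_change_by_level,
    entropy_rt_correlation,
    exclude_participants,
    majority_response,
    noise_ceiling_loo,
    preprocess_rts,
    relative_improvement,
    rsa_spearman,
    rsm,
)
from softalign.sampling import sample_random_triplets
from softalign.synthetic import AnnotatorModel, generate_hierarchy, simulate_responses
from softalign.triplets import batch_choice_probabilities, batch_pair_similarities


class TestRSM:
    def test_duplicated_rows_unit_similarity(self, rng):
        X = rng.normal(size=(5, 6))
        X[1] = X[0]
        for kernel in ("pearson", "cosine"):
            M = rsm(X, kernel).matrix
            assert M[0, 1] == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(np.diag(M), 1.0, atol=1e-12)
            np.testing.assert_allclose(M, M.T, atol=1e-12)

    def test_antipodal_cosine(self, rng):
        X = rng.normal(size=(3, 4))
        X[1] = -X[0]
        assert rsm(X, "cosine").matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_equals_cosine_of_centred_rows(self, rng):
        X = rng.normal(size=(8, 10))
        centred = X - X.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(
            rsm(X, "pearson").matrix, rsm(centred, "cosine").matrix, atol=1e-12
        )

    def test_constant_row_rejected_with_row_named(self):
        X = np.ones((3, 4))
        X[0] = [1, 2, 3, 4]
        with pytest.raises(ValueError, match="row 1"):
            rsm(X, "pearson")


class TestRSASpearman:
    def test_identity(self, rng):
        a = rsm(rng.normal(size=(10, 5)), "pearson")
        assert rsa_spearman(a, a) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        a = rsm(rng.normal(size=(10, 5)), "pearson")
        from softalign.evaluation import RSM

        b = RSM(np.tanh(3 * a.matrix) + 0.1 * a.matrix, "pearson")
        assert rsa_spearman(a, b) == pytest.approx(1.0)

    def test_independent_rsms_near_zero(self):
        rhos = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rsm(rng.normal(size=(100, 8)), "pearson")
            b = rsm(rng.normal(size=(100, 8)), "pearson")
            rhos.append(rsa_spearman(a, b))
        assert abs(np.mean(rhos)) < 0.05
        assert np.max(np.abs(rhos)) < 0.12

    def test_symmetry(self, rng):
        a = rsm(rng.normal(size=(9, 4)), "pearson")
        b = rsm(rng.normal(size=(9, 4)), "pearson")
        assert rsa_spearman(a, b) == pytest.approx(rsa_spearman(b, a))

    def test_dimension_mismatch(self, rng):
        a = rsm(rng.normal(size=(5, 4)), "pearson")
        b = rsm(rng.normal(size=(6, 4)), "pearson")
        with pytest.raises(ValueError):
            rsa_spearman(a, b)


class TestMajorityResponse:
    def test_strict_modes(self):
        assert majority_response([3, 1, 1]) == 0
        assert majority_response([0, 0, 5]) == 2

    def test_tie_breaks_roughly_uniform(self):
        picks = [majority_response([2, 2, 1], seed=s) for s in range(400)]
        freq0 = np.mean([p == 0 for p in picks])
        assert 0.4 < freq0 < 0.6
        assert set(picks) == {0, 1}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            majority_response([0, 0, 0])


class TestNoiseCeiling:
    def test_unanimous_is_one(self):
        assert noise_ceiling_loo([[0, 0, 0], [2, 2, 2, 2], [1, 1]]) == 1.0

    def test_uniform_random_near_third(self):
        rng = np.random.default_rng(0)
        groups = [rng.integers(0, 3, size=5).tolist() for _ in range(2000)]
        value = noise_ceiling_loo(groups, seed=1)
        # held-out uniform choice matches any majority with probability 1/3
        se = np.sqrt((1 / 3) * (2 / 3) / (2000 * 5))
        assert abs(value - 1 / 3) < 4 * se

    def test_two_always_disagreeing_annotators(self):
        assert noise_ceiling_loo([[0, 1], [2, 0], [1, 2]]) == 0.0

    def test_single_response_triplets_excluded(self):
        assert noise_ceiling_loo([[0], [1, 1]]) == 1.0
        with pytest.raises(ValueError):
            noise_ceiling_loo([[0], [1]])


class TestPreprocessRTs:
    def test_log_identity_and_bounds(self):
        log_rts, mask = preprocess_rts([1.0, 12.0, 10.0, 0.5])
        assert log_rts[0] == pytest.approx(0.0)
        assert mask.tolist() == [True, False, True, True]  # >10 s excluded, ==10 s kept

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            preprocess_rts([1.0, 0.0])


class TestExcludeParticipants:
    def test_rules(self):
        keep = exclude_participants(
            catch_accuracy=[0.95, 0.89, 1.0, 0.90], n_missing=[2, 0, 11, 10]
        )
        assert keep.tolist() == [True, False, False, True]

    def test_bad_accuracy_rejected(self):
        with pytest.raises(ValueError):
            exclude_participants([1.2], [0])


class TestEntropyRTCorrelation:
    def test_monotone_link_is_one(self, rng):
        e = rng.uniform(0, 1, size=50)
        assert entropy_rt_correlation(e, np.exp(2 * e)) == pytest.approx(1.0)

    def test_end_to_end_simulation(self):
        # modest spreads so pair similarities keep the softmax unsaturated
        space = generate_hierarchy(3, 2, 4, 6, (1.2, 0.8, 0.5), seed=0)
        trips = sample_random_triplets(space.n_items, 400, seed=1)
        annot = AnnotatorModel(temperature=2.0, lapse_rate=0.05, rt_slope=1.5, rt_noise_sd=0.2)
        resp = simulate_responses(space, trips, annot, 5, seed=2)
        log_rts, mask = preprocess_rts(resp.rt_seconds)
        mean_log_rt = np.array(
            [log_rts[mask][np.all(resp.triplets[mask] == t, axis=1)].mean() for t in trips]
        )
        sims = batch_pair_similarities(space.embeddings, trips)
        p = batch_choice_probabilities(sims, annot.temperature)
        ent = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        ok = ~np.isnan(mean_log_rt)
        assert entropy_rt_correlation(ent[ok], mean_log_rt[ok]) > 0.4

    def test_shuffled_pairing_near_zero(self, rng):
        rhos = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            e = r.uniform(0, 1, 200)
            rts = np.exp(e + 0.1 * r.normal(size=200))
            rhos.append(entropy_rt_correlation(e, r.permutation(rts)))
        assert abs(np.mean(rhos)) < 0.05


@pytest.fixture(scope="module")
def space():
    return generate_hierarchy(3, 2, 6, 5, (8.0, 2.0, 0.5), seed=3)


class TestDistanceChangeByLevel:

    def test_identity_checkpoint_all_zero(self, space):
        out = distance_change_by_level(space.embeddings, space.embeddings, space)
        assert {c.relation_level for c in out} <= set(RELATION_LEVELS)
        for c in out:
            assert c.mean_z_change == pytest.approx(0.0, abs=1e-12)
            assert c.n_pairs >= 1

    def test_global_scaling_invariance(self, space, rng):
        X_after = space.embeddings + 0.3 * rng.normal(size=space.embeddings.shape)
        base = distance_change_by_level(space.embeddings, X_after, space)
        scaled = distance_change_by_level(2.0 * space.embeddings, 5.0 * X_after, space)
        for c1, c2 in zip(base, scaled):
            assert c1.mean_z_change == pytest.approx(c2.mean_z_change, abs=1e-9)

    def test_rotation_invariance(self, space):
        Q1 = special_ortho_group.rvs(space.dim, random_state=0)
        Q2 = special_ortho_group.rvs(space.dim, random_state=1)
        rng = np.random.default_rng(2)
        X_after = space.embeddings + 0.3 * rng.normal(size=space.embeddings.shape)
        base = distance_change_by_level(space.embeddings, X_after, space)
        rotated = distance_change_by_level(space.embeddings @ Q1, X_after @ Q2, space)
        for c1, c2 in zip(base, rotated):
            assert c1.mean_z_change == pytest.approx(c2.mean_z_change, abs=1e-9)

    def test_directional_change_when_categories_tighten(self, space):
        # pull items halfway toward their basic-category centroids
        X = space.embeddings
        X_after = X.copy()
        for b in np.unique(space.basic_label):
            rows = space.basic_label == b
            X_after[rows] = 0.3 * X[rows] + 0.7 * X[rows].mean(axis=0)
        out = {c.relation_level: c.mean_z_change for c in
               distance_change_by_level(X, X_after, space)}
        assert out["same_basic"] < 0
        assert out["different_superordinate"] > 0

    def test_item_mismatch(self, space):
        with pytest.raises(ValueError):
            distance_change_by_level(space.embeddings[:-1], space.embeddings[:-1], space)


class TestBootstrapCI:
    def test_constant_scores_zero_width(self):
        mean, lo, hi = bootstrap_ci(np.full(100, 0.7), seed=0)
        assert mean == pytest.approx(0.7)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_determinism(self):
        scores = np.random.default_rng(0).random(500)
        assert bootstrap_ci(scores, seed=4) == bootstrap_ci(scores, seed=4)

    def test_coverage_on_bernoulli(self):
        covered = 0
        reps = 200
        for outer in range(reps):
            rng = np.random.default_rng(outer)
            scores = (rng.random(1000) < 0.5).astype(float)
            _, lo, hi = bootstrap_ci(scores, n_boot=100, sample_size=1000, seed=outer + 10_000)
            covered += lo <= 0.5 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestRelativeImprovement:
    def test_worked_example(self):
        assert relative_improvement(44.24, 61.7) == pytest.approx(39.47, abs=0.01)

    def test_zero_baseline(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 1.0)
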