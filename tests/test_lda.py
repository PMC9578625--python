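import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from shifttyper import SUBSET_III, SpinSystem
from shifttyper.lda import (
    Classification,
    LdaModel,
    ScalingState,
    TrainingTable,
    ZeroVarianceError,
    classify,
    classify_batch,
    fit,
    fit_class_stats,
    fit_restricted,
    pareto_scale,
    pareto_scaling_state,
    pooled_covariance,
    posterior_probabilities,
)

from conftest import random_instance


def simple_table(points_by_class, names=("CA",)):
    rows, labels = [], []
    for cls_, pts in points_by_class.items():
        for p in pts:
            rows.append(p if isinstance(p, (list, tuple)) else [p])
            labels.append(cls_)
    return TrainingTable(tuple(names), np.array(rows, float), np.array(labels, object))


def fit_on(points_by_class, names=("CA",)):
    table = simple_table(points_by_class, names)
    state = ScalingState(tuple(names), np.zeros(len(names)), np.ones(len(names)))
    return fit(table, state)


class TestParetoScaling:
    def test_hand_computed_example(self):
        # train {0, 2}, test {4}: mean 2, population sd sqrt(8/3),
        # divisor = sqrt(sd), scaled test value = 2 / divisor
        state = pareto_scaling_state(
            np.array([[0.0], [2.0]]), np.array([[4.0]]), ("CA",)
        )
        sd = np.sqrt(8.0 / 3.0)
        assert state.center[0] == pytest.approx(2.0)
        assert state.scale[0] == pytest.approx(np.sqrt(sd))  # ~1.27789
        assert state.transform(np.array([[4.0]]))[0, 0] == pytest.approx(1.56508, abs=1e-5)

    def test_zero_variance_column_errors(self):
        with pytest.raises(ZeroVarianceError, match="CA"):
            pareto_scaling_state(np.array([[1.0], [1.0]]), np.array([[1.0]]), ("CA",))

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(50, 3, size=(20, 2))
        state = pareto_scaling_state(X, None, ("CA", "CB"))
        back = state.inverse_transform(state.transform(X))
        np.testing.assert_allclose(back, X, rtol=1e-12)

    def test_operation_scales_train_and_test_jointly(self):
        table = simple_table({"A": [[0.0], [2.0]], "G": [[1.0], [3.0]]})
        test = [SpinSystem("q", {"CA": 4.0})]
        scaled_table, scaled_test, state = pareto_scale(table, test)
        combined = np.array([0.0, 2.0, 1.0, 3.0, 4.0])
        expect_center = combined.mean()
        expect_scale = np.sqrt(combined.std())
        assert state.center[0] == pytest.approx(expect_center)
        assert scaled_test[0].shifts["CA"] == pytest.approx(
            (4.0 - expect_center) / expect_scale
        )
        np.testing.assert_allclose(
            scaled_table.values[:, 0], (table.values[:, 0] - expect_center) / expect_scale
        )


class TestClassStats:
    def test_population_covariance_hand_example(self):
        table = simple_table({"A": [1.0, 3.0], "G": [0.0, 2.0]})
        classes, means, covs = fit_class_stats(table)
        assert classes == ["A", "G"]
        assert means[0, 0] == pytest.approx(2.0)
        # population normalization: var({1,3}) = 1, not 2
        assert covs[0][0, 0] == pytest.approx(1.0)

    def test_identical_points_zero_covariance(self):
        table = simple_table({"A": [5.0, 5.0, 5.0], "G": [0.0, 1.0]})
        _, _, covs = fit_class_stats(table)
        assert covs[0][0, 0] == pytest.approx(0.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(12, 2))
        labels = np.array(["A"] * 6 + ["G"] * 6, object)
        t1 = TrainingTable(("CA", "CB"), rows, labels)
        perm = rng.permutation(12)
        t2 = TrainingTable(("CA", "CB"), rows[perm], labels[perm])
        _, m1, c1 = fit_class_stats(t1)
        _, m2, c2 = fit_class_stats(t2)
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(c1, c2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            simple_table({"A": [1.0], "G": [0.0, 2.0]})


class TestPooledCovariance:
    def test_identical_covariances(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        pooled = pooled_covariance(np.array([C, C]), np.array([3, 7]), 10)
        np.testing.assert_allclose(pooled, C)

    def test_single_class(self):
        C = np.array([[1.5]])
        np.testing.assert_allclose(pooled_covariance(np.array([C]), np.array([4]), 4), C)

    def test_weighted_hand_example(self):
        covs = np.array([[[1.0]], [[3.0]]])
        pooled = pooled_covariance(covs, np.array([2, 2]), 4)
        assert pooled[0, 0] == pytest.approx(2.0)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum to N"):
            pooled_covariance(np.array([[[1.0]]]), np.array([2]), 5)


class TestDiscriminantScores:
    def test_nearest_mean_under_identity_covariance(self):
        rng = np.random.default_rng(7)
        means = rng.normal(0, 5, size=(4, 3))
        model = LdaModel(
            ("CA", "CB", "HA"), ["A", "C", "D", "E"], means,
            np.eye(3), np.eye(3), np.full(4, 0.25),
            ScalingState(("CA", "CB", "HA"), np.zeros(3), np.ones(3)),
        )
        for _ in range(200):
            x = rng.normal(0, 5, size=3)
            nearest = np.argmin(np.linalg.norm(means - x, axis=1))
            assert model.predict(x) == [model.classes[nearest]]

    def test_class_mean_wins_with_equal_priors(self):
        rng = np.random.default_rng(8)
        means = rng.normal(0, 5, size=(3, 2))
        model = LdaModel(
            ("CA", "CB"), ["A", "C", "D"], means, np.eye(2), np.eye(2),
            np.full(3, 1 / 3), ScalingState(("CA", "CB"), np.zeros(2), np.ones(2)),
        )
        for k in range(3):
            scores = model.discriminant_scores(means[k])
            assert np.argmax(scores) == k
            diffs = scores[k] - np.delete(scores, k)
            np.testing.assert_array_compare(np.greater_equal, diffs, 0)

    def test_agrees_with_gaussian_density_oracle(self):
        rng = np.random.default_rng(9)
        means, cov, X, y = random_instance(rng, n_classes=2, n_features=2, n_per_class=30)
        table = TrainingTable(
            ("CA", "CB"), X, np.array([["A", "G"][i] for i in y], object)
        )
        state = ScalingState(("CA", "CB"), np.zeros(2), np.ones(2))
        model = fit(table, state)
        for _ in range(50):
            x = rng.normal(0, 3, size=2)
            scores = model.discriminant_scores(x)
            oracle = np.array([
                np.log(model.priors[k])
                + multivariate_normal.logpdf(x, model.means[k], model.pooled_cov)
                for k in range(2)
            ])
            # equal up to a class-independent constant
            np.testing.assert_allclose(
                scores - scores[0], oracle - oracle[0], atol=1e-9
            )

    def test_dimension_mismatch(self):
        model = fit_on({"A": [0.0, 1.0], "G": [5.0, 6.0]})
        with pytest.raises(ValueError, match="features"):
            model.discriminant_scores(np.array([1.0, 2.0]))


class TestPosterior:
    def test_two_equal_scores(self):
        np.testing.assert_allclose(posterior_probabilities(np.array([3.0, 3.0])), [0.5, 0.5])

    def test_log3_example(self):
        np.testing.assert_allclose(
            posterior_probabilities(np.array([0.0, np.log(3.0)])), [0.25, 0.75]
        )

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.floats(-100, 100))
    def test_shift_invariance_and_normalization(self, scores, const):
        scores = np.array(scores)
        p1 = posterior_probabilities(scores)
        p2 = posterior_probabilities(scores + const)
        assert p1.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        top = np.sort(scores)
        if len(top) < 2 or top[-1] - top[-2] > 1e-9:  # order only meaningful then
            assert np.argmax(p1) == np.argmax(scores)

    def test_monotone_in_each_score(self):
        base = np.array([0.0, 1.0, -2.0])
        bumped = base.copy()
        bumped[2] += 0.5
        assert posterior_probabilities(bumped)[2] > posterior_probabilities(base)[2]


class TestQda:
    def test_equal_covariances_reduce_to_lda(self):
        rng = np.random.default_rng(11)
        means, cov, X, y = random_instance(rng, n_classes=3, n_features=2, n_per_class=25)
        labels = np.array([["A", "G", "S"][i] for i in y], object)
        model = fit(
            TrainingTable(("CA", "CB"), X, labels),
            ScalingState(("CA", "CB"), np.zeros(2), np.ones(2)),
        )
        # replace every class covariance by the pooled one
        model.per_class_cov = np.stack([model.pooled_cov] * 3)
        for _ in range(100):
            x = rng.normal(0, 3, size=2)
            assert np.argmax(model.qda_scores(x)) == np.argmax(model.discriminant_scores(x))

    def test_unequal_variances_against_density_oracle(self):
        # two 1-D classes, equal means, very different variances
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.5, 40)
        b = rng.normal(0, 4.0, 40)
        table = TrainingTable(
            ("CA",), np.concatenate([a, b])[:, None],
            np.array(["A"] * 40 + ["G"] * 40, object),
        )
        model = fit(table, ScalingState(("CA",), np.zeros(1), np.ones(1)))
        for x in np.linspace(-8, 8, 33):
            scores = model.qda_scores(np.array([x]))
            oracle = [
                np.log(model.priors[k]) + multivariate_normal.logpdf(
                    x, model.means[k, 0], model.per_class_cov[k, 0, 0]
                )
                for k in range(2)
            ]
            assert np.argmax(scores) == np.argmax(oracle)

    def test_boundary_is_nonlinear_in_x(self):
        # far from the shared mean the wide-variance class must win on both sides
        rng = np.random.default_rng(13)
        a = rng.normal(0, 0.5, 60)
        b = rng.normal(0, 4.0, 60)
        table = TrainingTable(
            ("CA",), np.concatenate([a, b])[:, None],
            np.array(["A"] * 60 + ["G"] * 60, object),
        )
        model = fit(table, ScalingState(("CA",), np.zeros(1), np.ones(1)))
        assert model.predict(np.array([8.0]), method="qda") == ["G"]
        assert model.predict(np.array([-8.0]), method="qda") == ["G"]
        assert model.predict(np.array([0.0]), method="qda") == ["A"]


class TestFit:
    def test_twenty_class_model(self, training_spins):
        table = TrainingTable.from_spin_systems(
            training_spins, SUBSET_III.shift_names
        )
        state = pareto_scaling_state(table.values, None, table.shift_names)
        model = fit(TrainingTable(table.shift_names, state.transform(table.values), table.labels), state)
        # Gly/Pro are incomplete for the full subset; the rest fit
        assert len(model.classes) >= 15
        assert model.priors.sum() == pytest.approx(1.0)
        # pooled covariance recomputable from stored per-class statistics
        counts = np.array([model.class_counts[c] for c in model.classes])
        recomputed = np.tensordot(counts / counts.sum(), model.per_class_cov, axes=1)
        np.testing.assert_allclose(recomputed, model.pooled_cov, atol=1e-10)

    def test_row_duplication_leaves_model_unchanged(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 2))
        labels = np.array(["A"] * 10 + ["G"] * 10, object)
        state = ScalingState(("CA", "CB"), np.zeros(2), np.ones(2))
        m1 = fit(TrainingTable(("CA", "CB"), X, labels), state)
        m2 = fit(
            TrainingTable(("CA", "CB"), np.vstack([X, X]), np.concatenate([labels, labels])),
            state,
        )
        np.testing.assert_allclose(m1.means, m2.means)
        np.testing.assert_allclose(m1.pooled_cov, m2.pooled_cov)
        np.testing.assert_allclose(m1.priors, m2.priors)

    def test_single_class_degenerate_model(self):
        model = fit_on({"A": [0.0, 1.0, 2.0]})
        assert model.predict(np.array([100.0])) == ["A"]
        assert model.priors[0] == pytest.approx(1.0)

    def test_json_round_trip(self, training_spins):
        table = TrainingTable.from_spin_systems(training_spins, ("CA", "CB"))
        state = pareto_scaling_state(table.values, None, table.shift_names)
        model = fit(TrainingTable(table.shift_names, state.transform(table.values), table.labels), state)
        clone = LdaModel.from_json(model.to_json())
        np.testing.assert_allclose(clone.means, model.means)
        np.testing.assert_allclose(clone.pooled_cov, model.pooled_cov)
        np.testing.assert_allclose(clone.priors, model.priors)
        assert clone.classes == model.classes
        x = np.zeros(2)
        np.testing.assert_allclose(
            clone.discriminant_scores(x), model.discriminant_scores(x), rtol=1e-9
        )


class TestRestrictedModels:
    def test_full_query_equals_full_subset_model(self, training_spins):
        query = np.array([[8.2, 120.0, 176.0, 55.0, 30.0, 4.4, 2.0]])
        restricted = fit_restricted(
            training_spins, SUBSET_III.shift_names, None, query
        )
        table = TrainingTable.from_spin_systems(training_spins, SUBSET_III.shift_names)
        state = pareto_scaling_state(table.values, query, table.shift_names)
        direct = fit(
            TrainingTable(table.shift_names, state.transform(table.values), table.labels),
            state,
        )
        np.testing.assert_allclose(restricted.means, direct.means)
        assert restricted.classes == direct.classes

    def test_glycine_query_uses_five_columns(self, training_spins):
        gly = SpinSystem(
            "g", {"HN": 8.3, "N": 108.8, "CO": 174.9, "CA": 45.1, "HA": 3.96}
        )
        result = classify(gly, training_spins, SUBSET_III, None)
        assert result.shifts_used == ("HN", "N", "CO", "CA", "HA")
        # training glycines retained: G must be among the scored classes
        assert "G" in result.probabilities
        assert result.predicted == "G"

    def test_proline_query_uses_six_columns(self, training_spins):
        pro = SpinSystem(
            "p", {"N": 137.0, "CO": 177.3, "CA": 63.3, "CB": 32.1, "HA": 4.42, "HB": 2.05}
        )
        result = classify(pro, training_spins, SUBSET_III, None)
        assert result.shifts_used == ("N", "CO", "CA", "CB", "HA", "HB")
        assert result.predicted == "P"

    def test_empty_required_class_warns(self, training_spins, caplog):
        no_trp = [s for s in training_spins if s.residue_type != "W"]
        query = np.array([[55.0, 30.0]])
        with caplog.at_level("WARNING"):
            fit_restricted(no_trp, ("CA", "CB"), {"A", "W"}, query)
        assert any("no usable training rows" in r.message for r in caplog.records)

    def test_structurally_absent_class_not_warned(self, training_spins, caplog):
        query = np.array([[55.0, 30.0]])
        with caplog.at_level("WARNING"):
            fit_restricted(training_spins, ("CA", "CB"), {"A", "G"}, query)
        assert not any("no usable training rows" in r.message for r in caplog.records)


class TestClassify:
    def test_query_at_class_mean_confident(self, separated_model, training_spins):
        means = separated_model.means["A"]
        query = SpinSystem("q", dict(means))
        result = classify(query, training_spins, SUBSET_III, None)
        assert result.predicted == "A"
        assert result.probabilities["A"] > 0.99

    def test_determinism(self, training_spins):
        query = SpinSystem("q", {"CA": 52.0, "CB": 19.0, "HA": 4.3, "HB": 1.4})
        r1 = classify(query, training_spins, SUBSET_III, None)
        r2 = classify(query, training_spins, SUBSET_III, None)
        assert r1.scores == r2.scores
        assert r1.predicted == r2.predicted

    def test_removing_shift_changes_only_columns(self, training_spins):
        full = SpinSystem("q", {"CA": 52.0, "CB": 19.0, "HA": 4.3, "HB": 1.4})
        partial = SpinSystem("q", {"CA": 52.0, "CB": 19.0, "HA": 4.3})
        r_full = classify(full, training_spins, SUBSET_III, None)
        r_part = classify(partial, training_spins, SUBSET_III, None)
        assert r_full.shifts_used == ("CA", "CB", "HA", "HB")
        assert r_part.shifts_used == ("CA", "CB", "HA")

    def test_no_usable_shifts_errors(self, training_spins):
        query = SpinSystem("q", {"HN": 8.2})
        with pytest.raises(ValueError, match="no usable shifts"):
            classify(query, training_spins, type(SUBSET_III)("custom", ("CA", "CB")), None)

    def test_probabilities_sum_to_one(self, training_spins):
        query = SpinSystem("q", {"CA": 56.0, "CB": 30.0})
        result = classify(query, training_spins, SUBSET_III, None)
        assert sum(result.probabilities.values()) == pytest.approx(1.0)
        assert max(result.probabilities, key=result.probabilities.get) == result.predicted
        assert isinstance(result, Classification)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_oracle_equivalence_property(seed):
    """argmax of the linear scores equals the shared-covariance Bayes oracle."""
    rng = np.random.default_rng(seed)
    means, cov, X, y = random_instance(rng)
    labels = np.array([chr(ord("A") + i) for i in y], object)
    table = TrainingTable(("HN", "N", "CO", "CA")[: X.shape[1]], X, labels)
    model = fit(table, ScalingState(table.shift_names, np.zeros(X.shape[1]), np.ones(X.shape[1])))
    for _ in range(10):
        x = rng.normal(0, 3, size=X.shape[1])
        scores = model.discriminant_scores(x)
        oracle = np.array([
            np.log(model.priors[k])
            + multivariate_normal.logpdf(
                x, model.means[k], model.pooled_cov, allow_singular=True
            )
            for k in range(len(model.classes))
        ])
        assert np.argmax(scores) == np.argmax(oracle)
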