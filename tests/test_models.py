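import numpy as np
import pytest

from metalinprog.io_tables import LabelSet
from metalinprog.models import (
    BinaryModel,
    MulticlassModel,
    binary_objective,
    decision_binary,
    encode_labels,
    fit_binary,
    fit_multiclass,
    multiclass_objective,
    predict_binary,
    predict_class,
    predict_proba,
    selected_features,
)

from conftest import random_binary_instance
from test_lp_core import brute_force_binary_1d


def make_binary(beta, beta0=0.0, ids=None):
    beta = np.asarray(beta, dtype=float)
    ids = ids or [f"f{j + 1}" for j in range(beta.size)]
    return BinaryModel(beta0=beta0, beta=beta, lam=0.1,
                       transform="arcsine", feature_ids=ids)


class TestEncoding:
    def test_two_class_column(self):
        labels = LabelSet(["s1", "s2", "s3"], ["A", "B", "A"])
        enc = encode_labels(labels)
        assert enc.classes == ["A", "B"] and enc.reference == "B"
        np.testing.assert_array_equal(enc.Y, [[1.0], [-1.0], [1.0]])

    def test_three_class_matrix(self):
        labels = LabelSet(["s1", "s2", "s3"], ["A", "B", "C"])
        enc = encode_labels(labels)
        np.testing.assert_array_equal(
            enc.Y, [[1.0, -1], [-1, 1], [-1, -1]]
        )

    def test_each_row_at_most_one_positive(self):
        rng = np.random.default_rng(0)
        labs = [f"c{i}" for i in rng.integers(0, 4, size=30)]
        labels = LabelSet([f"s{i}" for i in range(30)], labs)
        enc = encode_labels(labels)
        assert np.all((enc.Y == 1).sum(axis=1) <= 1)

    def test_reference_override(self):
        labels = LabelSet(["s1", "s2", "s3"], ["A", "B", "C"])
        enc = encode_labels(labels, reference="A")
        assert enc.classes[-1] == "A"

    def test_empty_class_rejected(self):
        labels = LabelSet(["s1", "s2"], ["A", "B"], classes=["A", "B", "C"])
        with pytest.raises(ValueError, match="C"):
            encode_labels(labels)


class TestBinaryFit:
    def test_separable_1d_matches_grid_oracle(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model = fit_binary(x[:, None], y, 0.1)
        assert model.beta[0] > 0
        assert np.all(predict_binary(model, x[:, None]) == y)
        achieved = binary_objective(x[:, None], y, model.beta0, model.beta, 0.1)
        expected = brute_force_binary_1d(x, y, 0.1)
        assert achieved == pytest.approx(expected, abs=1e-3)

    def test_huge_lambda_empties_model(self):
        rng = np.random.default_rng(1)
        Xt, y = random_binary_instance(rng, n=10, m=4)
        model = fit_binary(Xt, y, 1e3)
        np.testing.assert_allclose(model.beta, 0, atol=1e-8)

    def test_sample_duplication_lambda_doubling_identity(self):
        rng = np.random.default_rng(2)
        Xt, y = random_binary_instance(rng, n=6, m=2)
        lam = 0.2
        base = fit_binary(Xt, y, lam)
        dup = fit_binary(np.vstack([Xt, Xt]), np.concatenate([y, y]), 2 * lam)
        # optima may be non-unique; compare achieved objective values
        base_obj = binary_objective(Xt, y, base.beta0, base.beta, lam)
        dup_at_base = binary_objective(Xt, y, dup.beta0, dup.beta, lam)
        assert dup_at_base == pytest.approx(base_obj, abs=1e-6)

    def test_objective_reevaluation_matches_lp_optimum(self):
        from metalinprog.lp_core import assemble_binary_lp, solve_lp

        rng = np.random.default_rng(3)
        for _ in range(25):
            Xt, y = random_binary_instance(rng)
            lam = float(rng.uniform(0.01, 1.0))
            model = fit_binary(Xt, y, lam)
            direct = binary_objective(Xt, y, model.beta0, model.beta, lam)
            lp_value = solve_lp(assemble_binary_lp(Xt, y, lam)).objective_value
            assert direct == pytest.approx(lp_value, abs=1e-6)


class TestBinaryPrediction:
    def test_constant_model_scores(self):
        model = make_binary([0.0, 0.0], beta0=0.7)
        np.testing.assert_allclose(
            decision_binary(model, np.eye(2)), [0.7, 0.7]
        )

    def test_one_hot_scores(self):
        model = make_binary([1.5, -2.0], beta0=0.25)
        np.testing.assert_allclose(
            decision_binary(model, np.eye(2)), [1.75, -1.75]
        )

    def test_affine_combination_identity(self):
        rng = np.random.default_rng(4)
        model = make_binary(rng.normal(size=3), beta0=0.4)
        x1, x2 = rng.normal(size=(2, 3))
        a = 0.3
        mixed = decision_binary(model, (a * x1 + (1 - a) * x2)[None])[0]
        s1 = decision_binary(model, x1[None])[0]
        s2 = decision_binary(model, x2[None])[0]
        assert mixed == pytest.approx(a * s1 + (1 - a) * s2, abs=1e-12)

    @pytest.mark.parametrize("score,expected", [(2.3, 1), (-0.1, -1), (0.0, 1)])
    def test_sign_rule_with_tie_to_positive(self, score, expected):
        model = make_binary([0.0], beta0=score)
        assert predict_binary(model, np.zeros((1, 1)))[0] == expected

    def test_feature_mismatch_rejected(self):
        model = make_binary([1.0, 2.0])
        with pytest.raises(ValueError, match="mismatch"):
            decision_binary(model, np.zeros((2, 3)))


class TestMulticlass:
    def _labels(self, labs):
        return LabelSet([f"s{i}" for i in range(len(labs))], list(labs))

    def test_c2_predictions_match_binary(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            Xt, y = random_binary_instance(rng, n=8, m=3)
            labels = self._labels(["P" if v > 0 else "N" for v in y])
            lam = float(rng.uniform(0.05, 0.5))
            bin_model = fit_binary(Xt, y, lam)
            bin_model.classes = ["P", "N"]
            multi = fit_multiclass(Xt, labels, lam)
            bin_pred = np.where(
                predict_binary(bin_model, Xt) > 0, "P", "N"
            )
            np.testing.assert_array_equal(
                predict_class(multi, Xt).astype(str), bin_pred
            )

    def test_huge_lambda_gives_intercept_only(self):
        rng = np.random.default_rng(6)
        Xt = rng.normal(size=(9, 4))
        labels = self._labels(["a", "b", "c"] * 3)
        model = fit_multiclass(Xt, labels, 1e3)
        np.testing.assert_allclose(model.B, 0, atol=1e-8)

    def test_objective_reevaluation_matches_lp_optimum(self):
        from metalinprog.lp_core import assemble_multiclass_lp, solve_lp
        from metalinprog.models import encode_labels as enc

        rng = np.random.default_rng(7)
        for _ in range(10):
            Xt = rng.normal(size=(9, 3))
            labels = self._labels(["a", "b", "c"] * 3)
            lam = float(rng.uniform(0.05, 1.0))
            model = fit_multiclass(Xt, labels, lam)
            direct = multiclass_objective(
                Xt, enc(labels).Y, model.beta0, model.B, lam
            )
            lp_value = solve_lp(
                assemble_multiclass_lp(Xt, enc(labels).Y, lam)
            ).objective_value
            assert direct == pytest.approx(lp_value, abs=1e-6)


class TestProbabilities:
    def _model(self, B, beta0, classes):
        return MulticlassModel(
            classes=classes, beta0=np.asarray(beta0, dtype=float),
            B=np.asarray(B, dtype=float), lam=0.1, transform="arcsine",
            feature_ids=[f"f{j + 1}" for j in range(np.asarray(B).shape[0])],
        )

    def test_zero_scores_give_uniform(self):
        model = self._model(np.zeros((2, 2)), [0.0, 0.0], ["a", "b", "c"])
        proba = predict_proba(model, np.zeros((3, 2)))
        np.testing.assert_allclose(proba, 1 / 3)

    def test_c2_zero_score_is_half(self):
        model = self._model(np.zeros((2, 1)), [0.0], ["a", "b"])
        np.testing.assert_allclose(
            predict_proba(model, np.zeros((1, 2))), 0.5
        )

    def test_log_score_example(self):
        model = self._model(np.zeros((1, 2)), [np.log(2.0), 0.0],
                            ["a", "b", "c"])
        proba = predict_proba(model, np.zeros((1, 1)))
        np.testing.assert_allclose(proba[0], [0.5, 0.25, 0.25], atol=1e-12)

    def test_rows_sum_to_one_and_open_interval(self):
        rng = np.random.default_rng(8)
        model = self._model(rng.normal(size=(4, 3)), rng.normal(size=3),
                            ["a", "b", "c", "d"])
        proba = predict_proba(model, rng.normal(size=(20, 4)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(proba > 0) and np.all(proba < 1)

    def test_large_scores_do_not_overflow(self):
        model = self._model(np.full((1, 2), 500.0), [300.0, -300.0],
                            ["a", "b", "c"])
        proba = predict_proba(model, np.array([[2.0]]))
        assert np.all(np.isfinite(proba))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_argmax_over_proba_equals_argmax_over_scores(self):
        rng = np.random.default_rng(9)
        model = self._model(rng.normal(size=(3, 2)), rng.normal(size=2),
                            ["a", "b", "c"])
        Xt = rng.normal(size=(15, 3))
        from metalinprog.models import decision_multiclass

        raw = decision_multiclass(model, Xt)
        assert np.all(
            np.argmax(predict_proba(model, Xt), axis=1)
            == np.argmax(raw, axis=1)
        )

    def test_uniform_tie_goes_to_first_class(self):
        model = self._model(np.zeros((2, 2)), [0.0, 0.0], ["a", "b", "c"])
        assert predict_class(model, np.zeros((1, 2)))[0] == "a"

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        B = rng.normal(size=(3, 2))
        beta0 = rng.normal(size=2)
        Xt = rng.normal(size=(6, 3))
        base = self._model(B, beta0, ["a", "b", "c"])
        swapped = self._model(B[:, [1, 0]], beta0[[1, 0]], ["b", "a", "c"])
        np.testing.assert_allclose(
            predict_proba(base, Xt)[:, [1, 0, 2]],
            predict_proba(swapped, Xt),
            atol=1e-12,
        )


class TestSelectedFeatures:
    def test_ordered_by_magnitude(self):
        model = make_binary([0.0, 0.5, -3.0], ids=["f1", "f2", "f3"])
        assert selected_features(model) == ["f3", "f2"]

    def test_all_zero_model_selects_nothing(self):
        assert selected_features(make_binary([0.0, 0.0])) == []

    def test_multiclass_row_max_rule(self):
        model = MulticlassModel(
            classes=["a", "b", "c"], beta0=np.zeros(2),
            B=np.array([[0.0, 0.4], [0.0, 0.0]]), lam=0.1,
            transform="arcsine", feature_ids=["f1", "f2"],
        )
        assert selected_features(model) == ["f1"]

    def test_lambda_path_sparsity_mostly_monotone(self):
        rng = np.random.default_rng(11)
        ladder = [0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2]
        agree = total = 0
        for _ in range(10):
            Xt, y = random_binary_instance(rng, n=12, m=5)
            sizes = [
                len(selected_features(fit_binary(Xt, y, lam)))
                for lam in ladder
            ]
            for a, b in zip(sizes, sizes[1:]):
                total += 1
                agree += b <= a
        assert agree / total >= 0.9
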