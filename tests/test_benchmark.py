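import warnings

import numpy as np
import pytest

from vdlin.benchmark import (
    BASELINE_FAMILIES,
    BaselineSpec,
    NoiseProtocol,
    OptimizerProtocol,
    default_search_space,
    evaluate,
    inject_label_noise,
    make_baseline,
    noise_row_permutation,
    run_benchmark,
    tune,
)
from vdlin.errors import ConfigurationError, SchemaError
from vdlin.model import ModelConfig
from vdlin.optimize import Categorical, Integer, Real, gp_minimize
from vdlin.panel import DEFAULT_PANEL

warnings.filterwarnings("ignore", category=FutureWarning)


def auc_concordance_oracle(y_true, y_score):
    """All-pairs concordance count (ties count 1/2)."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


class TestEvaluate:
    def test_perfect_separation(self):
        res = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert res["auc"] == 1.0 and res["f1"] == 1.0 and res["tpr"] == 1.0

    def test_anti_ordered(self):
        res = evaluate([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert res["auc"] == 0.0

    def test_pair_enumeration_example(self):
        # 4 label-discordant pairs, 3 concordant -> 0.75
        res = evaluate([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert res["auc"] == pytest.approx(0.75)

    def test_random_instances_match_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.random(n)
            res = evaluate(y, s)
            assert res["auc"] == pytest.approx(auc_concordance_oracle(y, s))

    def test_single_class_auc_none_other_metrics_present(self):
        res = evaluate([1, 1, 1], [0.9, 0.2, 0.8])
        assert res["auc"] is None
        assert res["f1"] > 0 and "confusion" in res

    def test_multilabel_micro_flattening(self, rng):
        y = rng.integers(0, 2, size=(8, 10))
        s = rng.random((8, 10))
        assert evaluate(y, s) == evaluate(y.ravel(), s.ravel())

    def test_confusion_matrix_counts(self):
        res = evaluate([0, 1, 0, 1], [0.9, 0.9, 0.1, 0.1])
        assert res["confusion"] == [[1, 1], [1, 1]]

    def test_length_mismatch_errors(self):
        with pytest.raises(SchemaError):
            evaluate([0, 1], [0.5])


class TestInjectLabelNoise:
    def test_fraction_zero_unchanged(self, rng):
        labels = rng.integers(0, 2, size=(30, 10))
        np.testing.assert_array_equal(inject_label_noise(labels, 0.0, seed=1), labels)

    def test_exact_row_count_selected(self):
        selected, permuted = noise_row_permutation(100, 0.3, seed=5)
        assert len(selected) == 30
        assert sorted(selected) == sorted(permuted)

    def test_same_seed_identical(self, rng):
        labels = rng.integers(0, 2, size=(50, 10))
        a = inject_label_noise(labels, 0.2, seed=9)
        b = inject_label_noise(labels, 0.2, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_multiset_of_label_vectors_preserved(self, rng):
        labels = rng.integers(0, 2, size=(40, 10))
        noisy = inject_label_noise(labels, 0.5, seed=3)
        orig = sorted(map(tuple, labels.tolist()))
        new = sorted(map(tuple, noisy.tolist()))
        assert orig == new

    def test_per_entry_flip_count(self, rng):
        labels = rng.integers(0, 2, size=(20, 10))
        noisy = inject_label_noise(labels, 0.1, seed=2, scope="per_entry_flip")
        assert (noisy != labels).sum() == round(0.1 * labels.size)

    def test_bad_fraction_errors(self, rng):
        with pytest.raises(ConfigurationError):
            inject_label_noise(rng.integers(0, 2, size=(5, 2)), 1.5, seed=0)


class TestTune:
    def test_single_point_space_one_evaluation(self):
        space = [Real(3.0, 3.0, name="x"), Categorical(("a",), name="c")]
        calls = []

        def objective(point):
            calls.append(point)
            return 1.0

        params, result = tune(
            "svm_rbf", OptimizerProtocol(seed=0), None, None,
            objective=objective, space=space,
        )
        assert result.n_evaluations == 1 and len(calls) == 1
        assert params == {"x": 3.0, "c": "a"}

    def test_quadratic_optimum_recovered(self):
        space = [Real(0.0, 10.0, name="x")]

        def objective(point):
            return (point[0] - 3.0) ** 2

        params, result = tune(
            "svm_rbf", OptimizerProtocol(seed=1), None, None,
            objective=objective, space=space,
        )
        assert abs(params["x"] - 3.0) < 0.5
        assert result.n_evaluations <= 100

    def test_constant_objective_patience_truncation(self):
        space = [Real(0.0, 1.0, name="x")]
        params, result = tune(
            "svm_rbf", OptimizerProtocol(seed=2), None, None,
            objective=lambda p: 1.0, space=space,
        )
        # 1 improving evaluation + 20 consecutive non-improving ones
        assert result.n_evaluations == 21
        assert result.stopped_early

    def test_trace_within_declared_space(self):
        space = [Real(2.0, 5.0, name="x"), Integer(1, 4, name="k"),
                 Categorical(("u", "v"), name="m")]
        _, result = tune(
            "svm_rbf",
            OptimizerProtocol(max_iterations=25, early_stop_patience=24, seed=3),
            None, None, objective=lambda p: p[0] + p[1], space=space,
        )
        for (x, k, m), _ in result.trace:
            assert 2.0 <= x <= 5.0 and 1 <= k <= 4 and m in ("u", "v")

    def test_budget_respected_exactly(self):
        space = [Real(0.0, 1.0, name="x")]
        rng = np.random.default_rng(0)
        _, result = tune(
            "svm_rbf",
            OptimizerProtocol(max_iterations=30, early_stop_patience=29, seed=4),
            None, None, objective=lambda p: rng.random(), space=space,
        )
        assert result.n_evaluations <= 30

    def test_cv_tune_baseline_small(self, rng):
        X = rng.normal(size=(60, 8))
        beta = rng.normal(size=(8, 3))
        Y = (X @ beta > 0).astype(int)
        protocol = OptimizerProtocol(max_iterations=4, early_stop_patience=3, seed=0)
        spec = BaselineSpec(family="logistic")
        params, result = tune(spec, protocol, X, Y)
        assert set(params) == {"C", "penalty"}
        assert result.n_evaluations <= 4

    def test_injected_objective_requires_space(self):
        with pytest.raises(ConfigurationError):
            tune("svm_rbf", OptimizerProtocol(), None, None, objective=lambda p: 0.0)


class TestGpMinimize:
    def test_empty_space_errors(self):
        with pytest.raises(ConfigurationError):
            gp_minimize(lambda p: 0.0, [])

    def test_patience_must_be_below_budget(self):
        with pytest.raises(ConfigurationError):
            gp_minimize(lambda p: 0.0, [Real(0, 1)], max_iterations=10, patience=10)

    def test_seeded_determinism(self):
        space = [Real(0.0, 10.0, name="x")]
        r1 = gp_minimize(lambda p: (p[0] - 7) ** 2, space, max_iterations=15, patience=14, seed=5)
        r2 = gp_minimize(lambda p: (p[0] - 7) ** 2, space, max_iterations=15, patience=14, seed=5)
        assert r1.trace == r2.trace


class TestBaselines:
    @pytest.mark.parametrize("family", BASELINE_FAMILIES)
    def test_default_spaces_and_constructors(self, family):
        space = default_search_space(family)
        assert space
        model = make_baseline(family)
        assert hasattr(model, "fit")

    def test_unknown_family_errors(self):
        with pytest.raises(ConfigurationError):
            BaselineSpec(family="mlp")


@pytest.fixture(scope="module")
def tiny_report():
    rng = np.random.default_rng(0)
    n = 150
    active = rng.random(n) < 0.3
    X = rng.normal(size=(n, 12))
    X[active, :4] += 2.0
    Y = rng.normal(scale=0.3, size=(n, 10))
    Y[active] += 2.0 * DEFAULT_PANEL.directions
    return run_benchmark(
        X, Y, NoiseProtocol(noise_levels=(0.2,)), seeds=(0, 1),
        vdlin_config=ModelConfig(epochs=8),
    )


class TestRunBenchmark:
    def test_all_models_reported(self, tiny_report):
        assert set(tiny_report.frame["model"]) == {"vdlin", *BASELINE_FAMILIES}

    def test_degradation_zero_at_noise_zero(self, tiny_report):
        f = tiny_report.frame
        at0 = f[(f["noise_level"] == 0.0) & (f["metric"] == "f1_degradation")]
        assert (at0["value"] == 0.0).all()

    def test_identical_splits_recorded(self, tiny_report):
        splits = tiny_report.manifest["splits"]
        assert set(splits) == {"0", "1"}
        s0 = splits["0"]
        assert sorted(s0["train"] + s0["test"]) == list(range(150))

    def test_missing_model_errors(self, rng):
        with pytest.raises(ConfigurationError):
            run_benchmark(
                rng.normal(size=(30, 4)), rng.normal(size=(30, 10)),
                models=("vdlin", "mystery"), seeds=(0,),
            )

    def test_row_count_mismatch_errors(self, rng):
        with pytest.raises(SchemaError):
            run_benchmark(rng.normal(size=(10, 4)), rng.normal(size=(9, 10)))
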