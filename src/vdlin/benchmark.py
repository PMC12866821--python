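"""Baseline comparison, Bayesian tuning, label-noise robustness and metrics.

The 10-gene multi-label task is reduced micro-style for the single-output
baseline learners: one binary desired-effect problem per gene on shared
features, with all gene-level decisions pooled (flattened) before any metric
is computed. All models in a benchmark run share identical split indices and
input features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError, SchemaError
from .model import ModelConfig, VdlinModel
from .optimize import Categorical, Dimension, Integer, OptimizeResult, Real, gp_minimize
from .panel import DEFAULT_PANEL, GenePanel
from .prep import DEFAULT_TAU, ternarize

BASELINE_FAMILIES = ("svm_rbf", "knn", "logistic", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class OptimizerProtocol:
    max_iterations: int = 100
    early_stop_patience: int = 20
    cv_folds: int = 3
    validation_fraction: float = 0.2
    n_parallel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience >= self.max_iterations:
            raise ConfigurationError("early_stop_patience must be < max_iterations")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass(frozen=True)
class NoiseProtocol:
    noise_levels: tuple[float, ...] = (0.10, 0.20, 0.30)
    n_seeds: int = 5
    permute_scope: str = "whole_label_vector"  # | "per_entry_flip"

    def __post_init__(self) -> None:
        if any(not 0 <= f <= 1 for f in self.noise_levels):
            raise ConfigurationError("noise_levels must lie in [0, 1]")
        if self.permute_scope not in ("whole_label_vector", "per_entry_flip"):
            raise ConfigurationError(f"unknown permute_scope {self.permute_scope!r}")


def default_search_space(family: str) -> list[Dimension]:
    """Printed per-family hyperparameter ranges."""
    spaces: dict[str, list[Dimension]] = {
        "svm_rbf": [
            Real(0.1, 10.0, name="C"),
            Real(0.01, 1.0, name="gamma"),
            Categorical(("linear", "rbf"), name="kernel"),
        ],
        "knn": [
            Integer(1, 15, name="n_neighbors"),
            Categorical(("euclidean", "manhattan"), name="metric"),
        ],
        "logistic": [
            Real(0.01, 10.0, prior="log-uniform", name="C"),
            Categorical(("l1", "l2"), name="penalty"),
        ],
        "random_forest": [
            Integer(50, 200, name="n_estimators"),
            Integer(2, 15, name="max_depth"),
            Integer(2, 10, name="min_samples_split"),
        ],
        "gradient_boosting": [
            Real(0.01, 0.3, name="learning_rate"),
            Integer(2, 8, name="max_depth"),
            Real(0.6, 1.0, name="subsample"),
        ],
    }
    if family not in spaces:
        raise ConfigurationError(f"unknown baseline family {family!r}")
    return spaces[family]


@dataclass(frozen=True)
class BaselineSpec:
    family: str
    search_space: tuple[Dimension, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in BASELINE_FAMILIES:
            raise ConfigurationError(f"unknown baseline family {self.family!r}")
        if not self.search_space:
            object.__setattr__(
                self, "search_space", tuple(default_search_space(self.family))
            )


def make_baseline(family: str, params: dict | None = None, seed: int = 0):
    """Construct a single-output sklearn estimator for one family."""
    params = params or {}
    if family == "svm_rbf":
        return SVC(
            C=params.get("C", 1.0), gamma=params.get("gamma", "scale"),
            kernel=params.get("kernel", "rbf"), probability=True, random_state=seed,
        )
    if family == "knn":
        return KNeighborsClassifier(
            n_neighbors=params.get("n_neighbors", 5),
            metric=params.get("metric", "euclidean"),
        )
    if family == "logistic":
        return LogisticRegression(
            C=params.get("C", 1.0), penalty=params.get("penalty", "l2"),
            solver="liblinear", max_iter=500, random_state=seed,
        )
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", None),
            min_samples_split=params.get("min_samples_split", 2),
            random_state=seed,
        )
    if family == "gradient_boosting":
        return GradientBoostingClassifier(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 3),
            subsample=params.get("subsample", 1.0),
            n_estimators=params.get("n_estimators", 50),
            random_state=seed,
        )
    raise ConfigurationError(f"unknown baseline family {family!r}")


class MultiLabelBaseline:
    """Micro reduction: one binary estimator per gene over shared features."""

    def __init__(self, base_estimator):
        self.base = base_estimator
        self.models_: list = []
        self.constant_: list = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MultiLabelBaseline":
        Y = np.atleast_2d(Y)
        self.models_ = []
        self.constant_ = []
        for g in range(Y.shape[1]):
            y = Y[:, g]
            if len(np.unique(y)) < 2:
                self.models_.append(None)
                self.constant_.append(float(y[0]))
            else:
                m = clone(self.base)
                with warnings.catch_warnings():
                    # sklearn >= 1.9 warns about SVC(probability=True)
                    warnings.simplefilter("ignore", FutureWarning)
                    m.fit(X, y)
                self.models_.append(m)
                self.constant_.append(np.nan)
        return self

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for m, const in zip(self.models_, self.constant_):
            if m is None:
                cols.append(np.full(X.shape[0], const))
            else:
                cols.append(m.predict_proba(X)[:, 1])
        return np.column_stack(cols)


# -- metrics ---------------------------------------------------------------


def evaluate(y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5) -> dict:
    """Metric suite on binary labels vs real scores.

    Multi-label (2-D) inputs are micro-averaged by flattening before any
    metric is computed. AUC follows the rank (Mann-Whitney) formulation.
    When only one class is present, AUC is undefined and reported as None
    (the remaining metrics are still returned).
    """
    y_true = np.asarray(y_true).ravel().astype(int)
    y_score = np.asarray(y_score, dtype=float).ravel()
    if y_true.shape != y_score.shape:
        raise SchemaError("y_true and y_score must have equal lengths")
    y_pred = (y_score >= threshold).astype(int)
    tn, fp, fn, tp = skm.confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    out = {
        "auc": None,
        "f1": float(f1),
        "tpr": float(recall),
        "precision": float(precision),
        "recall": float(recall),
        "confusion": [[int(tn), int(fp)], [int(fn), int(tp)]],
    }
    if len(np.unique(y_true)) == 2:
        out["auc"] = float(skm.roc_auc_score(y_true, y_score))
    return out


def roc_pr_points(y_true: np.ndarray, y_score: np.ndarray) -> dict[str, pd.DataFrame]:
    """ROC and PR curve points (for plotting exports)."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_score = np.asarray(y_score, dtype=float).ravel()
    fpr, tpr, roc_thr = skm.roc_curve(y_true, y_score)
    prec, rec, pr_thr = skm.precision_recall_curve(y_true, y_score)
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "pr": pd.DataFrame({"recall": rec, "precision": prec}),
    }


# -- label noise -----------------------------------------------------------


def noise_row_permutation(
    n: int, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded choice of exactly round(fraction*n) rows and their shuffle.

    Returns (selected_rows, permuted_rows): row selected[i] receives the
    label vector of row permuted[i].
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("noise fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = round(fraction * n)
    selected = rng.choice(n, size=k, replace=False)
    permuted = selected[rng.permutation(k)]
    return selected, permuted


def inject_label_noise(
    labels: np.ndarray, fraction: float, seed: int, scope: str = "whole_label_vector"
) -> np.ndarray:
    """Corrupt training labels: permute whole label vectors of a seeded
    random sample of rows among themselves (default), or flip individual
    entries (`per_entry_flip`). The caller is responsible for applying this
    to the training partition only."""
    labels = np.asarray(labels)
    noisy = labels.copy()
    if scope == "whole_label_vector":
        selected, permuted = noise_row_permutation(labels.shape[0], fraction, seed)
        noisy[selected] = labels[permuted]
        return noisy
    if scope == "per_entry_flip":
        if not 0.0 <= fraction <= 1.0:
            raise ConfigurationError("noise fraction must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        flat = noisy.reshape(-1)
        k = round(fraction * flat.size)
        idx = rng.choice(flat.size, size=k, replace=False)
        flat[idx] = 1 - flat[idx]
        return noisy
    raise ConfigurationError(f"unknown noise scope {scope!r}")


# -- tuning ----------------------------------------------------------------


def _space_params(space: Sequence[Dimension], point: list) -> dict:
    return {d.name: v for d, v in zip(space, point)}


def vdlin_search_space() -> list[Dimension]:
    """Architectural/training space for the CNN model."""
    return [
        Categorical((64, 128, 256), name="dense_width"),
        Real(1e-4, 0.1, prior="log-uniform", name="learning_rate"),
        Categorical((32, 64, 128), name="batch_size"),
        Real(0.1, 0.5, name="dropout_rate"),
    ]


def tune(
    spec: BaselineSpec | str,
    protocol: OptimizerProtocol,
    X: np.ndarray,
    Y: np.ndarray,
    objective: Callable[[list], float] | None = None,
    space: Sequence[Dimension] | None = None,
    vdlin_epochs: int = 10,
) -> tuple[dict, OptimizeResult]:
    """Bayesian GP search for the best hyperparameters.

    The CV objective is 1 - mean micro AUC-ROC over ``cv_folds`` folds
    (early stopping monitors the same scalar). An arbitrary ``objective``
    callable (with explicit ``space``) may be injected for testing.
    """
    if objective is not None:
        if space is None:
            raise ConfigurationError("an injected objective requires an explicit space")
        result = gp_minimize(
            objective, space,
            max_iterations=protocol.max_iterations,
            patience=protocol.early_stop_patience,
            seed=protocol.seed,
        )
        return _space_params(space, result.best_point), result

    Y = np.atleast_2d(np.asarray(Y))
    X = np.asarray(X, dtype=float)
    kf = KFold(n_splits=protocol.cv_folds, shuffle=True, random_state=protocol.seed)

    if isinstance(spec, str) and spec == "vdlin":
        space = vdlin_search_space()

        def cv_objective(point: list) -> float:
            params = _space_params(space, point)
            aucs = []
            for tr, va in kf.split(X):
                cfg = ModelConfig(
                    dense_width=int(params["dense_width"]),
                    learning_rate=float(params["learning_rate"]),
                    batch_size=int(params["batch_size"]),
                    dropout_rate=float(params["dropout_rate"]),
                    epochs=vdlin_epochs, seed=protocol.seed,
                )
                m = VdlinModel(cfg).train(X[tr], Y[tr])
                probs = m.predict(X[va]).desired_effect_prob
                truth = (ternarize(Y[va], DEFAULT_TAU) == m.panel.directions).astype(int)
                res = evaluate(truth, probs)
                aucs.append(res["auc"] if res["auc"] is not None else 0.5)
            return 1.0 - float(np.mean(aucs))

    else:
        if isinstance(spec, str):
            spec = BaselineSpec(family=spec)
        space = list(spec.search_space)
        family = spec.family

        def cv_objective(point: list) -> float:
            params = _space_params(space, point)
            aucs = []
            for tr, va in kf.split(X):
                mdl = MultiLabelBaseline(make_baseline(family, params, seed=protocol.seed))
                mdl.fit(X[tr], Y[tr])
                scores = mdl.predict_proba_matrix(X[va])
                res = evaluate(Y[va], scores)
                aucs.append(res["auc"] if res["auc"] is not None else 0.5)
            return 1.0 - float(np.mean(aucs))

    result = gp_minimize(
        cv_objective, space,
        max_iterations=protocol.max_iterations,
        patience=protocol.early_stop_patience,
        seed=protocol.seed,
    )
    return _space_params(space, result.best_point), result


# -- benchmark harness -----------------------------------------------------


@dataclass
class BenchmarkReport:
    frame: pd.DataFrame  # tidy: model, noise_level, seed, metric, value
    manifest: dict = field(default_factory=dict)

    def metric(self, model: str, noise_level: float, metric: str) -> pd.Series:
        f = self.frame
        sel = (
            (f["model"] == model)
            & (f["noise_level"] == noise_level)
            & (f["metric"] == metric)
        )
        return f.loc[sel, "value"]

    def median_f1(self, model: str, noise_level: float) -> float:
        return float(self.metric(model, noise_level, "f1").median())


def run_benchmark(
    X: np.ndarray,
    Y_delta: np.ndarray,
    noise: NoiseProtocol = NoiseProtocol(),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    train_fraction: float = 0.7,
    tau: float = DEFAULT_TAU,
    panel: GenePanel = DEFAULT_PANEL,
    vdlin_config: ModelConfig | None = None,
    include_noise_free: bool = True,
    models: Sequence[str] = ("vdlin",) + BASELINE_FAMILIES,
) -> BenchmarkReport:
    """Train every model on identical splits/features across noise levels.

    Baselines consume binary desired-effect labels derived from the
    (possibly corrupted) training deltas; the CNN trains on the deltas
    themselves. The desired-effect label of a gene is 1 iff its ternarized
    delta (dead zone tau) matches the panel's desired direction, so genes
    with no significant change count as negatives. Noise permutes whole training label vectors (delta rows),
    so both label views stay consistent. Test labels are never corrupted.
    Degradation is relative to the same model's noise-free F1 at the same
    seed.
    """
    X = np.asarray(X, dtype=float)
    Y_delta = np.asarray(Y_delta, dtype=float)
    if X.shape[0] != Y_delta.shape[0]:
        raise SchemaError("X and Y_delta row counts differ")
    for m in models:
        if m != "vdlin" and m not in BASELINE_FAMILIES:
            raise ConfigurationError(f"unknown model {m!r}")
    dirs = panel.directions
    levels = tuple(noise.noise_levels)
    if include_noise_free and 0.0 not in levels:
        levels = (0.0,) + levels
    levels = tuple(sorted(levels))

    rows = []
    split_manifest = {}
    for seed in seeds:
        order = np.random.default_rng(seed).permutation(X.shape[0])
        n_train = int(train_fraction * X.shape[0])
        tr, te = order[:n_train], order[n_train:]
        split_manifest[str(seed)] = {"train": tr.tolist(), "test": te.tolist()}
        y_true_test = (ternarize(Y_delta[te], tau) == dirs).astype(int)

        f1_noise_free: dict[str, float] = {}
        for level in levels:
            noise_seed = seed * 1000 + int(level * 100)
            if level == 0.0:
                Yd_train = Y_delta[tr]
                y_bin_train = (ternarize(Yd_train, tau) == dirs).astype(int)
            elif noise.permute_scope == "whole_label_vector":
                Yd_train = inject_label_noise(Y_delta[tr], level, seed=noise_seed)
                y_bin_train = (ternarize(Yd_train, tau) == dirs).astype(int)
            else:  # per_entry_flip: flip binary entries, negate matching deltas
                y_bin_clean = (ternarize(Y_delta[tr], tau) == dirs).astype(int)
                y_bin_train = inject_label_noise(
                    y_bin_clean, level, seed=noise_seed, scope="per_entry_flip"
                )
                Yd_train = Y_delta[tr].copy()
                Yd_train[y_bin_train != y_bin_clean] *= -1.0

            for name in models:
                if name == "vdlin":
                    cfg = vdlin_config or ModelConfig(epochs=20, seed=seed)
                    if cfg.seed != seed:
                        cfg = ModelConfig(**{**cfg.__dict__, "seed": seed})
                    mdl = VdlinModel(cfg, panel=panel).train(X[tr], Yd_train)
                    scores = mdl.predict(X[te]).desired_effect_prob
                else:
                    base = make_baseline(name, seed=seed)
                    wrapped = MultiLabelBaseline(base).fit(X[tr], y_bin_train)
                    scores = wrapped.predict_proba_matrix(X[te])
                res = evaluate(y_true_test, scores)
                if level == 0.0:
                    f1_noise_free[name] = res["f1"]
                degradation = (
                    0.0
                    if level == 0.0 or f1_noise_free.get(name, 0.0) == 0.0
                    else (f1_noise_free[name] - res["f1"]) / f1_noise_free[name]
                )
                for metric_name in ("auc", "f1", "tpr", "precision", "recall"):
                    value = res[metric_name]
                    rows.append(
                        {
                            "model": name,
                            "noise_level": level,
                            "seed": seed,
                            "metric": metric_name,
                            "value": np.nan if value is None else value,
                        }
                    )
                rows.append(
                    {
                        "model": name,
                        "noise_level": level,
                        "seed": seed,
                        "metric": "f1_degradation",
                        "value": degradation,
                    }
                )
    frame = pd.DataFrame(rows)
    manifest = {
        "models": list(models),
        "noise_levels": list(levels),
        "seeds": list(seeds),
        "train_fraction": train_fraction,
        "permute_scope": noise.permute_scope,
        "splits": split_manifest,
    }
    return BenchmarkReport(frame=frame, manifest=manifest)
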