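"""Multi-task 1D-CNN mapping structural latent vectors to the predicted
10-gene panel delta profile.

Canonical stack: conv(32,3)+ReLU -> maxpool -> conv(64,3)+ReLU -> maxpool ->
flatten -> dense(128)+ReLU -> dropout(0.5) -> dense(10, linear). Trained with
the joint objective  alpha * MSE + (1 - alpha) * (1 - sigmoid(SoftScore/100)),
where SoftScore is the differentiable logistic relaxation of the hard
indicator score (the hard score itself is non-differentiable and is used
only for screening/reporting).

A `spherical_latent` architecture variant (extra conv block, stochastic
mean/radius bottleneck, 4-layer dense head) and a `bce` loss mode (sigmoid
head + binary cross-entropy on desired-effect labels) are provided as
alternates; the joint-loss `methods` stack is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NotFittedError, NumericalError, SchemaError
from .nn import (
    Adam,
    conv1d_backward,
    conv1d_forward,
    glorot,
    maxpool_backward,
    maxpool_forward,
    relu,
    sigmoid,
)
from .panel import DEFAULT_PANEL, GenePanel
from .screen import soft_score_batch


@dataclass(frozen=True)
class ModelConfig:
    conv_blocks: tuple[tuple[int, int], ...] = ((32, 3), (64, 3))
    dense_width: int = 128
    dropout_rate: float = 0.5
    output_dim: int = 10
    alpha: float = 0.7
    soft_score_temperature: float = 10.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    architecture_variant: str = "methods"  # "methods" | "spherical_latent"
    loss_mode: str = "joint"  # "joint" | "bce"
    spherical_latent_dim: int = 32
    spherical_mlp_widths: tuple[int, ...] = (128, 64, 32)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.output_dim != 10:
            raise ConfigurationError("output_dim must be 10 (the gene panel size)")
        if self.soft_score_temperature <= 0:
            raise ConfigurationError("soft_score_temperature must be > 0")
        if self.architecture_variant not in ("methods", "spherical_latent"):
            raise ConfigurationError(
                f"unknown architecture_variant {self.architecture_variant!r}"
            )
        if self.loss_mode not in ("joint", "bce"):
            raise ConfigurationError(f"unknown loss_mode {self.loss_mode!r}")


@dataclass
class PredictionBatch:
    """Regression output plus its classification view.

    desired_effect_prob[g] = sigmoid(beta * dir_g * predicted_delta[g]) with
    dir_g = +1 for IFN genes, -1 for inflammatory genes.
    """

    predicted_delta: np.ndarray
    desired_effect_prob: np.ndarray
    compound_ids: list[str] | None = None


def joint_loss(
    predicted_delta: np.ndarray,
    target_delta: np.ndarray,
    alpha: float = 0.7,
    temperature: float | None = None,
    panel: GenePanel = DEFAULT_PANEL,
) -> float:
    """alpha * MSE + (1 - alpha) * mean(1 - sigmoid(Score/100)).

    With ``temperature=None`` (default) Score is the hard indicator score —
    the loss as written, used for evaluation and reporting (an all-zero
    perfect prediction gives 0.3 * (1 - sigmoid(0)) = 0.15 at alpha 0.7).
    Passing a finite temperature substitutes the differentiable SoftScore
    surrogate, which is what training gradients flow through. Reduces to
    plain MSE at alpha = 1; the score term is averaged over the batch.
    Always nonnegative.
    """
    predicted_delta = np.atleast_2d(np.asarray(predicted_delta, dtype=float))
    target_delta = np.atleast_2d(np.asarray(target_delta, dtype=float))
    if predicted_delta.shape != target_delta.shape:
        raise SchemaError(
            f"shape mismatch: {predicted_delta.shape} vs {target_delta.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must lie in [0, 1]")
    mse = float(np.mean((predicted_delta - target_delta) ** 2))
    if temperature is None:
        from .screen import hard_score

        scores = np.array(
            [hard_score(row, panel).total_score for row in predicted_delta],
            dtype=float,
        )
    else:
        scores = soft_score_batch(predicted_delta, panel, temperature)
    score_term = float(np.mean(1.0 - sigmoid(scores / 100.0)))
    return alpha * mse + (1.0 - alpha) * score_term


def joint_loss_terms(
    predicted_delta: np.ndarray,
    target_delta: np.ndarray,
    alpha: float,
    temperature: float,
    panel: GenePanel = DEFAULT_PANEL,
) -> tuple[float, float, float]:
    """(total, mse, score_term) for history bookkeeping."""
    predicted_delta = np.atleast_2d(predicted_delta)
    target_delta = np.atleast_2d(target_delta)
    mse = float(np.mean((predicted_delta - target_delta) ** 2))
    scores = soft_score_batch(predicted_delta, panel, temperature)
    score_term = float(np.mean(1.0 - sigmoid(scores / 100.0)))
    return alpha * mse + (1.0 - alpha) * score_term, mse, score_term


class VdlinModel:
    """NumPy implementation of the panel-prediction CNN."""

    def __init__(
        self,
        config: ModelConfig = ModelConfig(),
        input_dim: int | None = None,
        panel: GenePanel = DEFAULT_PANEL,
    ):
        self.config = config
        self.panel = panel
        self.params: dict[str, np.ndarray] = {}
        self.input_dim: int | None = None
        self.fitted = False
        self.history: list[dict[str, float]] = []
        if input_dim is not None:
            self.build(input_dim)

    # -- construction ------------------------------------------------------

    def _conv_stack(self) -> tuple[tuple[int, int], ...]:
        blocks = self.config.conv_blocks
        if self.config.architecture_variant == "spherical_latent":
            # "three-layer" conv front end: repeat the last block once more
            blocks = blocks + (blocks[-1],)
        return blocks

    def build(self, input_dim: int) -> "VdlinModel":
        blocks = self._conv_stack()
        min_kernel = min(k for _, k in blocks)
        if input_dim < min_kernel:
            raise ConfigurationError(
                f"input_dim {input_dim} shorter than smallest kernel {min_kernel}"
            )
        rng = np.random.default_rng(self.config.seed)
        p: dict[str, np.ndarray] = {}
        length, channels = input_dim, 1
        for i, (filters, kernel) in enumerate(blocks):
            if length < kernel:
                raise ConfigurationError(
                    f"feature length {length} shorter than kernel {kernel} at block {i}"
                )
            p[f"conv{i}_w"] = glorot(
                rng, kernel * channels, filters, (kernel, channels, filters)
            )
            p[f"conv{i}_b"] = np.zeros(filters)
            length = (length - kernel + 1) // 2  # valid conv then pool/2
            channels = filters
            if length < 1:
                raise ConfigurationError("input too short for the conv/pool stack")
        flat = length * channels
        cfg = self.config
        if cfg.architecture_variant == "methods":
            p["dense_w"] = glorot(rng, flat, cfg.dense_width, (flat, cfg.dense_width))
            p["dense_b"] = np.zeros(cfg.dense_width)
            p["out_w"] = glorot(
                rng, cfg.dense_width, cfg.output_dim, (cfg.dense_width, cfg.output_dim)
            )
            p["out_b"] = np.zeros(cfg.output_dim)
        else:
            z = cfg.spherical_latent_dim
            p["mu_w"] = glorot(rng, flat, z, (flat, z))
            p["mu_b"] = np.zeros(z)
            p["rho_w"] = glorot(rng, flat, z, (flat, z))
            p["rho_b"] = np.full(z, -3.0)  # small initial radius
            widths = list(cfg.spherical_mlp_widths) + [cfg.output_dim]
            prev = z
            for i, w in enumerate(widths):
                p[f"mlp{i}_w"] = glorot(rng, prev, w, (prev, w))
                p[f"mlp{i}_b"] = np.zeros(w)
                prev = w
        self.params = p
        self.input_dim = input_dim
        self._rng = rng
        return self

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Forward pass; rng enables dropout / latent sampling (training only)."""
        cfg = self.config
        cache: dict = {"convs": []}
        a = X[:, :, None]
        for i in range(len(self._conv_stack())):
            pre = conv1d_forward(a, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            act = relu(pre)
            pooled, pcache = maxpool_forward(act)
            cache["convs"].append((a, pre, act, pcache))
            a = pooled
        B = X.shape[0]
        flat = a.reshape(B, -1)
        cache["flat"] = flat
        cache["flat_shape"] = a.shape
        if cfg.architecture_variant == "methods":
            d_pre = flat @ self.params["dense_w"] + self.params["dense_b"]
            d = relu(d_pre)
            if rng is not None and cfg.dropout_rate > 0:
                mask = (rng.random(d.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            else:
                mask = np.ones_like(d)
            dm = d * mask
            out = dm @ self.params["out_w"] + self.params["out_b"]
            cache.update(d=d, mask=mask, dm=dm)
        else:
            mu = flat @ self.params["mu_w"] + self.params["mu_b"]
            radius = np.exp(np.clip(flat @ self.params["rho_w"] + self.params["rho_b"], -10, 3))
            if rng is not None:
                eps = rng.standard_normal(mu.shape)
            else:
                eps = np.zeros_like(mu)
            z = mu + radius * eps
            cache.update(mu=mu, radius=radius, eps=eps)
            a_mlp = z
            mlp_cache = []
            n_mlp = len(cfg.spherical_mlp_widths) + 1
            for i in range(n_mlp):
                pre = a_mlp @ self.params[f"mlp{i}_w"] + self.params[f"mlp{i}_b"]
                post = pre if i == n_mlp - 1 else relu(pre)
                mlp_cache.append((a_mlp, pre))
                a_mlp = post
            out = a_mlp
            cache["mlp"] = mlp_cache
        return out, cache

    def _backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        g: dict[str, np.ndarray] = {}
        if cfg.architecture_variant == "methods":
            g["out_w"] = cache["dm"].T @ dout
            g["out_b"] = dout.sum(axis=0)
            ddm = dout @ self.params["out_w"].T
            dd = ddm * cache["mask"]
            dd[cache["d"] <= 0] = 0.0
            g["dense_w"] = cache["flat"].T @ dd
            g["dense_b"] = dd.sum(axis=0)
            dflat = dd @ self.params["dense_w"].T
        else:
            n_mlp = len(cfg.spherical_mlp_widths) + 1
            grad = dout
            for i in reversed(range(n_mlp)):
                a_in, pre = cache["mlp"][i]
                if i != n_mlp - 1:
                    grad = grad * (pre > 0)
                g[f"mlp{i}_w"] = a_in.T @ grad
                g[f"mlp{i}_b"] = grad.sum(axis=0)
                grad = grad @ self.params[f"mlp{i}_w"].T
            dz = grad
            dmu = dz
            drho = dz * cache["eps"] * cache["radius"]
            flat = cache["flat"]
            g["mu_w"] = flat.T @ dmu
            g["mu_b"] = dmu.sum(axis=0)
            g["rho_w"] = flat.T @ drho
            g["rho_b"] = drho.sum(axis=0)
            dflat = dmu @ self.params["mu_w"].T + drho @ self.params["rho_w"].T
        da = dflat.reshape(cache["flat_shape"])
        for i in reversed(range(len(cache["convs"]))):
            a_in, pre, act, pcache = cache["convs"][i]
            dact = maxpool_backward(da, pcache)
            dact[pre <= 0] = 0.0
            da, dw, db = conv1d_backward(a_in, self.params[f"conv{i}_w"], dact)
            g[f"conv{i}_w"] = dw
            g[f"conv{i}_b"] = db
        return g

    def _loss_grad(self, out: np.ndarray, yb: np.ndarray):
        """Loss value, per-term breakdown and d(loss)/d(out)."""
        cfg = self.config
        B, G = out.shape
        dirs = self.panel.directions
        if cfg.loss_mode == "bce":
            targets = (dirs * yb > 0).astype(float)
            logits = cfg.soft_score_temperature * dirs * out
            probs = sigmoid(logits)
            eps = 1e-12
            loss = float(
                -np.mean(targets * np.log(probs + eps) + (1 - targets) * np.log(1 - probs + eps))
            )
            dout = (probs - targets) * cfg.soft_score_temperature * dirs / (B * G)
            return loss, loss, 0.0, dout
        alpha, beta = cfg.alpha, cfg.soft_score_temperature
        diff = out - yb
        mse = float(np.mean(diff**2))
        sig = sigmoid(beta * dirs * out)
        scores = 10.0 * sig.sum(axis=1)
        s100 = sigmoid(scores / 100.0)
        score_term = float(np.mean(1.0 - s100))
        loss = alpha * mse + (1 - alpha) * score_term
        dout = alpha * 2.0 * diff / (B * G)
        dscore = -(1 - alpha) * (s100 * (1 - s100) / 100.0) / B  # d/ds_i of the term
        dout += dscore[:, None] * 10.0 * beta * dirs * sig * (1 - sig)
        return loss, mse, score_term, dout

    # -- public API --------------------------------------------------------

    def train(self, X: np.ndarray, Y: np.ndarray) -> "VdlinModel":
        """Seeded mini-batch Adam training; records both loss terms per epoch."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise SchemaError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
        if Y.shape[1] != self.config.output_dim:
            raise SchemaError(f"Y must have {self.config.output_dim} columns")
        if self.input_dim is None:
            self.build(X.shape[1])
        elif X.shape[1] != self.input_dim:
            raise SchemaError(f"X dimension {X.shape[1]} != built input_dim {self.input_dim}")
        cfg = self.config
        rng = self._rng
        opt = Adam(self.params, lr=cfg.learning_rate)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        self.history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            tot = tot_mse = tot_score = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                out, cache = self._forward(X[idx], rng)
                loss, mse, score_term, dout = self._loss_grad(out, Y[idx])
                if not np.isfinite(loss):
                    raise NumericalError(
                        f"non-finite loss at epoch {epoch}", epoch=epoch
                    )
                opt.step(self._backward(dout, cache))
                w = len(idx)
                tot += loss * w
                tot_mse += mse * w
                tot_score += score_term * w
            self.history.append(
                {
                    "epoch": epoch,
                    "loss": tot / n,
                    "mse": tot_mse / n,
                    "score_term": tot_score / n,
                }
            )
        self.fitted = True
        return self

    def predict(self, X: np.ndarray, compound_ids: list[str] | None = None) -> PredictionBatch:
        """Deterministic inference (dropout/sampling disabled)."""
        if not self.fitted:
            raise NotFittedError("model must be trained before predicting")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise SchemaError(f"X dimension {X.shape[1]} != built input_dim {self.input_dim}")
        out, _ = self._forward(X, rng=None)
        probs = sigmoid(
            self.config.soft_score_temperature * self.panel.directions * out
        )
        return PredictionBatch(
            predicted_delta=out, desired_effect_prob=probs, compound_ids=compound_ids
        )
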