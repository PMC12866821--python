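"""Variational autoencoder compressing one-hot grammar arrays into fixed-length
latent vectors.

Symmetric dense encoder/decoder over the flattened one-hot matrix; per-row
softmax categorical reconstruction; KL term annealed linearly over the first
half of training. Deterministic under a fixed seed. The deterministic latent
used downstream is the posterior mean (sampling happens only in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NotFittedError, SchemaError
from .grammar import OneHotEncoding
from .nn import Adam, glorot, relu


@dataclass(frozen=True)
class VaeConfig:
    latent_dim: int = 64
    hidden_dims: tuple[int, ...] = (128,)
    kl_weight: float = 0.1
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ConfigurationError("kl_weight must be >= 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


@dataclass
class LatentVector:
    values: np.ndarray

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def _row_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class GrammarVae:
    """Dense VAE over flattened (L x V) one-hot arrays."""

    def __init__(self, config: VaeConfig = VaeConfig()):
        self.config = config
        self.fitted = False
        self.input_shape: tuple[int, int] | None = None
        self.params: dict[str, np.ndarray] = {}
        self.history: list[dict[str, float]] = []

    # -- internals ---------------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> None:
        h = self.config.hidden_dims[0]
        z = self.config.latent_dim
        p = {}
        p["enc_w"] = glorot(rng, input_dim, h, (input_dim, h))
        p["enc_b"] = np.zeros(h)
        p["mu_w"] = glorot(rng, h, z, (h, z))
        p["mu_b"] = np.zeros(z)
        p["lv_w"] = glorot(rng, h, z, (h, z))
        p["lv_b"] = np.zeros(z)
        p["dec_w"] = glorot(rng, z, h, (z, h))
        p["dec_b"] = np.zeros(h)
        p["out_w"] = glorot(rng, h, input_dim, (h, input_dim))
        p["out_b"] = np.zeros(input_dim)
        self.params = p

    def _encode_hidden(self, x: np.ndarray):
        h = relu(x @ self.params["enc_w"] + self.params["enc_b"])
        mu = h @ self.params["mu_w"] + self.params["mu_b"]
        lv = h @ self.params["lv_w"] + self.params["lv_b"]
        return h, mu, np.clip(lv, -10.0, 10.0)

    def _decode(self, z: np.ndarray):
        h2 = relu(z @ self.params["dec_w"] + self.params["dec_b"])
        logits = h2 @ self.params["out_w"] + self.params["out_b"]
        return h2, logits

    # -- public API --------------------------------------------------------

    def fit(self, encodings: list[OneHotEncoding]) -> "GrammarVae":
        if len(encodings) < 2:
            raise SchemaError("fitting requires >= 2 encodings")
        shapes = {e.matrix.shape for e in encodings}
        if len(shapes) != 1:
            raise SchemaError(f"inconsistent one-hot shapes: {sorted(shapes)}")
        L, V = shapes.pop()
        self.input_shape = (L, V)
        X = np.stack([e.matrix for e in encodings]).reshape(len(encodings), L * V)
        X = X.astype(float)
        n, D = X.shape

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_params(D, rng)
        opt = Adam(self.params, lr=cfg.learning_rate)
        self.history = []

        for epoch in range(cfg.epochs):
            # linear KL annealing over the first half of training
            anneal = min(1.0, (epoch + 1) / max(1, cfg.epochs // 2))
            kl_w = cfg.kl_weight * anneal
            order = rng.permutation(n)
            recon_sum = kl_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = X[idx]
                B = xb.shape[0]

                h, mu, lv = self._encode_hidden(xb)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(0.5 * lv)
                zs = mu + std * eps
                h2, logits = self._decode(zs)
                probs = _row_softmax(logits.reshape(B, L, V))

                x3 = xb.reshape(B, L, V)
                recon = -np.sum(x3 * np.log(probs + 1e-12)) / B
                kl = -0.5 * np.sum(1 + lv - mu**2 - np.exp(lv)) / B
                recon_sum += recon * B
                kl_sum += kl * B

                # backward
                dlogits = (probs - x3).reshape(B, D) / B
                g = {}
                g["out_w"] = h2.T @ dlogits
                g["out_b"] = dlogits.sum(axis=0)
                dh2 = dlogits @ self.params["out_w"].T
                dh2[h2 <= 0] = 0.0
                g["dec_w"] = zs.T @ dh2
                g["dec_b"] = dh2.sum(axis=0)
                dz = dh2 @ self.params["dec_w"].T
                dmu = dz + kl_w * mu / B
                dlv = dz * eps * 0.5 * std + kl_w * 0.5 * (np.exp(lv) - 1) / B
                g["mu_w"] = h.T @ dmu
                g["mu_b"] = dmu.sum(axis=0)
                g["lv_w"] = h.T @ dlv
                g["lv_b"] = dlv.sum(axis=0)
                dh = dmu @ self.params["mu_w"].T + dlv @ self.params["lv_w"].T
                dh[h <= 0] = 0.0
                g["enc_w"] = xb.T @ dh
                g["enc_b"] = dh.sum(axis=0)
                opt.step(g)

            self.history.append(
                {"epoch": epoch, "recon": recon_sum / n, "kl": kl_sum / n}
            )
        self.fitted = True
        return self

    def encode_latent(self, encoding: OneHotEncoding) -> LatentVector:
        """Deterministic latent: the posterior mean of one encoding."""
        return LatentVector(values=self.encode_matrix(encoding.matrix[None])[0])

    def encode_matrix(self, matrices: np.ndarray) -> np.ndarray:
        """Posterior means for a (n, L, V) stack of one-hot matrices."""
        if not self.fitted:
            raise NotFittedError("VAE must be fitted before encoding")
        matrices = np.asarray(matrices, dtype=float)
        if matrices.shape[1:] != self.input_shape:
            raise SchemaError(
                f"expected one-hot shape {self.input_shape}, got {matrices.shape[1:]}"
            )
        X = matrices.reshape(matrices.shape[0], -1)
        _, mu, _ = self._encode_hidden(X)
        return mu
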