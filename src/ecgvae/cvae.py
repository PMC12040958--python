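"""Conditional VAE for 12-lead ECG median beats.

The model maps a 12 x 400 median beat x and a condition vector y (anatomical
pose, electrode coordinates, demographics, in any combination) to a 64-d
diagonal-Gaussian latent q(z | x, y) = N(mu, diag(exp(logvar))), and decodes
(z, y) back to a beat.  Training minimizes the conditional ELBO

    L = MSE(x, x_hat) + KL( q(z|x,y) || N(0, I) )

with equal weights, using Adam.  Conditioning is by concatenation: y joins the
flattened beat at the encoder's first fully connected layer and joins z at the
decoder input, so generation is controlled by swapping y while sampling
z ~ N(0, I).

The encoder/decoder are compact fully connected stacks with ELU activations
(hidden widths configurable through :class:`ModelConfig`); gradients are
hand-derived and exercised by finite-difference checks in the test suite.
Condition features mix units (mm, degrees, years), so they are z-scored with
statistics frozen from the training set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import (
    ConditionSchemaMismatch,
    DataTooSmall,
    ShapeMismatch,
    UntrainedModel,
)
from .nn import Adam, Dense, elu, elu_backward

__all__ = [
    "CONDITION_BLOCKS",
    "ConditionSchema",
    "ConditionScaler",
    "LatentState",
    "ModelConfig",
    "CVAE",
    "kl_divergence",
    "kl_loss",
    "recon_loss",
]

#: Named condition blocks and their dimensionalities.
CONDITION_BLOCKS: Dict[str, int] = {
    "heart_position": 3,
    "heart_orientation": 3,
    "electrodes": 30,
    "sex": 1,
    "age": 1,
    "bmi": 1,
}

_LOGVAR_LIMIT = 10.0  # clamp on log-variance for numerical safety


@dataclass(frozen=True)
class ConditionSchema:
    """Ordered list of named condition blocks; fixes the layout of y."""

    blocks: Tuple[str, ...]

    def __post_init__(self):
        unknown = [b for b in self.blocks if b not in CONDITION_BLOCKS]
        if unknown:
            raise ConditionSchemaMismatch(f"unknown condition blocks {unknown}")
        if len(set(self.blocks)) != len(self.blocks):
            raise ConditionSchemaMismatch("duplicate condition blocks")

    @property
    def dim(self) -> int:
        return sum(CONDITION_BLOCKS[b] for b in self.blocks)

    def slices(self) -> Dict[str, slice]:
        out, start = {}, 0
        for b in self.blocks:
            out[b] = slice(start, start + CONDITION_BLOCKS[b])
            start += CONDITION_BLOCKS[b]
        return out


@dataclass
class ConditionScaler:
    """Per-feature standardization statistics frozen from the training set."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, conds: np.ndarray) -> "ConditionScaler":
        mean = conds.mean(axis=0)
        scale = conds.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)  # constant features pass through
        return cls(mean, scale)

    def transform(self, conds: np.ndarray) -> np.ndarray:
        return (conds - self.mean) / self.scale


@dataclass(frozen=True)
class LatentState:
    """Encoder output: mean and log-variance of the diagonal Gaussian posterior."""

    mu: np.ndarray
    logvar: np.ndarray


@dataclass
class ModelConfig:
    """Hyperparameters for the cVAE (and, when present, the joint risk model)."""

    latent_dim: int = 64
    hidden_dims: Tuple[int, int] = (256, 128)
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 80
    beta: float = 1.0          # weight on the KL term (1 = plain ELBO)
    seed: int = 0
    standardize_beats: bool = False  # optional per-lead z-scoring of the beats
    augment_noise_sd: float = 0.0    # white-noise input augmentation (raw units)

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Closed-form KL(N(mu, diag e^logvar) || N(0, I)) per example (nats)."""
    return 0.5 * np.sum(mu * mu + np.exp(logvar) - 1.0 - logvar, axis=-1)


def kl_loss(state: LatentState) -> float:
    """Scalar KL for a single latent state (mean over examples if batched)."""
    return float(np.mean(kl_divergence(state.mu, state.logvar)))


def recon_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over all 12 x 400 entries (and the batch, if any)."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ShapeMismatch(f"{x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def _as_batch_beats(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    arr = arr.reshape(arr.shape) if arr.ndim != 4 else arr[:, 0]
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (12, 400):
        raise ShapeMismatch(f"expected (..., 12, 400), got {np.asarray(x).shape}")
    return arr, single


class CVAE:
    """Conditional VAE over 12 x 400 median beats with a named condition schema."""

    N_LEADS = 12
    N_SAMPLES = 400

    def __init__(self, schema: ConditionSchema, config: Optional[ModelConfig] = None):
        self.schema = schema
        self.config = config or ModelConfig()
        self.cond_scaler: Optional[ConditionScaler] = None
        self.beat_mean = np.zeros((self.N_LEADS, 1))
        self.beat_scale = np.ones((self.N_LEADS, 1))
        self.trained = False
        self.history: List[Dict[str, float]] = []
        self._build(np.random.default_rng(self.config.seed))

    # ------------------------------------------------------------------ setup
    def _build(self, rng: np.random.Generator) -> None:
        d_in = self.N_LEADS * self.N_SAMPLES
        c = self.schema.dim
        h1, h2 = self.config.hidden_dims
        k = self.config.latent_dim
        self.enc1 = Dense(d_in + c, h1, rng)
        self.enc2 = Dense(h1, h2, rng)
        self.mu_head = Dense(h2, k, rng)
        self.lv_head = Dense(h2, k, rng)
        self.dec1 = Dense(k + c, h2, rng)
        self.dec2 = Dense(h2, h1, rng)
        self.out = Dense(h1, d_in, rng)
        self.layers = [
            self.enc1, self.enc2, self.mu_head, self.lv_head,
            self.dec1, self.dec2, self.out,
        ]

    def _prep_cond(self, cond: np.ndarray) -> np.ndarray:
        arr = np.atleast_2d(np.asarray(cond, dtype=float))
        if arr.shape[1] != self.schema.dim:
            raise ConditionSchemaMismatch(
                f"condition has {arr.shape[1]} features, schema expects {self.schema.dim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ConditionSchemaMismatch("condition contains non-finite values")
        if self.cond_scaler is not None:
            arr = self.cond_scaler.transform(arr)
        return arr

    def _scale_beats(self, x: np.ndarray) -> np.ndarray:
        return (x - self.beat_mean) / self.beat_scale

    def _unscale_beats(self, x: np.ndarray) -> np.ndarray:
        return x * self.beat_scale + self.beat_mean

    # ------------------------------------------------------------ forward ops
    def encode(self, x, cond) -> LatentState:
        """Posterior parameters (mu, logvar) for beats x under condition y."""
        beats, single = _as_batch_beats(x)
        c = self._prep_cond(cond)
        if c.shape[0] == 1 and beats.shape[0] > 1:
            c = np.repeat(c, beats.shape[0], axis=0)
        xf = self._scale_beats(beats).reshape(beats.shape[0], -1)
        h1 = elu(self.enc1.forward(np.concatenate([xf, c], axis=1)))
        h2 = elu(self.enc2.forward(h1))
        mu = self.mu_head.forward(h2)
        lv = np.clip(self.lv_head.forward(h2), -_LOGVAR_LIMIT, _LOGVAR_LIMIT)
        if single:
            return LatentState(mu[0], lv[0])
        return LatentState(mu, lv)

    @staticmethod
    def reparameterize(state: LatentState, rng: np.random.Generator) -> np.ndarray:
        """Sample z = mu + exp(logvar / 2) * eps with eps ~ N(0, I)."""
        eps = rng.standard_normal(np.shape(state.mu))
        return state.mu + np.exp(0.5 * state.logvar) * eps

    def decode(self, z, cond) -> np.ndarray:
        """Decode latent z under condition y to a (12, 400) beat (or a batch)."""
        zb = np.atleast_2d(np.asarray(z, dtype=float))
        if zb.shape[1] != self.config.latent_dim:
            raise ShapeMismatch(f"z has dim {zb.shape[1]}, expected {self.config.latent_dim}")
        c = self._prep_cond(cond)
        if c.shape[0] == 1 and zb.shape[0] > 1:
            c = np.repeat(c, zb.shape[0], axis=0)
        g1 = elu(self.dec1.forward(np.concatenate([zb, c], axis=1)))
        g2 = elu(self.dec2.forward(g1))
        xf = self.out.forward(g2)
        beats = self._unscale_beats(xf.reshape(-1, self.N_LEADS, self.N_SAMPLES))
        return beats[0] if np.asarray(z).ndim == 1 else beats

    # --------------------------------------------------------------- training
    def fit(
        self,
        beats: np.ndarray,
        conds: np.ndarray,
        epochs: Optional[int] = None,
        survival_hook=None,
        verbose: bool = False,
    ) -> List[Dict[str, float]]:
        """Train on (beat, condition) pairs; optionally with a survival hook.

        ``survival_hook`` (see :mod:`ecgvae.survival`) receives the posterior
        mean mu of every batch together with the batch indices and returns the
        survival loss and its gradient with respect to mu; its own parameters
        join the Adam update.  The full run is deterministic for a fixed
        config seed.
        """
        cfg = self.config
        beats = np.asarray(beats, dtype=float)
        conds = np.atleast_2d(np.asarray(conds, dtype=float))
        n = beats.shape[0]
        if n < 2 * cfg.batch_size:
            raise DataTooSmall(f"need >= {2 * cfg.batch_size} examples, got {n}")
        if beats.shape[1:] != (self.N_LEADS, self.N_SAMPLES):
            raise ShapeMismatch(f"beats must be (n, 12, 400), got {beats.shape}")
        if conds.shape != (n, self.schema.dim):
            raise ConditionSchemaMismatch(
                f"conditions must be (n, {self.schema.dim}), got {conds.shape}"
            )

        rng = np.random.default_rng(cfg.seed)
        self.cond_scaler = ConditionScaler.fit(conds)
        if cfg.standardize_beats:
            self.beat_mean = beats.mean(axis=(0, 2)).reshape(self.N_LEADS, 1)
            scale = beats.std(axis=(0, 2)).reshape(self.N_LEADS, 1)
            self.beat_scale = np.where(scale < 1e-12, 1.0, scale)
        c_std = self.cond_scaler.transform(conds)
        x_all = self._scale_beats(beats).reshape(n, -1)

        pairs = [pg for layer in self.layers for pg in layer.params_and_grads]
        if survival_hook is not None and getattr(survival_hook, "optimizer", None) is None:
            pairs = pairs + survival_hook.params_and_grads
        opt = Adam(pairs, lr=cfg.learning_rate)
        n_epochs = epochs if epochs is not None else cfg.epochs
        d_in = self.N_LEADS * self.N_SAMPLES
        history: List[Dict[str, float]] = []

        for epoch in range(n_epochs):
            if survival_hook is not None and hasattr(survival_hook, "set_epoch"):
                survival_hook.set_epoch(epoch, n_epochs)
            order = rng.permutation(n)
            sums = {"recon": 0.0, "kl": 0.0, "surv": 0.0}
            n_batches = 0
            for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x = x_all[idx]
                c = c_std[idx]
                B = x.shape[0]
                if cfg.augment_noise_sd > 0:
                    # denoising-style augmentation: the encoder sees a freshly
                    # corrupted input, the reconstruction target stays clean
                    x_in = x + rng.normal(0.0, cfg.augment_noise_sd, x.shape)
                else:
                    x_in = x

                # ---- forward
                a1 = self.enc1.forward(np.concatenate([x_in, c], axis=1))
                h1 = elu(a1)
                a2 = self.enc2.forward(h1)
                h2 = elu(a2)
                mu = self.mu_head.forward(h2)
                lv_raw = self.lv_head.forward(h2)
                lv = np.clip(lv_raw, -_LOGVAR_LIMIT, _LOGVAR_LIMIT)
                eps = rng.standard_normal(mu.shape)
                sig = np.exp(0.5 * lv)
                z = mu + sig * eps
                b1 = self.dec1.forward(np.concatenate([z, c], axis=1))
                g1 = elu(b1)
                b2 = self.dec2.forward(g1)
                g2 = elu(b2)
                x_hat = self.out.forward(g2)

                l_recon = float(np.mean((x_hat - x) ** 2))
                l_kl = float(np.mean(kl_divergence(mu, lv)))
                # ---- backward (zero grads first: the hook accumulates into its own)
                for layer in self.layers:
                    layer.zero_grad()
                l_surv = 0.0
                dmu_surv = 0.0
                if survival_hook is not None:
                    survival_hook.zero_grad()
                    # risk is scored on the posterior mean, matching evaluation
                    l_surv, dmu_surv = survival_hook.loss_and_grad(mu, idx)
                d_xhat = 2.0 * (x_hat - x) / (B * d_in)
                dg2 = self.out.backward(d_xhat)
                dg1 = self.dec2.backward(elu_backward(dg2, b2))
                d_din = self.dec1.backward(elu_backward(dg1, b1))
                dz = d_din[:, : cfg.latent_dim]
                dmu = dz + cfg.beta * mu / B + dmu_surv
                dlv = dz * eps * 0.5 * sig + cfg.beta * 0.5 * (np.exp(lv) - 1.0) / B
                dlv *= (np.abs(lv_raw) < _LOGVAR_LIMIT)  # clamp is flat outside
                dh2 = self.mu_head.backward(dmu) + self.lv_head.backward(dlv)
                dh1 = self.enc2.backward(elu_backward(dh2, a2))
                self.enc1.backward(elu_backward(dh1, a1))
                opt.step()
                if survival_hook is not None and getattr(survival_hook, "optimizer", None) is not None:
                    survival_hook.optimizer.step()

                sums["recon"] += l_recon
                sums["kl"] += l_kl
                sums["surv"] += l_surv
                n_batches += 1
            entry = {
                "epoch": epoch,
                "recon": sums["recon"] / n_batches,
                "kl": sums["kl"] / n_batches,
            }
            if survival_hook is not None:
                entry["surv"] = sums["surv"] / n_batches
            history.append(entry)
            if verbose:
                print(
                    f"epoch {epoch:3d}  recon {entry['recon']:.4f}  kl {entry['kl']:.4f}"
                    + (f"  surv {entry['surv']:.4f}" if "surv" in entry else "")
                )
        self.trained = True
        self.history = history
        return history

    # ------------------------------------------------------------- generation
    def generate(self, cond, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n beats for condition y by decoding z ~ N(0, I)."""
        if not self.trained:
            raise UntrainedModel("call fit() before generate()")
        z = rng.standard_normal((n, self.config.latent_dim))
        c = np.atleast_2d(np.asarray(cond, dtype=float))
        if c.shape[0] not in (1, n):
            raise ConditionSchemaMismatch("condition batch must be 1 or n")
        if c.shape[0] == 1:
            c = np.repeat(c, n, axis=0)
        return self.decode(z, c)

    # ------------------------------------------------------------ persistence
    def save(self, path: str) -> None:
        """Single-file checkpoint: config, schema, scalers, and all weights."""
        meta = {
            "config": asdict(self.config),
            "schema": list(self.schema.blocks),
            "trained": self.trained,
            "history": self.history,
        }
        arrays = {"beat_mean": self.beat_mean, "beat_scale": self.beat_scale}
        if self.cond_scaler is not None:
            arrays["cond_mean"] = self.cond_scaler.mean
            arrays["cond_scale"] = self.cond_scaler.scale
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "CVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg = meta["config"]
            cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
            model = cls(ConditionSchema(tuple(meta["schema"])), ModelConfig(**cfg))
            for i, layer in enumerate(model.layers):
                layer.W = data[f"W{i}"].copy()
                layer.b = data[f"b{i}"].copy()
            model.beat_mean = data["beat_mean"].copy()
            model.beat_scale = data["beat_scale"].copy()
            if "cond_mean" in data:
                model.cond_scaler = ConditionScaler(
                    data["cond_mean"].copy(), data["cond_scale"].copy()
                )
            model.trained = bool(meta["trained"])
            model.history = meta["history"]
        return model
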