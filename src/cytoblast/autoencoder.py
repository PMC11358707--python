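"""Autoencoder / variational autoencoder core for anomaly detection.

A compact fully-connected autoencoder implemented directly on numpy with an
Adam optimiser.  The encoder compresses the scaled marker panel (23 channels
by default) into a low-dimensional latent space (default 4); the decoder
mirrors the encoder.  Trained only on healthy reference (remission) cells,
the model reconstructs unseen aberrant immunophenotypes poorly, and the
per-marker squared reconstruction error (SRE) becomes the feature vector of
the downstream blast classifier.

The variational variant adds a KL term to the reconstruction loss; both its
latent encoding and its reconstruction use the posterior mean, so SRE
features are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import CellMatrix
from .preprocess import MinMaxScaler, apply_minmax, fit_minmax


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class AEConfig:
    """Hyperparameters of one autoencoder.

    ``layer_widths`` lists the encoder layer widths *including* the input
    layer (e.g. ``[23, 16, 8]``); the decoder mirrors it.  The latent layer
    (``latent_dim``) sits between the two stacks.
    """

    architecture: str = "ae"  # "ae" | "vae"
    layer_widths: tuple[int, ...] = (23, 16, 8)
    latent_dim: int = 4
    activation: str = "relu"  # "relu" | "tanh" | "linear"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 256
    kl_weight: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("ae", "vae"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.activation not in ("relu", "tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.latent_dim < 1 or self.latent_dim >= self.layer_widths[0]:
            raise ValueError("latent_dim must be in [1, n_channels)")
        if any(w < 1 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimiser settings")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "tanh":
        return np.tanh(x)
    return x


def _act_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (pre > 0).astype(np.float64)
    if kind == "tanh":
        return 1.0 - post**2
    return np.ones_like(pre)


def _init_stack(widths: list[int], rng: np.random.Generator) -> list[list[np.ndarray]]:
    params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        params.append([rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                       np.zeros(fan_out)])
    return params


def _forward(params, X, activation, hidden_only_last_linear=True):
    """Forward pass; the final layer is linear, hidden layers use activation."""
    acts = [X]
    pres = []
    h = X
    n = len(params)
    for i, (W, b) in enumerate(params):
        z = h @ W + b
        pres.append(z)
        h = z if i == n - 1 else _act(z, activation)
        acts.append(h)
    return h, (acts, pres)


def _backward(params, cache, dOut, activation):
    acts, pres = cache
    grads = []
    delta = dOut
    n = len(params)
    for i in range(n - 1, -1, -1):
        W, _ = params[i]
        if i != n - 1:
            delta = delta * _act_grad(pres[i], acts[i + 1], activation)
        gW = acts[i].T @ delta
        gb = delta.sum(axis=0)
        grads.append((gW, gb))
        delta = delta @ W.T
    grads.reverse()
    return grads, delta


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in layer] for layer in params]
        self.v = [[np.zeros_like(p) for p in layer] for layer in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for layer, glayer, mlayer, vlayer in zip(params, grads, self.m, self.v):
            for j, (p, g) in enumerate(zip(layer, glayer)):
                mlayer[j] = self.b1 * mlayer[j] + (1 - self.b1) * g
                vlayer[j] = self.b2 * vlayer[j] + (1 - self.b2) * g**2
                p -= self.lr * (mlayer[j] / corr1) / (np.sqrt(vlayer[j] / corr2) + self.eps)


@dataclass
class SREMatrix:
    """Per-cell per-marker squared reconstruction error (nonnegative)."""

    values: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("SRE entries must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def total_per_cell(self) -> np.ndarray:
        """Row sums: each cell's total squared reconstruction error."""
        return self.values.sum(axis=1)


@dataclass
class TrainedAutoencoder:
    """A fitted model: weights, config, training loss and the scaler used."""

    config: AEConfig
    enc_params: list
    dec_params: list
    training_mse: float
    scaler: MinMaxScaler | None = None
    loss_history: list = field(default_factory=list)

    # -- deterministic forward passes -------------------------------------
    def encode_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.config.layer_widths[0]:
            raise ValueError(
                f"expected {self.config.layer_widths[0]} channels, got {X.shape[1] if X.ndim == 2 else '?'}"
            )
        h, _ = _forward(self.enc_params, X, self.config.activation)
        if self.config.architecture == "vae":
            h = h[:, : self.config.latent_dim]  # posterior mean
        return h

    def reconstruct_values(self, X: np.ndarray) -> np.ndarray:
        z = self.encode_values(X)
        out, _ = _forward(self.dec_params, z, self.config.activation)
        return out

    def sre_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return (X - self.reconstruct_values(X)) ** 2

    def mse(self, X: np.ndarray) -> float:
        """Mean per-entry squared reconstruction error over a matrix."""
        return float(self.sre_values(X).mean())

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "enc_params": [[W.tolist(), b.tolist()] for W, b in self.enc_params],
            "dec_params": [[W.tolist(), b.tolist()] for W, b in self.dec_params],
            "training_mse": self.training_mse,
            "scaler": None if self.scaler is None else self.scaler.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedAutoencoder":
        cfg = d["config"]
        cfg["layer_widths"] = tuple(cfg["layer_widths"])
        return cls(
            config=AEConfig(**cfg),
            enc_params=[[np.asarray(W), np.asarray(b)] for W, b in d["enc_params"]],
            dec_params=[[np.asarray(W), np.asarray(b)] for W, b in d["dec_params"]],
            training_mse=float(d["training_mse"]),
            scaler=None if d.get("scaler") is None else MinMaxScaler.from_dict(d["scaler"]),
        )

    @classmethod
    def load(cls, path) -> "TrainedAutoencoder":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_autoencoder(
    train: CellMatrix, config: AEConfig, scaler: MinMaxScaler | None = None
) -> TrainedAutoencoder:
    """Fit an AE or VAE on a scaled training matrix.

    The loss is the mean squared reconstruction error, plus
    ``kl_weight * KL`` for the VAE.  Training is fully deterministic under
    ``config.seed``.
    """
    train.require_state("scaled")
    if config.layer_widths[0] != train.n_channels:
        raise ValueError(
            f"first layer width {config.layer_widths[0]} != {train.n_channels} channels"
        )
    X = train.values
    vae = config.architecture == "vae"
    rng = np.random.default_rng(config.seed)
    enc_widths = list(config.layer_widths) + [config.latent_dim * (2 if vae else 1)]
    dec_widths = [config.latent_dim] + list(reversed(config.layer_widths))
    enc = _init_stack(enc_widths, rng)
    dec = _init_stack(dec_widths, rng)
    opt = _Adam(enc + dec, config.learning_rate)

    n = X.shape[0]
    d = config.latent_dim
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_recon = 0.0
        epoch_kl = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            xb = X[order[start : start + config.batch_size]]
            B = xb.shape[0]
            h, enc_cache = _forward(enc, xb, config.activation)
            if vae:
                mu, logvar = h[:, :d], h[:, d:]
                logvar = np.clip(logvar, -10.0, 10.0)
                eps = rng.standard_normal(mu.shape)
                z = mu + np.exp(0.5 * logvar) * eps
            else:
                z = h
            xhat, dec_cache = _forward(dec, z, config.activation)

            recon = float(((xb - xhat) ** 2).mean())
            dxhat = 2.0 * (xhat - xb) / xhat.size
            dec_grads, dz = _backward(dec, dec_cache, dxhat, config.activation)

            if vae:
                kl = float(-0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar)) / B)
                dmu = dz + config.kl_weight * mu / B
                dlogvar = (
                    dz * eps * 0.5 * np.exp(0.5 * logvar)
                    + config.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / B
                )
                dh = np.concatenate([dmu, dlogvar], axis=1)
                epoch_kl += kl
            else:
                dh = dz
            enc_grads, _ = _backward(enc, enc_cache, dh, config.activation)

            if not np.isfinite(recon):
                raise TrainingDivergenceError(f"loss diverged with config {config}")
            opt.step(enc + dec, enc_grads + dec_grads)
            epoch_recon += recon
            n_batches += 1
        history.append({
            "epoch": epoch,
            "mse": epoch_recon / n_batches,
            "kl": epoch_kl / n_batches if vae else 0.0,
        })

    model = TrainedAutoencoder(config=config, enc_params=enc, dec_params=dec,
                               training_mse=0.0, scaler=scaler, loss_history=history)
    model.training_mse = model.mse(X)
    if not np.isfinite(model.training_mse):
        raise TrainingDivergenceError(f"final loss non-finite with config {config}")
    return model


def encode(model: TrainedAutoencoder, m: CellMatrix) -> np.ndarray:
    """Latent coordinates (n_cells x latent_dim) of a scaled matrix."""
    m.require_state("scaled")
    return model.encode_values(m.values)


def sre(model: TrainedAutoencoder, m: CellMatrix) -> SREMatrix:
    """Per-marker squared reconstruction error of a scaled matrix."""
    m.require_state("scaled")
    return SREMatrix(values=model.sre_values(m.values), channels=list(m.channels))


# --------------------------------------------------------------------------
# Randomised hyperparameter search with k-fold cross-validation


DEFAULT_GRID = {
    "n_hidden": [1, 2, 3],
    "hidden_width": (8, 64),
    "latent_dim": [2, 3, 4, 5, 6],
    "activation": ["relu", "tanh"],
    "learning_rate": (1e-4, 1e-2, "log"),
    "epochs": [15],
    "batch_size": [256],
    "kl_weight": [1e-3],
}


def sample_configs(
    grid: dict, n_samples: int, n_channels: int, seed: int
) -> list[dict]:
    """Draw ``n_samples`` architecture-agnostic hyperparameter settings."""
    rng = np.random.default_rng(seed)

    def draw(spec):
        if isinstance(spec, list):
            return spec[rng.integers(len(spec))]
        if isinstance(spec, tuple) and len(spec) == 3 and spec[2] == "log":
            return float(np.exp(rng.uniform(np.log(spec[0]), np.log(spec[1]))))
        if isinstance(spec, tuple) and len(spec) == 2:
            return int(rng.integers(spec[0], spec[1] + 1))
        raise ValueError(f"cannot sample from grid entry {spec!r}")

    out = []
    for _ in range(n_samples):
        n_hidden = int(draw(grid["n_hidden"]))
        widths = sorted(
            (int(draw(grid["hidden_width"])) for _ in range(n_hidden)), reverse=True
        )
        latent = int(draw(grid["latent_dim"]))
        widths = [max(w, latent + 1) for w in widths]
        out.append({
            "layer_widths": tuple([n_channels] + widths),
            "latent_dim": min(latent, n_channels - 1),
            "activation": draw(grid["activation"]),
            "learning_rate": float(draw(grid["learning_rate"])),
            "epochs": int(draw(grid["epochs"])),
            "batch_size": int(draw(grid["batch_size"])),
            "kl_weight": float(draw(grid["kl_weight"])),
        })
    return out


@dataclass
class CVReport:
    """Fold-level validation MSEs of the randomised search plus the winner."""

    records: list
    n_configs: int
    n_folds: int
    selected_config: AEConfig | None = None
    final_model: TrainedAutoencoder | None = None

    @property
    def n_fits(self) -> int:
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def hyperparameter_search(
    train: CellMatrix,
    grid: dict | None = None,
    n_samples: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    architectures: tuple[str, ...] = ("ae", "vae"),
    trainer=None,
) -> CVReport:
    """Randomised search: every sampled setting is trained as every
    architecture on every fold; the (setting, architecture) pair with the
    lowest fold-mean validation MSE is retrained on the full training set.

    ``train`` may be in arcsinh state — the min-max scaler is then refit on
    each fold's training part (and on the full set for the final retrain) —
    or already scaled, in which case scaling is reused as-is.  ``trainer``
    is injectable for accounting/stub runs; it must return an object with an
    ``mse(X)`` method.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if train.n_cells < n_folds:
        raise ValueError("fewer cells than folds")
    grid = grid or DEFAULT_GRID
    trainer = trainer or train_autoencoder
    settings = sample_configs(grid, n_samples, train.n_channels, seed)
    if not settings:
        raise ValueError("empty search space")

    rng = np.random.default_rng(seed)
    fold_ids = rng.permutation(train.n_cells) % n_folds

    def fold_matrices(f: int) -> tuple[CellMatrix, CellMatrix]:
        tr = train.subset(fold_ids != f)
        va = train.subset(fold_ids == f)
        if train.state == "arcsinh":
            scaler = fit_minmax(tr)
            return apply_minmax(scaler, tr), apply_minmax(scaler, va)
        return tr, va

    prepared = [fold_matrices(f) for f in range(n_folds)]
    records = []
    for ci, setting in enumerate(settings):
        for arch in architectures:
            config = AEConfig(architecture=arch, seed=int(seed) + ci, **setting)
            for f, (tr, va) in enumerate(prepared):
                try:
                    model = trainer(tr, config)
                    val_mse = float(model.mse(va.values))
                except TrainingDivergenceError:
                    val_mse = float("inf")
                records.append({
                    "config_index": ci, "architecture": arch, "fold": f,
                    "val_mse": val_mse, **{k: str(v) for k, v in setting.items()},
                })

    frame_keys = {}
    for r in records:
        key = (r["config_index"], r["architecture"])
        frame_keys.setdefault(key, []).append(r["val_mse"])
    means = {k: float(np.mean(v)) for k, v in frame_keys.items()}
    if all(not np.isfinite(v) for v in means.values()):
        raise TrainingDivergenceError("all sampled configurations diverged")
    best_key = min(means, key=lambda k: (means[k], k))
    ci, arch = best_key
    selected = AEConfig(architecture=arch, seed=int(seed) + ci, **settings[ci])

    if train.state == "arcsinh":
        full_scaler = fit_minmax(train)
        full_scaled = apply_minmax(full_scaler, train)
    else:
        full_scaler, full_scaled = None, train
    final = trainer(full_scaled, selected)
    if isinstance(final, TrainedAutoencoder):
        final.scaler = full_scaler
    return CVReport(records=records, n_configs=len(settings), n_folds=n_folds,
                    selected_config=selected, final_model=final)
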