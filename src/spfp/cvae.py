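"""Conditional variational autoencoder over structure-potency fingerprints.

The model learns, per activity class, to reconstruct the cumulative
potency module X conditioned on the structure module c. The encoder
q(z|X, c) maps [X | c] through tanh hidden layers to a diagonal
Gaussian over the latent variable z; the decoder p(X|z, c) maps [z | c]
through mirrored hidden layers to per-bit Bernoulli probabilities. The
training objective is the negative evidence lower bound

    L = E_batch[ BCE(X, X_hat) + beta * KL(q(z|X,c) || N(0, I)) ],

with the binary cross-entropy summed over the module's bits and the KL
divergence in closed form for diagonal Gaussians. beta > 1 weights the
regularizer as in a beta-VAE.

Prediction submits only the structure module: z is sampled from
N(0, sigma^2 I), decoded under condition c, and binarized; the sample
is accepted only if it passes the cumulative-encoding validity check
(a non-empty contiguous prefix of ones), in which case it decodes to
the center of its potency interval. Invalid samples trigger resampling
up to a cap.

The network is implemented directly in NumPy (dense layers, tanh,
inverted dropout, Adam, hand-written backprop); all randomness flows
from a single seed.
"""

from __future__ import annotations

import itertools
import json
import zipfile
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .encoding import (
    DEFAULT_SPEC,
    SPFP,
    STRUCTURE_BITS,
    PotencyModuleSpec,
    decode_potency,
    encode_potency,
)

__all__ = [
    "CVAEConfig",
    "GRID",
    "TrainingDivergedError",
    "PredictionResult",
    "TrainedCVAE",
    "elbo_loss",
    "fit",
    "predict",
    "tune",
    "CVAERegressor",
]

#: Hyperparameter search space. ``tune`` accepts any sub-grid of it.
GRID: dict[str, list] = {
    "latent_dim": [16, 32, 64],
    "learning_rate": [0.1, 0.01, 0.001],
    "dropout": [0.0, 0.5],
    "batch_size": [16, 32, 64],
    "beta": [1.0, 2.0],
    "sigma": [0.01, 0.1, 1.0],
}

_PROB_EPS = 1e-7
_LOGVAR_CLIP = 15.0


class TrainingDivergedError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class CVAEConfig:
    """Architecture and training settings.

    ``hidden_sizes`` are the encoder's layer widths; the decoder mirrors
    them in reverse. ``beta`` weights the KL term of the objective;
    ``sigma`` is the standard deviation of prior sampling at prediction
    time (training always uses the N(0, I) prior in the KL). The
    learning rate is halved whenever the validation loss stalls for
    ``lr_patience`` epochs, and training stops early after
    ``early_stop_patience`` stalled epochs with best weights restored.
    """

    hidden_sizes: tuple[int, ...] = (512, 256, 128)
    latent_dim: int = 32
    learning_rate: float = 0.001
    dropout: float = 0.0
    batch_size: int = 64
    beta: float = 1.0
    sigma: float = 0.1
    max_epochs: int = 150
    max_sampling_attempts: int = 100
    binarize_threshold: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class PredictionResult:
    """Outcome of one sampling-based potency prediction."""

    predicted_pIC50: float
    valid: bool
    attempts: int
    interval_halfwidth: float


def elbo_loss(
    x: np.ndarray,
    x_prob: np.ndarray,
    mu: np.ndarray,
    logvar: np.ndarray,
    beta: float = 1.0,
) -> float:
    """Negative ELBO of a batch, from reconstruction probabilities.

    ``x`` and ``x_prob`` are (batch, L) bit targets and per-bit
    probabilities; ``mu``/``logvar`` parameterize the approximate
    posterior. Probabilities are clamped away from exact 0/1 so a
    saturated output against an opposite target stays finite.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_prob = np.clip(np.atleast_2d(np.asarray(x_prob, dtype=float)), _PROB_EPS, 1 - _PROB_EPS)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    if x.shape != x_prob.shape:
        raise ValueError("x and x_prob must have the same shape")
    bce = -(x * np.log(x_prob) + (1 - x) * np.log(1 - x_prob)).sum(axis=1)
    kl = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=1)
    return float(np.mean(bce + beta * kl))


# ---------------------------------------------------------------------------
# network internals


class _MLP:
    """Plain dense tanh stack with linear output head(s)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        # Glorot-uniform initialization
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray, dropout: float, rng: np.random.Generator | None):
        """Tanh after every layer except the last; inverted dropout on
        hidden activations when ``rng`` is given (training mode)."""
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            pre = h @ W + b
            if i < last:
                a = np.tanh(pre)
                mask = None
                if dropout > 0 and rng is not None:
                    mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                cache.append((h, a, mask))
                h = a if mask is None else a * mask
            else:
                cache.append((h, None, None))
                h = pre
        return h, cache

    def backward(self, dout: np.ndarray, cache) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return gradient w.r.t. the input and w.r.t. params()."""
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        grad = dout
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            h_in, a, mask = cache[i]
            if i < last:
                if mask is not None:
                    grad = grad * mask
                grad = grad * (1.0 - a * a)
            dW[i] = h_in.T @ grad
            db[i] = grad.sum(axis=0)
            grad = grad @ self.W[i].T
        return grad, dW + db


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# trained model


@dataclass
class TrainedCVAE:
    """Fitted encoder/decoder with config, module spec and history."""

    config: CVAEConfig
    spec: PotencyModuleSpec
    encoder: _MLP = field(repr=False)
    decoder: _MLP = field(repr=False)
    history: list[dict] = field(default_factory=list, repr=False)

    def encode(self, x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, logvar) for potency modules x under
        conditions c."""
        inp = np.concatenate([x, c], axis=1).astype(float)
        out, _ = self.encoder.forward(inp, 0.0, None)
        d = self.config.latent_dim
        mu, logvar = out[:, :d], np.clip(out[:, d:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, logvar

    def decode(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Per-bit Bernoulli probabilities of the potency module."""
        inp = np.concatenate([z, c], axis=1).astype(float)
        logits, _ = self.decoder.forward(inp, 0.0, None)
        return _sigmoid(logits)

    def reconstruct(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Posterior-mean reconstruction probabilities (no sampling)."""
        mu, _ = self.encode(x, c)
        return self.decode(mu, c)

    def predict(self, c: np.ndarray, rng: np.random.Generator | None = None) -> PredictionResult:
        """Sampling-based potency prediction for one structure module."""
        c = np.asarray(c, dtype=float).reshape(1, -1)
        values, valid, attempts = self._predict_matrix(c, rng)
        return PredictionResult(
            predicted_pIC50=float(values[0]),
            valid=bool(valid[0]),
            attempts=int(attempts[0]),
            interval_halfwidth=self.spec.resolution / 2.0,
        )

    def predict_batch(
        self, C: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized prediction: (values, valid flags, attempt counts)."""
        return self._predict_matrix(np.asarray(C, dtype=float), rng)

    def _predict_matrix(self, C: np.ndarray, rng: np.random.Generator | None):
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed + 1)
        n, L = C.shape[0], self.spec.n_bits
        values = np.zeros(n)
        valid = np.zeros(n, dtype=bool)
        attempts = np.zeros(n, dtype=int)
        last_prob = np.zeros((n, L))
        active = np.ones(n, dtype=bool)
        for _ in range(cfg.max_sampling_attempts):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            z = rng.normal(0.0, cfg.sigma, size=(idx.size, cfg.latent_dim))
            prob = self.decode(z, C[idx])
            last_prob[idx] = prob
            bits = prob >= cfg.binarize_threshold
            attempts[idx] += 1
            pop = bits.sum(axis=1)
            ok = (pop >= 1) & np.all(bits == (np.arange(L)[None, :] < pop[:, None]), axis=1)
            hit = idx[ok]
            if hit.size:
                r = self.spec.resolution
                values[hit] = self.spec.range_low + (pop[ok] - 1) * r + r / 2.0
                valid[hit] = True
                active[hit] = False
        # fallback: longest prefix of confident bits from the last sample
        rest = np.flatnonzero(active)
        if rest.size:
            conf = last_prob[rest] >= cfg.binarize_threshold
            k = np.argmin(conf, axis=1)  # first low-confidence position
            k = np.where(conf.all(axis=1), L, k)
            k = np.maximum(k, 1)
            r = self.spec.resolution
            values[rest] = self.spec.range_low + (k - 1) * r + r / 2.0
        return values, valid, attempts

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Archive weights plus a JSON manifest and history CSV."""
        import io

        manifest = {
            "config": asdict(self.config),
            "spec": json.loads(self.spec.to_json()),
            "n_encoder_params": len(self.encoder.params()),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))
            buf = io.BytesIO()
            arrays = {f"enc_{i}": p for i, p in enumerate(self.encoder.params())}
            arrays |= {f"dec_{i}": p for i, p in enumerate(self.decoder.params())}
            np.savez(buf, **arrays)
            zf.writestr("weights.npz", buf.getvalue())
            hist = "epoch,train_loss,val_loss,lr\n" + "\n".join(
                f"{h['epoch']},{h['train_loss']},{h['val_loss']},{h['lr']}"
                for h in self.history
            )
            zf.writestr("history.csv", hist)

    @classmethod
    def load(cls, path) -> "TrainedCVAE":
        import io

        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            cfg_d = manifest["config"]
            cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
            config = CVAEConfig(**cfg_d)
            spec = PotencyModuleSpec(**manifest["spec"])
            data = np.load(io.BytesIO(zf.read("weights.npz")))
        model = _build_model(config, spec, np.random.default_rng(0))
        enc_params = model.encoder.params()
        dec_params = model.decoder.params()
        for i, p in enumerate(enc_params):
            p[...] = data[f"enc_{i}"]
        for i, p in enumerate(dec_params):
            p[...] = data[f"dec_{i}"]
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _build_model(config: CVAEConfig, spec: PotencyModuleSpec, rng: np.random.Generator) -> TrainedCVAE:
    L, d = spec.n_bits, config.latent_dim
    enc_sizes = [L + STRUCTURE_BITS, *config.hidden_sizes, 2 * d]
    dec_sizes = [d + STRUCTURE_BITS, *reversed(config.hidden_sizes), L]
    return TrainedCVAE(
        config=config,
        spec=spec,
        encoder=_MLP(enc_sizes, rng),
        decoder=_MLP(dec_sizes, rng),
    )


def _spfps_to_matrices(spfps: Sequence[SPFP]) -> tuple[np.ndarray, np.ndarray, PotencyModuleSpec]:
    specs = {s.spec for s in spfps}
    if len(specs) != 1:
        raise ValueError("all SPFPs must share one potency-module spec")
    X = np.vstack([s.potency for s in spfps]).astype(float)
    C = np.vstack([s.structure for s in spfps]).astype(float)
    return X, C, next(iter(specs))


def fit(spfps: Sequence[SPFP], config: CVAEConfig = CVAEConfig()) -> TrainedCVAE:
    """Train a CVAE on the SPFPs of an activity class's training set."""
    if len(spfps) < 2:
        raise ValueError("need at least 2 training compounds")
    X, C, spec = _spfps_to_matrices(spfps)
    return fit_matrices(X, C, spec, config)


def fit_matrices(
    X: np.ndarray, C: np.ndarray, spec: PotencyModuleSpec, config: CVAEConfig
) -> TrainedCVAE:
    """Train from raw potency-module / structure-module matrices."""
    rng = np.random.default_rng(config.seed)
    model = _build_model(config, spec, rng)
    n = X.shape[0]

    # internal validation split for the LR schedule and early stopping
    n_val = max(1, int(round(config.val_fraction * n))) if n >= 5 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ctr = X[tr_idx], C[tr_idx]
    Xval, Cval = X[val_idx], C[val_idx]

    params = model.encoder.params() + model.decoder.params()
    opt = _Adam(params, config.learning_rate)
    d = config.latent_dim
    n_enc = len(model.encoder.params())

    best_val = np.inf
    best_weights = [p.copy() for p in params]
    stall = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(Xtr), config.batch_size):
            bidx = order[start : start + config.batch_size]
            xb, cb = Xtr[bidx], Ctr[bidx]
            B = len(bidx)

            # ---- forward
            enc_in = np.concatenate([xb, cb], axis=1)
            enc_out, enc_cache = model.encoder.forward(enc_in, config.dropout, rng)
            mu, logvar = enc_out[:, :d], np.clip(enc_out[:, d:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + eps * std
            dec_in = np.concatenate([z, cb], axis=1)
            logits, dec_cache = model.decoder.forward(dec_in, config.dropout, rng)
            prob = _sigmoid(logits)

            bce = -(
                xb * np.log(np.clip(prob, _PROB_EPS, 1.0))
                + (1 - xb) * np.log(np.clip(1 - prob, _PROB_EPS, 1.0))
            ).sum(axis=1)
            kl = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=1)
            loss = float(np.mean(bce + config.beta * kl))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_loss += loss * B

            # ---- backward
            dlogits = (prob - xb) / B
            ddec_in, dec_grads = model.decoder.backward(dlogits, dec_cache)
            dz = ddec_in[:, :d]
            dmu = dz + config.beta * mu / B
            dlogvar = dz * eps * 0.5 * std + config.beta * 0.5 * (np.exp(logvar) - 1.0) / B
            denc_out = np.concatenate([dmu, dlogvar], axis=1)
            _, enc_grads = model.encoder.backward(denc_out, enc_cache)
            opt.step(enc_grads + dec_grads)

        train_loss = epoch_loss / len(Xtr)
        if n_val:
            mu_v, logvar_v = model.encode(Xval, Cval)
            prob_v = model.decode(mu_v, Cval)
            val_loss = elbo_loss(Xval, prob_v, mu_v, logvar_v, config.beta)
        else:
            val_loss = train_loss
        model.history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": opt.lr}
        )

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall % config.lr_patience == 0:
                opt.lr *= 0.5
            if stall >= config.early_stop_patience:
                break

    for p, w in zip(params, best_weights):
        p[...] = w
    return model


def predict(c: np.ndarray, model: TrainedCVAE, rng: np.random.Generator | None = None) -> PredictionResult:
    """Functional form of :meth:`TrainedCVAE.predict`."""
    return model.predict(c, rng)


def tune(
    X: np.ndarray,
    C: np.ndarray,
    spec: PotencyModuleSpec = DEFAULT_SPEC,
    grid: dict[str, list] | None = None,
    base_config: CVAEConfig = CVAEConfig(),
    n_folds: int = 5,
    potencies: np.ndarray | None = None,
) -> tuple[CVAEConfig, list[dict]]:
    """Grid search by internal cross-validated MAE of decoded predictions.

    ``grid`` maps config field names to candidate values (defaults to
    the full :data:`GRID`); every combination is scored by k-fold CV on
    (X, C) and the argmin returned along with the full score table.
    Configurations that diverge score infinity and are never selected
    while any finite-scoring one exists.
    """
    grid = grid if grid is not None else GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    if potencies is None:
        potencies = np.array([decode_potency(row.astype(np.uint8), spec) for row in X])

    n = X.shape[0]
    rng = np.random.default_rng(base_config.seed)
    fold_of = rng.permutation(n) % n_folds

    keys = sorted(grid)
    table: list[dict] = []
    best_cfg, best_score = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        fold_mae = []
        for f in range(n_folds):
            tr, va = fold_of != f, fold_of == f
            if tr.sum() < 2 or va.sum() < 1:
                continue
            try:
                m = fit_matrices(X[tr], C[tr], spec, cfg)
                pred, _, _ = m.predict_batch(C[va], np.random.default_rng(cfg.seed + 10 + f))
                fold_mae.append(float(np.mean(np.abs(pred - potencies[va]))))
            except TrainingDivergedError:
                fold_mae.append(np.inf)
        score = float(np.mean(fold_mae)) if fold_mae else np.inf
        table.append({**dict(zip(keys, combo)), "cv_mae": score})
        if score < best_score:
            best_score, best_cfg = score, cfg
    if best_cfg is None:
        best_cfg = replace(base_config, **dict(zip(keys, next(itertools.product(*(grid[k] for k in keys))))))
    return best_cfg, table


class CVAERegressor:
    """Uniform fit/predict wrapper used by the benchmark harness.

    fit(fingerprints, potencies) encodes each training potency into its
    module, assembles SPFPs implicitly, and trains the CVAE; predict
    returns decoded pIC50 values from validity-checked sampling.
    """

    def __init__(self, config: CVAEConfig = CVAEConfig(), spec: PotencyModuleSpec = DEFAULT_SPEC):
        self.config = config
        self.spec = spec
        self.model: TrainedCVAE | None = None
        self.last_valid_fraction: float | None = None

    def fit(self, X_fp: np.ndarray, y: np.ndarray) -> "CVAERegressor":
        X = np.vstack([encode_potency(v, self.spec) for v in y]).astype(float)
        self.model = fit_matrices(X, np.asarray(X_fp, dtype=float), self.spec, self.config)
        return self

    def predict(self, X_fp: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before predict")
        values, valid, _ = self.model.predict_batch(
            np.asarray(X_fp, dtype=float), np.random.default_rng(self.config.seed + 1)
        )
        self.last_valid_fraction = float(valid.mean())
        return values
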