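"""Four autoencoder variants over the fused multi-omics matrix.

The fused matrix (entries in [0, 1]) is compressed through a bottleneck
and the bottleneck activations are the patient embedding handed to
clustering. Four variants are provided:

- **vanilla** — plain reconstruction, mean-squared-error loss;
- **denoising** — reconstruct the clean input from a copy whose entries
  were independently masked to zero with probability ``noise_factor``;
- **sparse** — binary cross-entropy loss plus an L1 penalty on bottleneck
  activations and an L2 penalty on weights;
- **variational** — Gaussian latent posterior (mu, log sigma^2) regularised
  toward the unit Gaussian by a KL term, Bernoulli reconstruction
  negative log-likelihood, embedding = posterior mean.

All variants share the architecture used at full scale: 1000-500-100-500-
1000 with tanh hidden / sigmoid output for the first three, and a
1000-500-250 encoder with a 100-dim latent (mirrored decoder, ReLU hidden,
sigmoid output) for the variational one. Optimisation is Adam on
mini-batches; everything is seeded and deterministic.

The networks are implemented directly on NumPy (dense layers, manual
backpropagation): at cohort scale (a few hundred patients x ~1000
features) this trains in seconds on one CPU and keeps the package free of
a deep-learning framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VARIANTS",
    "EncoderConfig",
    "LatentEmbedding",
    "default_config",
    "corrupt",
    "kl_unit_gaussian",
    "train",
]

VARIANTS = ("vanilla", "denoising", "sparse", "variational")

#: training arithmetic runs in single precision (the usual choice for
#: neural nets; halves memory traffic); embeddings are returned as float64
_DTYPE = np.float32

_EPS = 1e-7


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# activation -> (forward on pre-activation, derivative in terms of output)
_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class EncoderConfig:
    """Hyperparameters of one autoencoder variant."""

    variant: str
    layer_widths: tuple[int, ...]  # encoder-side hidden widths, incl. latent
    hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    loss: str = "mse"  # mse | bce | nll_kl
    noise_factor: float = 0.0
    corruption: str = "mask"  # mask | gaussian
    l1: float = 0.0
    l2: float = 0.0
    latent_dim: int = 100
    kl_weight: float = 1.0
    #: fraction of training over which the KL weight ramps linearly from 0
    #: to ``kl_weight`` (warm-up against posterior collapse); 0 disables
    kl_warmup: float = 0.5
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.loss not in ("mse", "bce", "nll_kl"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not 0.0 <= self.noise_factor <= 1.0:
            raise ValueError("noise_factor must lie in [0, 1]")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if not 0.0 <= self.kl_warmup <= 1.0:
            raise ValueError("kl_warmup must lie in [0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")


def default_config(variant: str, **overrides) -> EncoderConfig:
    """The per-variant defaults used at full scale.

    Vanilla/denoising/sparse: hidden layers 500-100-500 around a 1000-wide
    input/output, tanh hidden + sigmoid output; MSE loss (BCE for sparse);
    denoising masks half the inputs; sparse uses L1 = L2 = 0.01.
    Variational: 500-250 encoder into a 100-dim Gaussian latent, ReLU
    hidden + sigmoid output, Bernoulli NLL + KL loss.
    """
    if variant in ("vanilla", "denoising", "sparse"):
        cfg = EncoderConfig(
            variant=variant,
            layer_widths=(500, 100, 500),
            hidden_activation="tanh",
            output_activation="sigmoid",
            loss="bce" if variant == "sparse" else "mse",
            noise_factor=0.5 if variant == "denoising" else 0.0,
            l1=0.01 if variant == "sparse" else 0.0,
            l2=0.01 if variant == "sparse" else 0.0,
            latent_dim=100,
        )
    elif variant == "variational":
        cfg = EncoderConfig(
            variant="variational",
            layer_widths=(500, 250),
            hidden_activation="relu",
            output_activation="sigmoid",
            loss="nll_kl",
            latent_dim=100,
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class LatentEmbedding:
    """Per-patient bottleneck coordinates of one trained variant."""

    coordinates: np.ndarray  # samples x latent_dim
    variant: str
    training_history: list[float]
    sample_ids: list[str] | None = None
    config: EncoderConfig | None = None
    model: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        index = self.sample_ids or range(self.coordinates.shape[0])
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(index, name="sample_id"),
            columns=[f"latent_{j}" for j in range(self.coordinates.shape[1])],
        )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def corrupt(
    x: np.ndarray,
    noise_factor: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "mask",
) -> np.ndarray:
    """Stochastically corrupt a [0, 1] matrix for denoising training.

    ``mask`` (default) zeroes each entry independently with probability
    ``noise_factor``; ``gaussian`` adds N(0, noise_factor^2) noise and
    clips back to [0, 1]. The same seed yields the same corruption.
    """
    if not 0.0 <= noise_factor <= 1.0:
        raise ValueError("noise_factor must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode == "mask":
        keep = rng.random(x.shape) >= noise_factor
        return x * keep
    if mode == "gaussian":
        return np.clip(x + rng.normal(0.0, noise_factor or _EPS, x.shape), 0.0, 1.0)
    raise ValueError(f"unknown corruption mode {mode!r}")


def kl_unit_gaussian(mu: np.ndarray, logvar: np.ndarray):
    """KL divergence of N(mu, exp(logvar)) from the unit Gaussian.

    Computed as -1/2 * sum(1 + logvar - mu^2 - exp(logvar)) over the last
    axis; vectors give a scalar, matrices one value per row.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: mu {mu.shape} vs logvar {logvar.shape}")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("mu/logvar must be finite")
    kl = -0.5 * np.sum(1.0 + logvar - mu * mu - np.exp(logvar), axis=-1)
    return float(kl) if kl.ndim == 0 else kl


# ---------------------------------------------------------------------------
# dense layer with Adam state
# ---------------------------------------------------------------------------

class _Dense:
    def __init__(self, rng, n_in: int, n_out: int, activation: str):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.activation = activation
        self._fwd, self._dact = _ACTIVATIONS[activation]
        self._mW = np.zeros_like(self.W)
        self._vW = np.zeros_like(self.W)
        self._mb = np.zeros_like(self.b)
        self._vb = np.zeros_like(self.b)
        self._x = None
        self.out = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self.out = self._fwd(x @ self.W + self.b)
        return self.out

    def backward(self, grad_out: np.ndarray, l2: float = 0.0) -> np.ndarray:
        """grad_out is dLoss/d(activation output); returns dLoss/d(input)."""
        dz = grad_out * self._dact(self.out)
        self._gW = self._x.T @ dz
        if l2:
            self._gW += 2.0 * l2 * self.W
        self._gb = dz.sum(axis=0)
        return dz @ self.W.T

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        for p, g, m, v in (
            (self.W, self._gW, self._mW, self._vW),
            (self.b, self._gb, self._mb, self._vb),
        ):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# standard (vanilla / denoising / sparse) autoencoder
# ---------------------------------------------------------------------------

class _FeedForwardAE:
    """Symmetric dense autoencoder; bottleneck = narrowest hidden layer."""

    def __init__(self, config: EncoderConfig, input_dim: int, rng):
        widths = [input_dim, *config.layer_widths, input_dim]
        acts = [config.hidden_activation] * len(config.layer_widths) + [
            config.output_activation
        ]
        self.layers = [
            _Dense(rng, widths[i], widths[i + 1], acts[i])
            for i in range(len(widths) - 1)
        ]
        hidden = list(config.layer_widths)
        self.bottleneck_index = hidden.index(min(hidden))  # first narrowest
        self.config = config
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def encode(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[: self.bottleneck_index + 1]:
            x = layer.forward(x)
        return x

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def _loss_and_delta(self, y: np.ndarray, target: np.ndarray):
        n_entries = y.size
        if self.config.loss == "mse":
            diff = y - target
            return float(np.mean(diff * diff)), 2.0 * diff / n_entries
        # bce with sigmoid output: delta w.r.t. pre-activation is (y - t)/N,
        # expressed here w.r.t. the activation by dividing the sigmoid slope
        yc = np.clip(y, _EPS, 1 - _EPS)
        loss = float(-np.mean(target * np.log(yc) + (1 - target) * np.log(1 - yc)))
        delta = (yc - target) / (yc * (1 - yc)) / n_entries
        return loss, delta

    def train_step(self, x: np.ndarray, rng: np.random.Generator) -> float:
        cfg = self.config
        inputs = x
        if cfg.variant == "denoising" and cfg.noise_factor > 0:
            inputs = corrupt(x, cfg.noise_factor, rng=rng, mode=cfg.corruption)
        y = self.forward(inputs)
        loss, grad = self._loss_and_delta(y, x)
        h = self.layers[self.bottleneck_index].out
        if cfg.l1:
            loss += cfg.l1 * float(np.abs(h).sum(axis=1).mean())
        if cfg.l2:
            loss += cfg.l2 * float(sum((lay.W**2).sum() for lay in self.layers))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"{cfg.variant} autoencoder loss became non-finite at step "
                f"{self._t + 1}; lower the learning rate"
            )
        for i in range(len(self.layers) - 1, -1, -1):
            if cfg.l1 and i == self.bottleneck_index:
                # sparsity penalty attaches to bottleneck activations
                grad = grad + cfg.l1 * np.sign(h) / x.shape[0]
            grad = self.layers[i].backward(grad, l2=cfg.l2)
        self._t += 1
        for layer in self.layers:
            layer.adam_step(cfg.learning_rate, self._t)
        return loss


# ---------------------------------------------------------------------------
# variational autoencoder
# ---------------------------------------------------------------------------

class _VariationalAE:
    """Dense VAE with Gaussian latent; embedding is the posterior mean."""

    def __init__(self, config: EncoderConfig, input_dim: int, rng):
        act = config.hidden_activation
        widths = [input_dim, *config.layer_widths]
        self.encoder = [
            _Dense(rng, widths[i], widths[i + 1], act)
            for i in range(len(widths) - 1)
        ]
        last = widths[-1]
        self.head_mu = _Dense(rng, last, config.latent_dim, "identity")
        self.head_logvar = _Dense(rng, last, config.latent_dim, "identity")
        dec_widths = [config.latent_dim, *reversed(config.layer_widths), input_dim]
        dec_acts = [act] * len(config.layer_widths) + [config.output_activation]
        self.decoder = [
            _Dense(rng, dec_widths[i], dec_widths[i + 1], dec_acts[i])
            for i in range(len(dec_widths) - 1)
        ]
        self.config = config
        self.kl_scale = 1.0  # warm-up multiplier set per epoch by train()
        self._t = 0

    def _encode_shared(self, x: np.ndarray) -> np.ndarray:
        for layer in self.encoder:
            x = layer.forward(x)
        return x

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.head_mu.forward(self._encode_shared(x))

    def _decode(self, z: np.ndarray) -> np.ndarray:
        for layer in self.decoder:
            z = layer.forward(z)
        return z

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._decode(self.encode(x))

    def train_step(self, x: np.ndarray, rng: np.random.Generator) -> float:
        cfg = self.config
        kl_w = cfg.kl_weight * self.kl_scale
        n = x.shape[0]
        shared = self._encode_shared(x)
        mu = self.head_mu.forward(shared)
        logvar = np.clip(self.head_logvar.forward(shared), -15.0, 15.0)
        eps = rng.standard_normal(mu.shape).astype(_DTYPE)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps
        y = self._decode(z)
        yc = np.clip(y, _EPS, 1 - _EPS)
        # Bernoulli NLL summed over features, averaged over the batch
        recon = float(
            -(x * np.log(yc) + (1 - x) * np.log(1 - yc)).sum(axis=1).mean()
        )
        kl = float(np.mean(kl_unit_gaussian(mu, logvar)))
        loss = recon + kl_w * kl
        if not np.isfinite(loss):
            raise RuntimeError(
                f"variational autoencoder loss became non-finite at step "
                f"{self._t + 1}; lower the learning rate"
            )
        grad = (yc - x) / (yc * (1 - yc)) / n  # summed-over-features NLL
        for i in range(len(self.decoder) - 1, -1, -1):
            grad = self.decoder[i].backward(grad)
        dz = grad
        dmu = dz + kl_w * mu / n
        dlogvar = (
            dz * eps * 0.5 * sigma
            + kl_w * 0.5 * (np.exp(logvar) - 1.0) / n
        )
        dshared = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        for i in range(len(self.encoder) - 1, -1, -1):
            dshared = self.encoder[i].backward(dshared)
        self._t += 1
        for layer in (
            *self.decoder,
            self.head_mu,
            self.head_logvar,
            *self.encoder,
        ):
            layer.adam_step(cfg.learning_rate, self._t)
        return loss


# ---------------------------------------------------------------------------
# training entry point
# ---------------------------------------------------------------------------

def train(config: EncoderConfig, fused) -> LatentEmbedding:
    """Train one variant on the fused matrix; return the bottleneck embedding.

    ``fused`` is a sample-by-feature DataFrame or array with entries in
    [0, 1] (the range the sigmoid output and the BCE/Bernoulli losses
    presuppose). With ``epochs=0`` the embedding comes from the untrained
    (seeded) weights and the loss history is empty. Fixed seed → identical
    embedding and history.
    """
    if isinstance(fused, pd.DataFrame):
        sample_ids = [str(s) for s in fused.index]
        x = fused.to_numpy(dtype=float)
    else:
        sample_ids = None
        x = np.asarray(fused, dtype=float)
    if x.ndim != 2:
        raise ValueError("fused matrix must be 2-D (samples x features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("fused matrix contains non-finite entries")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("fused matrix entries must lie in [0, 1]")
    n, p = x.shape
    if config.latent_dim >= p:
        raise ValueError(
            f"latent_dim {config.latent_dim} must be smaller than the fused "
            f"width {p}"
        )
    if config.epochs > 0 and n < config.batch_size:
        raise ValueError(
            f"sample count {n} is smaller than batch_size {config.batch_size}"
        )

    x = x.astype(_DTYPE)
    rng = np.random.default_rng(config.seed)
    if config.variant == "variational":
        model: _FeedForwardAE | _VariationalAE = _VariationalAE(config, p, rng)
    else:
        model = _FeedForwardAE(config, p, rng)

    warmup_epochs = int(round(config.kl_warmup * config.epochs))
    history: list[float] = []
    for epoch in range(config.epochs):
        if isinstance(model, _VariationalAE):
            model.kl_scale = (
                1.0 if warmup_epochs == 0
                else min(1.0, (epoch + 1) / warmup_epochs)
            )
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            batch = x[perm[start : start + config.batch_size]]
            loss = model.train_step(batch, rng)
            total += loss * batch.shape[0]
        history.append(total / n)

    coordinates = model.encode(x)
    return LatentEmbedding(
        coordinates=coordinates,
        variant=config.variant,
        training_history=history,
        sample_ids=sample_ids,
        config=config,
        model=model,
    )
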