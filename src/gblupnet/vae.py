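"""Phenotype-binned variational-autoencoder data augmentation.

Training animals are divided into equal-frequency phenotype bins (10 by
default).  A Gaussian-latent VAE (16-dimensional latent space by default) is
trained on the training genotypes; for each bin, a Gaussian is fitted to the
encoded means of the bin's members, latent vectors are sampled from it and
decoded, and the decoder outputs are mapped back to {0, 1, 2} dosages.  Each
synthetic animal is assigned the midpoint of its bin's phenotype edges, and
the batch (100 per bin by default, i.e. 1000 synthetic animals) is appended
to the training set only — validation and test sets are never augmented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn


@dataclass
class VAEConfig:
    latent_dim: int = 16
    encoder_sizes: tuple[int, ...] = (256, 64)
    decoder_sizes: tuple[int, ...] = (64, 256)
    n_bins: int = 10
    per_bin: int = 100
    kl_weight: float = 1.0
    leaky_alpha: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    output_mode: str = "round"  # round | softmax (per-marker 3-class argmax)
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_bins < 2 or self.per_bin < 1:
            raise ValueError("n_bins must be >= 2 and per_bin >= 1")
        if self.output_mode not in ("round", "softmax"):
            raise ValueError("output_mode must be 'round' or 'softmax'")


@dataclass
class SyntheticBatch:
    """Decoded synthetic animals with bin-midpoint phenotypes."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    bin_id: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("synthetic genotypes must be coded 0/1/2")


def bin_phenotypes(y_train, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency phenotype bins.

    Returns (bin assignment per animal in 0..n_bins-1, bin edges of length
    n_bins + 1).  Ties that would empty a quantile bin are merged with their
    neighbor with a warning.
    """
    y = np.asarray(y_train, dtype=float)
    if len(y) < n_bins:
        raise ValueError("need at least n_bins training animals")
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    uniq_edges = np.unique(edges)
    if len(uniq_edges) < len(edges):
        warnings.warn("tied phenotype quantiles: merging empty bins with neighbors")
        edges = uniq_edges
    assign = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(edges) - 2)
    return assign, edges


def bin_midpoints(edges: np.ndarray) -> np.ndarray:
    return (np.asarray(edges)[:-1] + np.asarray(edges)[1:]) / 2.0


class GenotypeVAE:
    """Gaussian-latent VAE over 0/1/2 dosage rows.

    The encoder body feeds two linear heads emitting per-dimension posterior
    means and log-variances; the decoder maps latent vectors back to one real
    output per marker (or 3 logits per marker in 'softmax' mode).
    """

    def __init__(self, n_markers: int, config: VAEConfig):
        self.n_markers = n_markers
        self.config = config
        rng = np.random.default_rng(config.seed)
        a = config.leaky_alpha

        enc_layers, width = [], n_markers
        for h in config.encoder_sizes:
            enc_layers += [_nn.Dense(width, h, rng), _nn.LeakyReLU(a)]
            width = h
        self.encoder_body = _nn.Sequential(enc_layers)
        self.head_mu = _nn.Dense(width, config.latent_dim, rng)
        self.head_logvar = _nn.Dense(width, config.latent_dim, rng)

        out_dim = n_markers if config.output_mode == "round" else 3 * n_markers
        dec_layers, width = [], config.latent_dim
        for h in config.decoder_sizes:
            dec_layers += [_nn.Dense(width, h, rng), _nn.LeakyReLU(a)]
            width = h
        dec_layers.append(_nn.Dense(width, out_dim, rng))
        self.decoder = _nn.Sequential(dec_layers)
        self._rng = rng

    def params(self):
        return (
            self.encoder_body.params()
            + self.head_mu.params()
            + self.head_logvar.params()
            + self.decoder.params()
        )

    def grads(self):
        return (
            self.encoder_body.grads()
            + self.head_mu.grads()
            + self.head_logvar.grads()
            + self.decoder.grads()
        )

    def encode(self, X) -> tuple[np.ndarray, np.ndarray]:
        h = self.encoder_body.forward(np.asarray(X, dtype=float))
        return self.head_mu.forward(h), self.head_logvar.forward(h)

    def decode(self, Z) -> np.ndarray:
        """Map latent vectors to 0/1/2 dosage rows."""
        out = self.decoder.forward(np.asarray(Z, dtype=float))
        if self.config.output_mode == "round":
            return np.clip(np.rint(out), 0, 2).astype(np.int8)
        logits = out.reshape(len(out), self.n_markers, 3)
        return logits.argmax(axis=2).astype(np.int8)

    def decode_raw(self, Z) -> np.ndarray:
        return self.decoder.forward(np.asarray(Z, dtype=float))

    def _targets(self, X):
        if self.config.output_mode == "round":
            return X
        onehot = np.zeros((len(X), self.n_markers, 3))
        idx = X.astype(int)
        bi, mi = np.ogrid[: len(X), : self.n_markers]
        onehot[bi, mi, idx] = 1.0
        return onehot.reshape(len(X), -1)

    def _step(self, xb, opt):
        cfg = self.config
        h = self.encoder_body.forward(xb)
        mu = self.head_mu.forward(h)
        logvar = np.clip(self.head_logvar.forward(h), -10.0, 10.0)
        eps = self._rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        xhat = self.decoder.forward(z)
        target = self._targets(xb)
        b = len(xb)

        recon = float(np.sum((xhat - target) ** 2)) / b
        kl = float(np.sum(-0.5 * (1.0 + logvar - mu**2 - np.exp(logvar)))) / b
        loss = recon + cfg.kl_weight * kl
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite VAE loss; lower the learning rate")

        dxhat = 2.0 * (xhat - target) / b
        dz = self.decoder.backward(dxhat)
        dmu = dz + cfg.kl_weight * mu / b
        dlogvar = dz * (0.5 * std * eps) + cfg.kl_weight * (-0.5) * (1.0 - np.exp(logvar)) / b
        dh = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        self.encoder_body.backward(dh)
        opt.step(self.grads())
        return loss

    def fit(self, X) -> dict:
        X = np.asarray(X, dtype=float)
        cfg = self.config
        opt = _nn.Adam(self.params(), lr=cfg.learning_rate)
        history = {"loss": []}
        for _ in range(cfg.max_epochs):
            total, nb = 0.0, 0
            for idx in _nn.iterate_minibatches(len(X), cfg.batch_size, self._rng):
                total += self._step(X[idx], opt)
                nb += 1
            history["loss"].append(total / max(nb, 1))
        return history


def train_vae(X_train, config: VAEConfig) -> GenotypeVAE:
    """Train a VAE on training-set genotypes; deterministic under config.seed."""
    X_train = np.asarray(X_train)
    vae = GenotypeVAE(X_train.shape[1], config)
    vae.history = vae.fit(X_train)
    return vae


def generate_synthetic(
    vae: GenotypeVAE, X_train, y_train, config: VAEConfig | None = None
) -> SyntheticBatch:
    """Decode per-bin latent samples into synthetic 0/1/2 animals.

    For each phenotype bin a Gaussian (diagonal covariance) is fitted to the
    encoded posterior means of the bin's members and ``per_bin`` latent
    vectors are sampled from it; bins with a single member fall back to that
    member's own posterior.  Phenotypes are the bin-edge midpoints.
    """
    config = config or vae.config
    X_train = np.asarray(X_train, dtype=float)
    assign, edges = bin_phenotypes(y_train, config.n_bins)
    mids = bin_midpoints(edges)
    mu, logvar = vae.encode(X_train)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    genos, phens, bins = [], [], []
    for b in range(len(mids)):
        members = np.flatnonzero(assign == b)
        if members.size == 0:
            continue
        if members.size >= 2:
            center = mu[members].mean(axis=0)
            spread = mu[members].std(axis=0, ddof=1)
        else:
            center = mu[members[0]]
            spread = np.exp(0.5 * np.clip(logvar[members[0]], -10, 10))
        z = center + spread * rng.standard_normal((config.per_bin, config.latent_dim))
        genos.append(vae.decode(z))
        phens.append(np.full(config.per_bin, mids[b]))
        bins.append(np.full(config.per_bin, b))
    return SyntheticBatch(
        genotypes=np.vstack(genos),
        phenotypes=np.concatenate(phens),
        bin_id=np.concatenate(bins),
    )


def augment(
    X_train, y_train, batch: SyntheticBatch
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append the synthetic batch to the training arrays.

    Returns (X_augmented, y_augmented, is_synthetic mask).  Only the training
    set is touched; callers keep validation/test sets as they were.
    """
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train, dtype=float)
    if batch.genotypes.shape[0] == 0:
        return X_train, y_train, np.zeros(len(y_train), dtype=bool)
    if batch.genotypes.shape[1] != X_train.shape[1]:
        raise ValueError("synthetic and real marker columns do not match")
    X_aug = np.vstack([X_train, batch.genotypes])
    y_aug = np.concatenate([y_train, batch.phenotypes])
    mask = np.concatenate([np.zeros(len(y_train), bool), np.ones(len(batch.phenotypes), bool)])
    return X_aug, y_aug, mask
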