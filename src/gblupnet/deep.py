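"""MLP and CNN genotype-to-phenotype regressors.

Both architectures take the raw 0/1/2 dosage vector of an animal as input
(no standardization) and emit a single linear output.  Hidden layers use
leaky-ReLU activations, He-normal initialization and L1/L2 kernel penalties;
training minimizes mean-squared error with Adam and stops early on a
validation split, restoring the best-validation weights.

``preset(line, arch)`` bundles the tuned hyperparameter columns for the two
populations: an MLP with hidden sizes 96:64:32:16, and a CNN with one
convolution (16 filters for the sire preset, 8 for the dam preset, kernel 5,
pooling 3) followed by a 64:32:16 dense stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _nn


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters for one regressor."""

    arch: str = "mlp"  # mlp | cnn
    hidden_sizes: tuple[int, ...] = None
    conv_filters: int | None = None
    kernel_size: int | None = None
    pool_size: int | None = None
    pool_type: str = "max"  # max | average
    l1: float = 0.0
    l2: float = 0.0
    leaky_alpha: float = 0.3
    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ("mlp", "cnn"):
            raise ValueError("arch must be 'mlp' or 'cnn'")
        if self.hidden_sizes is None:
            self.hidden_sizes = (96, 64, 32, 16) if self.arch == "mlp" else (64, 32, 16)
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.arch == "cnn":
            if self.conv_filters is None:
                self.conv_filters = 16
            if self.kernel_size is None:
                self.kernel_size = 5
            if self.pool_size is None:
                self.pool_size = 3
            if min(self.conv_filters, self.kernel_size, self.pool_size) <= 0:
                raise ValueError("conv_filters, kernel_size and pool_size must be positive")
        else:
            if any(v is not None for v in (self.conv_filters, self.kernel_size, self.pool_size)):
                raise ValueError("mlp config must not set convolution fields")
        if min(self.l1, self.l2, self.learning_rate) < 0:
            raise ValueError("l1, l2 and learning_rate must be >= 0")
        if self.batch_size <= 0 or self.max_epochs < 0 or self.early_stop_patience <= 0:
            raise ValueError("batch_size/early_stop_patience must be positive, max_epochs >= 0")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


#: Tuned hyperparameter bundles per population line and architecture.
PRESETS = {
    ("sire", "mlp"): dict(arch="mlp", hidden_sizes=(96, 64, 32, 16), l1=0.01, l2=0.1),
    ("sire", "cnn"): dict(
        arch="cnn", hidden_sizes=(64, 32, 16), conv_filters=16, kernel_size=5, pool_size=3,
        l1=0.005, l2=0.1,
    ),
    ("dam", "mlp"): dict(arch="mlp", hidden_sizes=(96, 64, 32, 16), l1=0.007, l2=0.15),
    ("dam", "cnn"): dict(
        arch="cnn", hidden_sizes=(64, 32, 16), conv_filters=8, kernel_size=5, pool_size=3,
        l1=0.003, l2=0.15,
    ),
}


def preset(line: str, arch: str, **overrides) -> NetworkConfig:
    """Return the tuned NetworkConfig for a population line ('sire'/'dam')."""
    key = (line, arch)
    if key not in PRESETS:
        raise ValueError(f"no preset for line={line!r}, arch={arch!r}")
    params = dict(PRESETS[key])
    params.update(overrides)
    return NetworkConfig(**params)


class GenomicNet:
    """A built (possibly trained) regressor: a Sequential net plus its config."""

    def __init__(self, net: _nn.Sequential, config: NetworkConfig, n_markers: int):
        self.net = net
        self.config = config
        self.n_markers = n_markers
        self.history = None

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_markers:
            raise ValueError(f"expected (n, {self.n_markers}) input, got {X.shape}")
        return self.net.predict(X)

    def __call__(self, X):
        return self.predict(X)


def build_model(config: NetworkConfig, n_markers: int) -> GenomicNet:
    """Construct an untrained network; weights are seeded from config.seed."""
    rng = np.random.default_rng(config.seed)
    layers = []
    width = n_markers
    if config.arch == "cnn":
        if config.kernel_size > n_markers:
            raise ValueError("kernel larger than the number of markers")
        layers.append(_nn.Conv1D(config.kernel_size, config.conv_filters, rng, config.l1, config.l2))
        layers.append(_nn.LeakyReLU(config.leaky_alpha))
        conv_len = n_markers - config.kernel_size + 1
        if config.pool_size > conv_len:
            raise ValueError("pooling window larger than the convolution output")
        layers.append(_nn.Pool1D(config.pool_size, config.pool_type))
        layers.append(_nn.Flatten())
        width = (conv_len // config.pool_size) * config.conv_filters
    for h in config.hidden_sizes:
        layers.append(_nn.Dense(width, h, rng, config.l1, config.l2))
        layers.append(_nn.LeakyReLU(config.leaky_alpha))
        width = h
    layers.append(_nn.Dense(width, 1, rng, config.l1, config.l2))
    return GenomicNet(_nn.Sequential(layers), config, n_markers)


def train(model: GenomicNet, X_train, y_train, X_val, y_val, config: NetworkConfig | None = None):
    """Train in place with early stopping; returns (model, history)."""
    config = config or model.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history = _nn.train_regressor(
        model.net,
        X_train,
        y_train,
        X_val,
        y_val,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.early_stop_patience,
        rng=rng,
    )
    model.history = history
    return model, history


def predict(model: GenomicNet, X) -> np.ndarray:
    """Deterministic forward pass on a 0/1/2 dosage matrix."""
    return model.predict(X)


def save_model(model: GenomicNet, path: str) -> None:
    """Checkpoint weights to .npz with a JSON sidecar of the NetworkConfig."""
    weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path, n_markers=model.n_markers, **weights)
    side = str(path)
    side = side[:-4] if side.endswith(".npz") else side
    model.config.to_json(side + ".config.json")


def load_model(path: str) -> GenomicNet:
    """Rebuild a checkpointed model from .npz weights and its config sidecar."""
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    side = str(path)
    side = side[:-4] if side.endswith(".npz") else side
    with open(side + ".config.json") as fh:
        cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in json.load(fh).items()})
    model = build_model(cfg, int(data["n_markers"]))
    weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    model.net.set_weights(weights)
    return model
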