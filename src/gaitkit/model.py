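"""The lightweight CNN gait-type classifier.

Architecture: five 3x3 convolutions with stride 2 and 'same' padding
(channel widths 32, 32, 32, 64, 64), each followed by batch normalization
and ReLU; the 7x7x64 feature map is flattened into a 512-unit dense layer,
a dropout of 0.5, and a 5-unit softmax output — one unit per gait type.
The input is a 224x224 grayscale energy image replicated to 3 channels.

Counting batch-normalization moving statistics (4 values per channel), the
default configuration has exactly 1,684,421 parameters:

    conv:   896 + 9,248 + 9,248 + 18,496 + 36,928 =    74,816
    norm:   4 * (32+32+32+64+64)                  =       896
    dense:  3136*512+512 + 512*5+5                = 1,608,709

Training uses categorical cross entropy with the Nadam optimizer (Adam with
Nesterov momentum) at learning rate 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .represent import REPRESENTATION_SIZE, GaitRepresentation

#: fixed class-label order; confusion matrices use this row/column order
CLASS_LABELS = ("scissor", "spastic", "steppage", "normal", "propulsive")


@dataclass
class ModelConfig:
    """Hyperparameters of the gait CNN."""

    input_size: int = REPRESENTATION_SIZE
    input_channels: int = 3
    conv_channels: tuple = (32, 32, 32, 64, 64)
    kernel: int = 3
    stride: int = 2
    dense_units: int = 512
    n_classes: int = 5
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 5:
            raise ValueError("the classifier outputs the 5 gait types")
        if len(self.conv_channels) != 5:
            raise ValueError("the architecture uses exactly 5 conv layers")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _build_network(config: ModelConfig) -> nn.Network:
    rng = np.random.default_rng(config.seed)
    layers = []
    c_in = config.input_channels
    size = config.input_size
    for c_out in config.conv_channels:
        layers.append(nn.Conv2D(c_in, c_out, kernel=config.kernel,
                                stride=config.stride, rng=rng))
        layers.append(nn.BatchNorm(c_out))
        layers.append(nn.ReLU())
        c_in = c_out
        size = -(-size // config.stride)
    layers.append(nn.Flatten())
    layers.append(nn.Dense(size * size * c_in, config.dense_units, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(config.dropout))
    layers.append(nn.Dense(config.dense_units, config.n_classes, rng=rng))
    return nn.Network(layers)


class GaitClassifier:
    """The gait CNN together with its configuration and training state."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.network = _build_network(self.config)
        self.class_labels = CLASS_LABELS
        self.history: dict[str, list] = {"loss": [], "accuracy": [],
                                         "val_loss": [], "val_accuracy": []}

    # -- introspection ------------------------------------------------------

    def count_parameters(self) -> int:
        """Total parameters, including batch-norm moving statistics."""
        return self.network.n_parameters()

    def feature_map_sizes(self) -> list[int]:
        """Spatial size after each conv layer (224 -> 112, 56, 28, 14, 7)."""
        sizes = []
        s = self.config.input_size
        for _ in self.config.conv_channels:
            s = -(-s // self.config.stride)
            sizes.append(s)
        return sizes

    # -- input handling -----------------------------------------------------

    def _to_batch(self, representations):
        """Grayscale energy images -> (n, 224, 224, 3) float32 batch."""
        arrs = []
        for r in representations:
            px = r.pixels if isinstance(r, GaitRepresentation) else np.asarray(r)
            px = np.asarray(px, dtype=np.float32)
            if px.shape != (self.config.input_size, self.config.input_size):
                raise ValueError(f"expected {self.config.input_size}x"
                                 f"{self.config.input_size} input, got {px.shape}")
            arrs.append(np.repeat(px[:, :, None], self.config.input_channels,
                                  axis=2))
        return np.stack(arrs)

    def _encode_labels(self, labels):
        index = {lab: i for i, lab in enumerate(self.class_labels)}
        try:
            y = np.array([index[lab] for lab in labels])
        except KeyError as e:
            raise ValueError(f"unknown gait type label {e.args[0]!r}") from None
        return y

    # -- inference ----------------------------------------------------------

    def predict_proba(self, representations) -> np.ndarray:
        """Class probabilities, one length-5 simplex row per representation."""
        x = self._to_batch(representations)
        logits = self.network.forward(x, training=False)
        return nn.softmax(logits)

    def predict(self, representation) -> np.ndarray:
        """Probability vector over the 5 gait types for one representation."""
        return self.predict_proba([representation])[0]

    def predict_label(self, representation) -> str:
        return self.class_labels[int(np.argmax(self.predict(representation)))]

    # -- training -----------------------------------------------------------

    def evaluate_loss(self, x, y):
        logits = self.network.forward(x, training=False)
        p = nn.softmax(logits)
        n = x.shape[0]
        loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
        acc = float((p.argmax(axis=1) == y).mean())
        return float(loss), acc

    def train(self, representations, labels, validation_fraction: float = 0.2,
              epochs: int | None = None):
        """Fit the network on labelled energy images.

        Training is reproducible for a fixed config seed and data order.
        A random ``validation_fraction`` of the data (at least one sample
        when the fraction is positive) is held out for the epoch-indexed
        validation history and early stopping.
        """
        y = self._encode_labels(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires at least 2 classes")
        x = self._to_batch(representations)
        rng = np.random.default_rng(self.config.seed + 1)
        n = x.shape[0]
        perm = rng.permutation(n)
        n_val = int(round(validation_fraction * n))
        if validation_fraction > 0:
            n_val = max(1, n_val)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]

        first_conv = self.network.layers[0]
        first_conv.compute_dx = False  # input gradient not needed while fitting
        opt = nn.Nadam(learning_rate=self.config.learning_rate)
        epochs = epochs or self.config.epochs
        batch = self.config.batch_size
        best_val = np.inf
        best_weights = None
        patience = self.config.early_stopping_patience
        stale = 0

        for epoch in range(epochs):
            order = rng.permutation(len(xt))
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, len(xt), batch):
                idx = order[start:start + batch]
                xb, yb = xt[idx], yt[idx]
                logits = self.network.forward(xb, training=True, rng=rng)
                p = nn.softmax(logits)
                m = len(idx)
                ep_loss += -np.log(np.clip(p[np.arange(m), yb],
                                           1e-12, None)).sum()
                ep_correct += int((p.argmax(axis=1) == yb).sum())
                dlogits = p.copy()
                dlogits[np.arange(m), yb] -= 1.0
                dlogits /= m
                self.network.backward(dlogits.astype(np.float32))
                opt.step(self.network.layers)
            self.history["loss"].append(ep_loss / len(xt))
            self.history["accuracy"].append(ep_correct / len(xt))
            if len(xv):
                vl, va = self.evaluate_loss(xv, yv)
            else:
                vl, va = float("nan"), float("nan")
            self.history["val_loss"].append(vl)
            self.history["val_accuracy"].append(va)
            if len(xv) and vl < best_val - 1e-6:
                best_val = vl
                best_weights = self._get_weights()
                stale = 0
            else:
                stale += 1
                if len(xv) and patience and stale >= patience:
                    break
        first_conv.compute_dx = True
        if best_weights is not None:
            self._set_weights(best_weights)
        return self

    # -- (de)serialization --------------------------------------------------

    def _get_weights(self):
        out = []
        for layer in self.network.layers:
            entry = {k: v.copy() for k, v in layer.params().items()}
            entry.update({k: v.copy() for k, v in layer.state().items()})
            out.append(entry)
        return out

    def _set_weights(self, weights):
        for layer, entry in zip(self.network.layers, weights):
            for k, v in layer.params().items():
                v[...] = entry[k]
            for k in layer.state():
                setattr(layer, k, entry[k].copy())

    def save(self, path):
        """Store config and layered weights in an HDF5 container."""
        import h5py
        import yaml

        with h5py.File(path, "w") as f:
            f.attrs["config"] = yaml.safe_dump(asdict(self.config))
            f.attrs["class_labels"] = list(self.class_labels)
            for i, entry in enumerate(self._get_weights()):
                grp = f.create_group(f"layer_{i:02d}")
                for k, v in entry.items():
                    grp.create_dataset(k, data=v)

    @classmethod
    def load(cls, path) -> "GaitClassifier":
        import h5py
        import yaml

        with h5py.File(path, "r") as f:
            cfg_dict = yaml.safe_load(f.attrs["config"])
            cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
            clf = cls(ModelConfig(**cfg_dict))
            weights = []
            for i in range(len(clf.network.layers)):
                key = f"layer_{i:02d}"
                weights.append({k: np.asarray(v) for k, v in f[key].items()}
                               if key in f else {})
            clf._set_weights(weights)
        return clf


def build_classifier(config: ModelConfig | None = None) -> GaitClassifier:
    """Construct the classifier with seeded weight initialization."""
    return GaitClassifier(config)


def count_parameters(classifier: GaitClassifier) -> int:
    return classifier.count_parameters()
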