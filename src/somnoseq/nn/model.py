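"""The sequence-to-sequence CNN–biLSTM sleep stager.

Per 30-s epoch, a six-layer 1-D convolutional stack (each convolution
followed by batch normalization and ReLU, with max pooling after every
two convolutions and global average pooling at the end) summarizes the
3-channel raw signal into a feature vector; the same stack is applied
to every epoch of the input sequence (time-distributed).  The epoch
feature sequence then passes through Gaussian dropout (training only),
a bidirectional LSTM (one output per epoch), and a time-distributed
dense softmax layer producing a 5-class stage posterior per epoch.
The predicted stage of an epoch is the argmax of its posterior.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..stages import Hypnogram, N_STAGES
from .layers import (
    Adam,
    BatchNorm1d,
    BiLSTM,
    Conv1d,
    Dense,
    GaussianDropout,
    GlobalAvgPool1d,
    MaxPool1d,
    ReLU,
    softmax,
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The six convolutional layers are described by parallel tuples of
    filter counts, kernel sizes and strides; the two max-pooling layers
    by (pool size, pool stride) pairs.  ``lstm_units`` is per direction.
    ``samples_per_epoch`` defaults to 3000 = 30 s x 100 Hz.
    """

    conv_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    conv_kernels: tuple[int, ...] = (7, 7, 5, 5, 3, 3)
    conv_strides: tuple[int, ...] = (1, 1, 1, 1, 1, 1)
    pool_sizes: tuple[int, int] = (4, 4)
    pool_strides: tuple[int, int] = (4, 4)
    lstm_units: int = 64
    dense_units: int = N_STAGES
    dropout_rate: float = 0.3
    seq_len: int = 100
    samples_per_epoch: int = 3000
    n_channels: int = 3
    n_classes: int = N_STAGES
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not (len(self.conv_filters) == len(self.conv_kernels)
                == len(self.conv_strides) == 6):
            raise ValueError("exactly six convolutional layers are required")
        if self.dense_units != self.n_classes:
            raise ValueError("dense_units must equal n_classes")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        self.feature_lengths()  # validates the conv/pool arithmetic

    def feature_lengths(self) -> list[int]:
        """Per-epoch sample-axis length after each conv/pool layer."""
        L = self.samples_per_epoch
        out = []
        for i in range(6):
            L = -(-L // self.conv_strides[i])  # 'same' conv: ceil(L / stride)
            out.append(L)
            if L < 1:
                raise ValueError(f"feature length collapsed at conv layer {i + 1}")
            if i in (1, 3):
                j = 0 if i == 1 else 1
                L = (L - self.pool_sizes[j]) // self.pool_strides[j] + 1
                out.append(L)
                if L < 1:
                    raise ValueError(
                        f"feature length collapsed at pooling layer {j + 1}")
        return out

    def param_count(self) -> int:
        """Trainable parameter total (conv + BN + biLSTM + dense)."""
        n = 0
        cin = self.n_channels
        for f, k in zip(self.conv_filters, self.conv_kernels):
            n += k * cin * f + f      # conv kernel + bias
            n += 2 * f                # BN gamma + beta
            cin = f
        feat, h = self.conv_filters[-1], self.lstm_units
        n += 2 * (4 * h * (feat + h + 1))   # biLSTM, both directions
        n += 2 * h * self.n_classes + self.n_classes
        return n


#: CPU-scale preset used by tests, the demo pipeline and the examples.
TINY_PRESET = ModelConfig(
    conv_filters=(8, 8, 16, 16, 32, 32),
    conv_kernels=(7, 7, 5, 5, 3, 3),
    conv_strides=(2, 1, 1, 1, 1, 1),
    lstm_units=16,
    seq_len=20,
)


class SleepStager:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        self.conv_stack: list = []
        cin = config.n_channels
        for i in range(6):
            self.conv_stack.append(Conv1d(
                cin, config.conv_filters[i], config.conv_kernels[i],
                config.conv_strides[i], rng, dtype, name=f"conv{i + 1}"))
            self.conv_stack.append(BatchNorm1d(
                config.conv_filters[i], dtype=dtype, name=f"bn{i + 1}"))
            self.conv_stack.append(ReLU())
            cin = config.conv_filters[i]
            if i in (1, 3):
                j = 0 if i == 1 else 1
                self.conv_stack.append(MaxPool1d(config.pool_sizes[j],
                                                 config.pool_strides[j]))
        self.conv_stack.append(GlobalAvgPool1d())
        self.dropout = GaussianDropout(config.dropout_rate)
        self.bilstm = BiLSTM(config.conv_filters[-1], config.lstm_units,
                             rng, dtype)
        self.head = Dense(2 * config.lstm_units, config.n_classes, rng, dtype,
                          name="head")
        self._all_layers = self.conv_stack + [self.dropout, self.bilstm, self.head]
        self.params = [p for layer in self._all_layers for p in layer.params]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, T, L, C) -> per-epoch stage posteriors (B, T, n_classes)."""
        B, T, L, C = x.shape
        h = np.ascontiguousarray(x.reshape(B * T, L, C),
                                 dtype=np.dtype(self.config.dtype))
        for layer in self.conv_stack:
            h = layer.forward(h, training=training, rng=rng)
        h = h.reshape(B, T, -1)
        h = self.dropout.forward(h, training=training, rng=rng)
        h = self.bilstm.forward(h, training=training, rng=rng)
        logits = self.head.forward(h, training=training, rng=rng)
        self._shape = (B, T)
        return softmax(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate the gradient w.r.t. the pre-softmax logits."""
        B, T = self._shape
        d = self.head.backward(dlogits)
        d = self.bilstm.backward(d)
        d = self.dropout.backward(d)
        d = np.ascontiguousarray(d.reshape(B * T, -1))
        for layer in reversed(self.conv_stack):
            d = layer.backward(d)

    # -- parameter utilities -------------------------------------------------

    def count_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        arrs = [p.value.copy() for p in self.params]
        for layer in self._all_layers:
            if isinstance(layer, BatchNorm1d):
                arrs += [layer.running_mean.copy(), layer.running_var.copy()]
        return arrs

    def set_weights(self, arrs: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, a in zip(self.params, arrs[:n]):
            p.value[...] = a
        it = iter(arrs[n:])
        for layer in self._all_layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def make_optimizer(self) -> Adam:
        return Adam(self.params)


def build_model(config: ModelConfig, seed: int = 0) -> SleepStager:
    """Construct the stager with deterministic seeded initialization."""
    return SleepStager(config, seed=seed)


def predict_posteriors(model: SleepStager, sequences: np.ndarray,
                       batch_size: int = 8) -> np.ndarray:
    """Inference-mode posteriors for a batch of epoch sequences.

    ``sequences``: (B, T, L, C).  Dropout is inactive and batch
    normalization uses running statistics, so the output for a sequence
    does not depend on how the batch is partitioned.
    """
    if sequences.ndim != 4:
        raise ValueError("expected (batch, seq_len, samples, channels)")
    outs = [model.forward(sequences[i:i + batch_size], training=False)
            for i in range(0, len(sequences), batch_size)]
    return np.concatenate(outs, axis=0)


def decode_stages(posteriors: np.ndarray, source_id: str = "auto") -> Hypnogram:
    """Argmax decoding; ties break toward the lowest ordinal stage (W first)."""
    post = np.asarray(posteriors)
    if post.ndim != 2 or post.shape[1] != N_STAGES:
        raise ValueError("expected an (n_epochs, 5) posterior array")
    return Hypnogram(post.argmax(axis=1), source_id=source_id)


def predict_hypnogram(model: SleepStager, epochs: np.ndarray,
                      batch_size: int = 8, source_id: str = "auto") -> Hypnogram:
    """Stage every epoch of a trimmed recording exactly once.

    ``epochs``: (n_epochs, n_channels, samples_per_epoch) as produced by
    :func:`somnoseq.psg_io.epochize`.  The recording is split into
    non-overlapping seq_len windows; a final short window is padded by
    repeating its last epoch and the pad predictions are discarded.
    """
    n = len(epochs)
    if n < 1:
        raise ValueError("recording shorter than one epoch")
    T = model.config.seq_len
    x = np.transpose(epochs, (0, 2, 1))  # (n, L, C)
    windows = []
    starts = list(range(0, n, T))
    for s in starts:
        w = x[s:s + T]
        if len(w) < T:
            w = np.concatenate([w, np.repeat(w[-1:], T - len(w), axis=0)])
        windows.append(w)
    post = predict_posteriors(model, np.stack(windows), batch_size=batch_size)
    flat = post.reshape(-1, N_STAGES)[:len(starts) * T]
    keep = np.concatenate([np.arange(s, min(s + T, n)) + i * T - s
                           for i, s in enumerate(starts)])
    return decode_stages(flat[keep], source_id=source_id)


# -- checkpointing -----------------------------------------------------------


def save_model(model: SleepStager, path: str | Path) -> None:
    """Save weights (.npz) with a JSON sidecar of config + seed."""
    path = Path(path)
    arrs = model.get_weights()
    np.savez(path.with_suffix(".npz"),
             **{f"w{i:04d}": a for i, a in enumerate(arrs)})
    sidecar = {"config": asdict(model.config), "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> SleepStager:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    for key in ("conv_filters", "conv_kernels", "conv_strides",
                "pool_sizes", "pool_strides"):
        cfg[key] = tuple(cfg[key])
    model = SleepStager(ModelConfig(**cfg), seed=sidecar["seed"])
    with np.load(path.with_suffix(".npz")) as z:
        model.set_weights([z[k] for k in sorted(z.files)])
    return model
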