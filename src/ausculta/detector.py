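"""Convolutional-recurrent frame-level sound-event detector.

The detector maps a log-mel spectrogram to a *probability raster*: a
frames-by-classes matrix of independent per-frame detection probabilities on
the 10 ms grid.  Architecture: stacked convolution blocks (3x3 kernels,
ReLU, max pooling over frequency only — time resolution is preserved
end-to-end), a bidirectional GRU over time that captures long-range
structure such as the breathing cycle, and a per-frame sigmoid output per
class.  Training minimizes per-frame multilabel binary cross-entropy with
Adam on fixed-length chunks sampled from the training recordings.

Exposed as a scikit-learn-style estimator (`fit` / `predict_proba` /
`predict`, fitted attributes with trailing underscores).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator

from . import nnet
from .features import Spectrogram
from .phenomena import CLASSES, NOISE_CLASS


class InvalidConfigError(ValueError):
    """Model configuration violates an architectural contract."""


@dataclass
class ModelConfig:
    """Hyperparameters of the detector.

    ``time_pool`` must be 1: any time-axis downsampling would break the
    frame-for-frame correspondence between input spectrogram and output
    raster.  ``n_classes`` is 4, or 5 when the optional noise output is
    enabled.
    """

    conv_channels: tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    freq_pool: int = 2
    time_pool: int = 1
    rnn_hidden: int = 32
    rnn_layers: int = 1
    dropout: float = 0.25
    n_classes: int = 4
    learning_rate: float = 2e-3
    batch_size: int = 8
    chunk_frames: int = 256
    chunks_per_recording: int | None = None
    epochs: int = 15
    pos_weight: str | None = "auto"
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.time_pool != 1:
            raise InvalidConfigError(
                "time_pool must be 1: the raster must keep 10 ms time resolution"
            )
        if self.n_classes not in (4, 5):
            raise InvalidConfigError("n_classes must be 4, or 5 with the noise output")
        positive = {
            "kernel": self.kernel, "freq_pool": self.freq_pool,
            "rnn_hidden": self.rnn_hidden, "rnn_layers": self.rnn_layers,
            "learning_rate": self.learning_rate, "batch_size": self.batch_size,
            "chunk_frames": self.chunk_frames, "epochs": self.epochs,
        }
        for k, v in positive.items():
            if v <= 0:
                raise InvalidConfigError(f"{k} must be positive, got {v}")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidConfigError("dropout must lie in [0, 1)")
        if any(c <= 0 for c in self.conv_channels):
            raise InvalidConfigError("conv channel counts must be positive")
        return self


def class_names_for(n_classes: int) -> tuple[str, ...]:
    return CLASSES if n_classes == 4 else (*CLASSES, NOISE_CLASS)


class CRNNDetector(BaseEstimator):
    """Polyphonic respiratory sound-event detector (CRNN).

    Parameters mirror :class:`ModelConfig`; see that class for meanings.
    ``pos_weight="auto"`` weights each class's positive frames by
    ``sqrt(n_negative / n_positive)`` computed on the training set and
    clipped to [1, 8], countering the rarity of pathological frames without
    flooding rare classes with false alarms; ``None`` trains unweighted.

    Fitted attributes: ``layers_`` (parameterized network), ``history_``
    (per-epoch losses and validation scores), ``n_features_in_``,
    ``classes_``.
    """

    def __init__(self, conv_channels=(16, 32, 64), kernel=3, freq_pool=2, time_pool=1,
                 rnn_hidden=32, rnn_layers=1, dropout=0.25, n_classes=4,
                 learning_rate=2e-3, batch_size=8, chunk_frames=256,
                 chunks_per_recording=None, epochs=15, pos_weight="auto", seed=0):
        self.conv_channels = conv_channels
        self.kernel = kernel
        self.freq_pool = freq_pool
        self.time_pool = time_pool
        self.rnn_hidden = rnn_hidden
        self.rnn_layers = rnn_layers
        self.dropout = dropout
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.chunk_frames = chunk_frames
        self.chunks_per_recording = chunks_per_recording
        self.epochs = epochs
        self.pos_weight = pos_weight
        self.seed = seed

    # -- construction -------------------------------------------------

    def config(self) -> ModelConfig:
        return ModelConfig(
            conv_channels=tuple(self.conv_channels), kernel=self.kernel,
            freq_pool=self.freq_pool, time_pool=self.time_pool,
            rnn_hidden=self.rnn_hidden, rnn_layers=self.rnn_layers,
            dropout=self.dropout, n_classes=self.n_classes,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            chunk_frames=self.chunk_frames, chunks_per_recording=self.chunks_per_recording,
            epochs=self.epochs, pos_weight=self.pos_weight, seed=self.seed,
        ).validate()

    def initialize(self, n_features: int) -> "CRNNDetector":
        """Build (seeded) untrained weights for ``n_features`` input bins."""
        cfg = self.config()
        f = n_features
        for _ in cfg.conv_channels:
            if f % cfg.freq_pool:
                raise InvalidConfigError(
                    f"{n_features} input bins not divisible by freq_pool^{len(cfg.conv_channels)}"
                )
            f //= cfg.freq_pool
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        layers = []
        c_in = 1
        for c_out in cfg.conv_channels:
            layers.append(nnet.Conv2d(c_in, c_out, cfg.kernel, rng))
            layers.append(nnet.ReLU())
            layers.append(nnet.MaxPoolFreq(cfg.freq_pool))
            c_in = c_out
        self._conv_layers = layers
        self._conv_dropout = nnet.Dropout(cfg.dropout, self._dropout_rng)
        d_rnn = c_in * f
        self._rnns = []
        d_in = d_rnn
        for _ in range(cfg.rnn_layers):
            self._rnns.append(nnet.BiGRU(d_in, cfg.rnn_hidden, rng))
            d_in = 2 * cfg.rnn_hidden
        self._rnn_dropout = nnet.Dropout(cfg.dropout, self._dropout_rng)
        self._head = nnet.Dense(d_in, cfg.n_classes, rng)
        self.layers_ = nnet.flatten_layers(
            [*self._conv_layers, *self._rnns, self._head]
        )
        self.n_features_in_ = n_features
        self.classes_ = class_names_for(cfg.n_classes)
        self.history_ = []
        return self

    # -- forward/backward ---------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """x: (B, T, F) -> probabilities (B, T, C)."""
        h = x[:, None, :, :]  # (B, 1, T, F)
        for layer in self._conv_layers:
            h = layer.forward(h, train)
        h = self._conv_dropout.forward(h, train)
        B, C, T, F = h.shape
        self._conv_out_shape = (B, C, T, F)
        h = h.transpose(0, 2, 1, 3).reshape(B, T, C * F)
        for rnn in self._rnns:
            h = rnn.forward(h, train)
        h = self._rnn_dropout.forward(h, train)
        logits = self._head.forward(h, train)
        return nnet.sigmoid(logits)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self._head.backward(dlogits)
        d = self._rnn_dropout.backward(d)
        for rnn in reversed(self._rnns):
            d = rnn.backward(d)
        B, C, T, F = self._conv_out_shape
        d = d.reshape(B, T, C, F).transpose(0, 2, 1, 3)
        d = self._conv_dropout.backward(d)
        for layer in reversed(self._conv_layers):
            d = layer.backward(d)

    # -- training ------------------------------------------------------

    @staticmethod
    def _as_matrix(s) -> np.ndarray:
        v = s.values if isinstance(s, Spectrogram) else np.asarray(s)
        return np.ascontiguousarray(v, dtype=np.float32)

    def _resolve_pos_weight(self, Y: list[np.ndarray]):
        if self.pos_weight is None:
            return None
        if isinstance(self.pos_weight, str) and self.pos_weight == "auto":
            stacked = np.concatenate(Y, axis=0)
            pos = stacked.sum(axis=0).astype(np.float64)
            neg = stacked.shape[0] - pos
            w = np.sqrt(np.where(pos > 0, neg / np.maximum(pos, 1.0), 1.0))
            return np.clip(w, 1.0, 8.0).astype(np.float32)
        return np.asarray(self.pos_weight, dtype=np.float32)

    def fit(self, X, y, validation_data=None):
        """Train on lists of spectrograms and frame-truth matrices.

        X : list of (T_i, F) arrays or :class:`Spectrogram`
        y : list of (T_i, C) boolean frame-activation matrices
        validation_data : optional (X_val, y_val); when given, the weights
            from the epoch with the best validation loss are retained.
        """
        cfg = self.config()
        X = [self._as_matrix(s) for s in X]
        Y = [np.asarray(t, dtype=np.float32) for t in y]
        if len(X) == 0:
            raise ValueError("empty training corpus")
        if len(X) != len(Y):
            raise ValueError("X and y length mismatch")
        for s, t in zip(X, Y):
            if s.shape[0] != t.shape[0]:
                raise ValueError("spectrogram and frame truth disagree on frame count")
            if t.shape[1] != cfg.n_classes:
                raise ValueError(
                    f"frame truth has {t.shape[1]} classes, model expects {cfg.n_classes}"
                )
        class_pos = np.concatenate(Y, axis=0).sum(axis=0)
        absent = [class_names_for(cfg.n_classes)[j] for j in np.nonzero(class_pos == 0)[0]]
        if absent:
            warnings.warn(f"classes with no positive frames in corpus: {absent}", RuntimeWarning)

        self.initialize(X[0].shape[1])
        pos_weight = self._resolve_pos_weight(Y)
        opt = nnet.Adam(self.layers_, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 2)
        chunk = min(cfg.chunk_frames, min(s.shape[0] for s in X))

        best = None
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(X))
            batches = self._make_chunks(X, Y, order, chunk, cfg.batch_size, rng)
            losses = []
            for xb, yb in batches:
                probs = self._forward(xb, train=True)
                loss, dlogits = nnet.bce_loss(probs, yb, pos_weight)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch}; "
                        "lower the learning rate or check input scaling"
                    )
                for layer in self.layers_:
                    layer.zero_grad()
                self._backward(dlogits)
                opt.step()
                losses.append(loss)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if validation_data is not None:
                Xv = [self._as_matrix(s) for s in validation_data[0]]
                Yv = [np.asarray(t, dtype=np.float32) for t in validation_data[1]]
                vloss = self._eval_loss(Xv, Yv, pos_weight)
                entry["val_loss"] = vloss
                if best is None or vloss < best[0]:
                    best = (vloss, self._get_weights())
            self.history_.append(entry)
        if best is not None:
            self._set_weights(best[1])
        return self

    def _make_chunks(self, X, Y, order, chunk, batch_size, rng):
        xs, ys = [], []
        for i in order:
            T = X[i].shape[0]
            n_chunks = self.chunks_per_recording or max(1, T // chunk)
            for _ in range(n_chunks):
                start = int(rng.integers(0, T - chunk + 1))
                xs.append(X[i][start : start + chunk])
                ys.append(Y[i][start : start + chunk])
        batches = []
        for b in range(0, len(xs), batch_size):
            batches.append(
                (np.stack(xs[b : b + batch_size]), np.stack(ys[b : b + batch_size]))
            )
        return batches

    def _eval_loss(self, X, Y, pos_weight) -> float:
        total, n = 0.0, 0
        for probs, t in zip(self._forward_many(X), Y):
            loss, _ = nnet.bce_loss(probs.astype(np.float32), t, pos_weight)
            total += loss * t.size
            n += t.size
        return total / max(n, 1)

    def _forward_many(self, X, batch: int = 8):
        """Inference rasters for a list of inputs, batching runs of
        equal-length sequences for speed (results match the per-sequence
        path to float32 round-off)."""
        X = [self._as_matrix(s) for s in X]
        out: list = [None] * len(X)
        i = 0
        while i < len(X):
            j = i + 1
            while j < len(X) and j - i < batch and X[j].shape == X[i].shape:
                j += 1
            block = self._forward(np.stack(X[i:j]), train=False)
            for k in range(i, j):
                out[k] = block[k - i].astype(np.float64)
            i = j
        return out

    def _get_weights(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers_]

    def _set_weights(self, weights):
        for l, w in zip(self.layers_, weights):
            for k in l.params:
                l.params[k][...] = w[k]

    # -- inference -----------------------------------------------------

    def predict_proba(self, X):
        """Probability raster(s): (T, C) per input, entries in [0, 1].

        Each recording is processed independently, so results do not depend
        on how inputs are grouped or ordered.
        """
        if not hasattr(self, "layers_"):
            raise RuntimeError("detector is not initialized; call fit() or initialize()")
        single = isinstance(X, (Spectrogram, np.ndarray))
        seqs = [X] if single else list(X)
        out = []
        for s in seqs:
            m = self._as_matrix(s)
            if m.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"input has {m.shape[1]} bins, model was built for {self.n_features_in_}"
                )
            out.append(self._forward(m[None], train=False)[0].astype(np.float64))
        return out[0] if single else out

    def predict(self, X, thresholds=0.5):
        from .postprocess import threshold_raster

        rasters = self.predict_proba(X)
        if isinstance(rasters, np.ndarray):
            return threshold_raster(rasters, thresholds)
        return [threshold_raster(r, thresholds) for r in rasters]

    # -- persistence ---------------------------------------------------

    def save(self, path, frontend_config: dict | None = None) -> None:
        """Self-describing checkpoint: weights + model config + frontend
        config + class order, with a config hash verified on load."""
        meta = {
            "model_config": asdict(self.config()),
            "frontend_config": frontend_config or {},
            "class_order": list(self.classes_),
            "n_features_in": int(self.n_features_in_),
        }
        blob = json.dumps(meta, sort_keys=True)
        arrays = {"__meta__": np.frombuffer(blob.encode(), dtype=np.uint8),
                  "__hash__": np.frombuffer(hashlib.sha256(blob.encode()).digest(), dtype=np.uint8)}
        for i, l in enumerate(self.layers_):
            for k, v in l.params.items():
                arrays[f"layer{i}.{k}"] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> tuple["CRNNDetector", dict]:
        data = np.load(path)
        blob = bytes(data["__meta__"]).decode()
        if hashlib.sha256(blob.encode()).digest() != bytes(data["__hash__"]):
            raise ValueError(f"checkpoint {path}: config hash mismatch (corrupt file?)")
        meta = json.loads(blob)
        mc = meta["model_config"]
        mc["conv_channels"] = tuple(mc["conv_channels"])
        det = cls(**mc)
        det.initialize(meta["n_features_in"])
        for i, l in enumerate(det.layers_):
            for k in l.params:
                l.params[k][...] = data[f"layer{i}.{k}"]
        return det, meta


def build_model(config: ModelConfig) -> CRNNDetector:
    """Detector from a validated :class:`ModelConfig`."""
    return CRNNDetector(**asdict(config.validate()))
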