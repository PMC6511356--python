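"""Time-frequency frontend aligned to the 10 ms raster grid.

The detector consumes a log-power spectrogram whose frame ``i`` covers the
half-open interval ``[i*10 ms, (i+1)*10 ms)`` — exactly the grid of the
ground-truth activation matrices, so the frame counts of features and labels
always agree.  Default configuration: 256-sample (32 ms) Hann window,
80-sample (10 ms) hop, 64 mel bands spanning 30-4000 Hz, log floor 1e-10.
A linear-frequency axis is available via ``n_mels=None``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .phenomena import FRAME_HOP_S
from .simulate import DEFAULT_SAMPLE_RATE


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int,
                   fmin: float, fmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filters (peak 1).  Returns (filters[n_mels, n_bins],
    band center frequencies in Hz)."""
    n_bins = n_fft // 2 + 1
    fft_freqs = np.arange(n_bins) * sample_rate / n_fft
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return fb, hz_pts[1:-1]


@dataclass
class Spectrogram:
    """Log-power time-frequency matrix on the 10 ms grid.

    ``values`` is (frames, bins) in dB-like units (10*log10 power, floored);
    ``bin_centers`` are the band center frequencies in Hz.
    """

    values: np.ndarray
    bin_centers: np.ndarray
    frame_hop: float = FRAME_HOP_S
    config: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


class MelFrontend(BaseEstimator, TransformerMixin):
    """Stateless spectrogram transformer (scikit-learn style).

    Parameters
    ----------
    sample_rate : expected input rate in Hz.
    n_fft : analysis window length in samples (Hann).
    n_mels : number of mel bands, or None for a linear-frequency axis.
    fmin, fmax : mel filterbank frequency range in Hz.
    log_floor : power floor before the log, guarding silence.
    """

    def __init__(self, sample_rate: int = DEFAULT_SAMPLE_RATE, n_fft: int = 256,
                 n_mels: int | None = 64, fmin: float = 30.0, fmax: float = 4000.0,
                 log_floor: float = 1e-10):
        self.sample_rate = sample_rate
        self.n_fft = n_fft
        self.n_mels = n_mels
        self.fmin = fmin
        self.fmax = fmax
        self.log_floor = log_floor

    @property
    def hop(self) -> int:
        return round(self.sample_rate * FRAME_HOP_S)

    def fit(self, X=None, y=None):
        return self

    def transform(self, samples: np.ndarray, sample_rate: int | None = None) -> Spectrogram:
        """Spectrogram of one mono signal; frame count = floor(n/hop)."""
        x = np.asarray(samples, dtype=np.float64)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("expected a non-empty 1-D signal")
        if sample_rate is not None and sample_rate != self.sample_rate:
            raise ValueError(
                f"signal rate {sample_rate} Hz does not match frontend rate {self.sample_rate} Hz"
            )
        hop, n_fft = self.hop, self.n_fft
        if x.size < n_fft:
            raise ValueError(f"need at least one full window ({n_fft} samples), got {x.size}")
        frames = x.size // hop
        pad = (n_fft - hop) // 2
        xp = np.pad(x, pad, mode="reflect")
        windows = np.lib.stride_tricks.sliding_window_view(xp, n_fft)[::hop][:frames]
        win = np.hanning(n_fft)
        power = np.abs(np.fft.rfft(windows * win, axis=1)) ** 2
        if self.n_mels is not None:
            fb, centers = mel_filterbank(self.n_mels, n_fft, self.sample_rate, self.fmin, self.fmax)
            power = power @ fb.T
        else:
            centers = np.arange(n_fft // 2 + 1) * self.sample_rate / n_fft
        values = 10.0 * np.log10(np.maximum(power, self.log_floor))
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in input signal")
        return Spectrogram(values=values, bin_centers=centers, config=self.get_params())


def spectrogram(samples: np.ndarray, sample_rate: int = DEFAULT_SAMPLE_RATE,
                **params) -> Spectrogram:
    """Functional wrapper over :class:`MelFrontend`."""
    return MelFrontend(sample_rate=sample_rate, **params).transform(samples)


class SpectrogramScaler(BaseEstimator, TransformerMixin):
    """Per-bin standardization fitted on the training corpus.

    After ``fit`` on a set of spectrograms, ``transform`` maps each frequency
    bin to zero mean and unit variance (bins with zero variance keep a unit
    divisor, with a warning).  ``inverse_transform`` undoes the mapping.
    """

    def fit(self, X, y=None):
        if isinstance(X, (list, tuple)):
            stacked = np.concatenate([self._values(s) for s in X], axis=0)
        else:
            stacked = self._values(X)
        self.mean_ = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        zero = sd < 1e-12
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance bins; unit divisor substituted", RuntimeWarning
            )
            sd = np.where(zero, 1.0, sd)
        self.scale_ = sd
        self.n_features_in_ = stacked.shape[1]
        return self

    @staticmethod
    def _values(s):
        return s.values if isinstance(s, Spectrogram) else np.asarray(s, dtype=np.float64)

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [self.transform(s) for s in X]
        v = (self._values(X) - self.mean_) / self.scale_
        if isinstance(X, Spectrogram):
            return Spectrogram(values=v, bin_centers=X.bin_centers,
                               frame_hop=X.frame_hop, config=X.config)
        return v

    def inverse_transform(self, X):
        if isinstance(X, (list, tuple)):
            return [self.inverse_transform(s) for s in X]
        v = self._values(X) * self.scale_ + self.mean_
        if isinstance(X, Spectrogram):
            return Spectrogram(values=v, bin_centers=X.bin_centers,
                               frame_hop=X.frame_hop, config=X.config)
        return v


def normalize(spec: Spectrogram, stats: SpectrogramScaler) -> Spectrogram:
    """Apply fitted per-bin standardization (training-corpus statistics)."""
    return stats.transform(spec)


def denormalize(spec: Spectrogram, stats: SpectrogramScaler) -> Spectrogram:
    return stats.inverse_transform(spec)


def to_png(spec: Spectrogram, path) -> None:
    """Write the spectrogram as a grayscale PNG (low frequencies at the
    bottom), for visual inspection."""
    from PIL import Image

    v = spec.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    img = (255.0 * scaled.T[::-1]).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))
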