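"""Audio ingestion, pitch estimation and glottal inverse filtering.

Recorded sustained vowels stand in for the lip pressure pm(t).  This module
reads PCM WAV audio, resamples and normalizes it, estimates the fundamental
frequency by autocorrelation, and provides an IAIF-style (iterative adaptive
inverse filtering) utility that strips the vocal-tract resonances and lip
radiation from a voiced segment to estimate the glottal flow, which serves
as the reference signal of the glottal-side estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter, resample_poly

from .exceptions import DegenerateSignalError, NoPeriodicityError

__all__ = [
    "AudioSignal",
    "ReferenceFlow",
    "read_wav",
    "write_wav",
    "normalize_signal",
    "load_normalize_audio",
    "estimate_f0",
    "lpc",
    "inverse_filter",
]

DEFAULT_TARGET_FS = 16000


@dataclass
class AudioSignal:
    """Mono audio samples with sample rate; ``normalized`` marks zero-mean
    unit-variance scaling."""

    samples: np.ndarray
    fs: float
    normalized: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DegenerateSignalError("sample rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ReferenceFlow:
    """Normalized glottal volume-velocity estimate on a physical time grid."""

    t: np.ndarray
    ug: np.ndarray


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file, downmixing multichannel audio to mono."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(data, float(fs))


def write_wav(path, sig: AudioSignal, dtype=np.int16) -> None:
    """Write audio as PCM WAV, scaling to the full range of ``dtype``."""
    x = sig.samples
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 0:
        x = x / peak
    scaled = np.round(x * (np.iinfo(dtype).max - 1)).astype(dtype)
    wavfile.write(path, int(sig.fs), scaled)


def normalize_signal(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization; errors on constant input."""
    x = np.asarray(x, dtype=float)
    s = x.std()
    if not np.isfinite(s) or s < 1e-300:
        raise DegenerateSignalError("cannot normalize a zero-variance signal")
    return (x - x.mean()) / s


def load_normalize_audio(path, target_fs: int = DEFAULT_TARGET_FS) -> AudioSignal:
    """Read, resample to ``target_fs`` and normalize a voiced recording."""
    sig = read_wav(path)
    return preprocess_audio(sig, target_fs)


def preprocess_audio(sig: AudioSignal, target_fs: int = DEFAULT_TARGET_FS) -> AudioSignal:
    """Resample to ``target_fs`` (polyphase) and normalize."""
    x = sig.samples
    if int(sig.fs) != int(target_fs):
        frac = Fraction(int(target_fs), int(sig.fs)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    return AudioSignal(normalize_signal(x), float(target_fs), normalized=True)


def estimate_f0(sig: AudioSignal, fmin: float = 50.0, fmax: float = 500.0,
                min_periodicity: float = 0.3) -> float:
    """Fundamental frequency by the autocorrelation method.

    Searches the autocorrelation peak between lags fs/fmax and fs/fmin with
    parabolic interpolation; raises if the normalized peak falls below
    ``min_periodicity`` (aperiodic input).
    """
    x = np.asarray(sig.samples, dtype=float)
    x = x - x.mean()
    if x.size < int(2 * sig.fs / fmin):
        raise DegenerateSignalError("signal too short for pitch estimation")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        raise DegenerateSignalError("zero-energy signal")
    ac = ac / ac[0]
    lag_min = max(2, int(np.floor(sig.fs / fmax)))
    lag_max = min(n - 2, int(np.ceil(sig.fs / fmin)))
    if lag_max <= lag_min:
        raise DegenerateSignalError("invalid pitch search range")
    seg = ac[lag_min:lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] < min_periodicity:
        raise NoPeriodicityError(
            f"autocorrelation peak {ac[k]:.3f} below {min_periodicity}")
    # parabolic refinement of the peak lag
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float(sig.fs / (k + shift))


def lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Linear-prediction coefficients by the autocorrelation method.

    Returns ``a = [1, a1, ..., a_order]`` from Levinson-Durbin recursion;
    the autocorrelation method guarantees a stable all-pole model.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        raise DegenerateSignalError("signal shorter than LPC order")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:order + 1]
    if r[0] <= 0:
        raise DegenerateSignalError("zero-energy frame in LPC")
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[i - 1:0:-1])
        k = -acc / err
        a[1:i + 1] = a[1:i + 1] + k * a[i - 1::-1][:i]
        err *= (1 - k * k)
        if err <= 0:
            raise DegenerateSignalError("LPC recursion lost positivity")
    return a


def _integrate(x, leak=0.99):
    """Leaky integration 1/(1 - leak z^-1); cancels a differentiation."""
    return lfilter([1.0], [1.0, -leak], x)


def inverse_filter(sig: AudioSignal, lpc_order: int | None = None,
                   glottal_order: int = 4, n_refine: int = 2,
                   pre_emphasis: float = 0.97) -> ReferenceFlow:
    """Glottal flow estimate by iterative adaptive inverse filtering.

    The standard IAIF recipe: a low-order model of the glottal contribution
    is estimated and removed before each vocal-tract LPC analysis, the
    speech is inverse filtered by the tract model, and the lip-radiation
    differentiation is cancelled by leaky integration.  ``n_refine`` extra
    passes re-estimate the tract model from the current flow estimate.  The
    returned flow is normalized to zero mean and unit variance.
    """
    x = np.asarray(sig.samples, dtype=float)
    if x.size == 0 or x.std() < 1e-300:
        raise DegenerateSignalError("silent or empty signal")
    fs = sig.fs
    if lpc_order is None:
        lpc_order = int(fs / 1000) + 2
    win = np.hamming(x.size)

    # first pass: order-1 glottal pre-model, tract LPC, inverse filter
    g1 = lpc(win * lfilter([1, -pre_emphasis], [1], x), 1)
    y1 = lfilter(g1, [1], x)
    a_vt = lpc(win * y1, lpc_order)
    flow = _integrate(lfilter(a_vt, [1], x))

    for _ in range(n_refine):
        g = lpc(win * flow, glottal_order)
        y = lfilter(g, [1], x)
        a_vt = lpc(win * y, lpc_order)
        flow = _integrate(lfilter(a_vt, [1], x))

    t = np.arange(x.size) / fs
    return ReferenceFlow(t, normalize_signal(flow))
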