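"""Gabor filter-bank decomposition of iEEG into canonical frequency bands.

The eight bands span delta through fast ripples (FR).  Each band is
realized by an analytic log-Gabor kernel: the magnitude response is a
Gaussian on the log-frequency axis, centered at the geometric mean of the
band edges and -3 dB at both edges.  A Gaussian on a *linear* frequency
axis cannot be -3 dB at both edges of an octave-spanning band, which is
why the log-frequency parameterization is used; the time-domain
coefficients are recovered by inverse FFT of the one-sided response and
truncated where the envelope falls to exp(-8) of its peak (the 4-sigma
point of a Gaussian envelope).

"Background" activity is defined as the 3.5–200 Hz range, reconstructed
as the sum of the theta..ripple band outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .circuits import ConfigurationError

__all__ = [
    "BandDef",
    "GaborKernel",
    "Spectrogram",
    "PAPER_BANDS",
    "BACKGROUND_BAND_NAMES",
    "build_filter_bank",
    "band_decompose",
    "compute_spectrogram",
]

# amplitude ratio at a -3 dB point
_EDGE_AMPLITUDE = 10.0 ** (-3.0 / 20.0)
# exp(-x^2/(2 s^2)) = _EDGE_AMPLITUDE  =>  x = s * _EDGE_X
_EDGE_X = math.sqrt(-2.0 * math.log(_EDGE_AMPLITUDE))


@dataclass(frozen=True)
class BandDef:
    name: str
    f_low: float   # Hz
    f_high: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ConfigurationError(f"band {self.name}: need 0 < f_low < f_high")


#: Canonical eight-band table (Hz).
PAPER_BANDS: list[BandDef] = [
    BandDef("delta", 0.5, 3.5),
    BandDef("theta", 3.5, 8.0),
    BandDef("alpha", 8.0, 15.0),
    BandDef("beta", 15.0, 30.0),
    BandDef("gamma", 30.0, 80.0),
    BandDef("high_gamma", 80.0, 120.0),
    BandDef("ripple", 120.0, 200.0),
    BandDef("fr", 200.0, 600.0),
]

#: Bands summed to reconstruct the background (theta..ripple, 3.5-200 Hz).
BACKGROUND_BAND_NAMES: tuple[str, ...] = (
    "theta",
    "alpha",
    "beta",
    "gamma",
    "high_gamma",
    "ripple",
)


@dataclass(frozen=True)
class GaborKernel:
    """Analytic band-pass kernel with unit peak response at center_freq.

    ``freq_sigma`` is the local linear-frequency equivalent of the
    log-axis Gaussian width (f_c * sigma_log).
    """

    name: str
    center_freq: float       # Hz
    freq_sigma: float        # Hz
    length: int              # samples, odd
    coefficients: np.ndarray  # complex

    def frequency_response(self, freqs: np.ndarray, fs: float) -> np.ndarray:
        """DTFT of the kernel at the given frequencies (Hz)."""
        m = np.arange(self.length) - self.length // 2
        return np.exp(-2j * np.pi * np.outer(freqs, m) / fs) @ self.coefficients


def _log_gabor_response(freqs: np.ndarray, f_c: float, sigma_log: float) -> np.ndarray:
    resp = np.zeros_like(freqs, dtype=float)
    pos = freqs > 0
    resp[pos] = np.exp(-(np.log(freqs[pos] / f_c) ** 2) / (2.0 * sigma_log**2))
    return resp


def _design_kernel(band: BandDef, fs: float) -> GaborKernel:
    f_c = math.sqrt(band.f_low * band.f_high)
    sigma_log = math.log(band.f_high / f_c) / _EDGE_X
    # design grid long enough for the slowest envelope to decay
    n_fft = 1 << max(10, math.ceil(math.log2(16.0 * fs / band.f_low)))
    freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)
    g = np.fft.ifft(_log_gabor_response(freqs, f_c, sigma_log))
    g = np.roll(g, n_fft // 2)  # center the kernel
    env = np.abs(g)
    peak = int(np.argmax(env))
    keep = env >= env[peak] * math.exp(-8.0)
    idx = np.nonzero(keep)[0]
    half = max(peak - idx[0], idx[-1] - peak, 1)
    lo, hi = max(0, peak - half), min(n_fft, peak + half + 1)
    coeffs = g[lo:hi]
    if coeffs.size % 2 == 0:  # keep odd length, peak centered
        coeffs = coeffs[:-1]
    # normalize to unit peak response at the center frequency
    m = np.arange(coeffs.size) - coeffs.size // 2
    h_fc = np.sum(coeffs * np.exp(-2j * np.pi * f_c * m / fs))
    coeffs = coeffs / np.abs(h_fc)
    return GaborKernel(
        name=band.name,
        center_freq=f_c,
        freq_sigma=f_c * sigma_log,
        length=coeffs.size,
        coefficients=coeffs,
    )


def build_filter_bank(bands: list[BandDef], fs: float) -> list[GaborKernel]:
    """One analytic kernel per band; raises if any band exceeds Nyquist/2 margin."""
    for band in bands:
        if fs <= 2.0 * band.f_high:
            raise ConfigurationError(
                f"band {band.name} upper edge {band.f_high} Hz needs fs > {2 * band.f_high} Hz"
            )
    return [_design_kernel(band, fs) for band in bands]


def _convolve_same_reflect(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-length convolution with reflect padding at the edges."""
    half = kernel.size // 2
    pad = min(half, signal.size - 1) if signal.size > 1 else 0
    if pad:
        padded = np.concatenate([signal[pad:0:-1], signal, signal[-2 : -2 - pad : -1]])
    else:
        padded = signal
    out = fftconvolve(padded, kernel, mode="same")
    return out[pad : pad + signal.size]


def band_decompose(
    signal: np.ndarray, bank: list[GaborKernel], fs: float
) -> dict[str, np.ndarray]:
    """Decompose a signal onto the filter bank.

    Returns one real band signal per kernel (same length as the input,
    reflect-padded edges) plus a ``background`` entry summing the
    theta..ripple outputs when those bands are present.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    out: dict[str, np.ndarray] = {}
    for kernel in bank:
        # factor 2: the analytic kernel only passes positive frequencies, so
        # a real in-band tone of amplitude A comes out at A/2 before scaling
        out[kernel.name] = 2.0 * _convolve_same_reflect(x, kernel.coefficients).real
    bg_parts = [out[name] for name in BACKGROUND_BAND_NAMES if name in out]
    if bg_parts:
        out["background"] = np.sum(bg_parts, axis=0)
    return out


@dataclass(frozen=True)
class Spectrogram:
    times: np.ndarray       # s
    freqs: np.ndarray       # Hz
    magnitudes: np.ndarray  # (n_times, n_freqs), >= 0

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (self.times.size, self.freqs.size):
            raise ValueError("magnitudes must be (n_times, n_freqs)")


def compute_spectrogram(
    signal: np.ndarray,
    fs: float,
    f_min: float = 200.0,
    f_max: float = 600.0,
    f_step: float = 5.0,
    n_cycles: float = 6.0,
) -> Spectrogram:
    """Morlet-style Gabor transform magnitude on a linear frequency grid.

    Each analysis frequency uses a Gaussian window of temporal width
    sigma_t = n_cycles / (2*pi*f), truncated at 4 sigma, with unit peak
    frequency response so magnitudes are comparable across frequencies.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if not (0 < f_min < f_max <= fs / 2):
        raise ConfigurationError("need 0 < f_min < f_max <= fs/2")
    freqs = np.arange(f_min, f_max + f_step / 2, f_step)
    mags = np.empty((x.size, freqs.size), dtype=float)
    for j, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = max(1, int(round(4.0 * sigma_t * fs)))
        t = np.arange(-half, half + 1) / fs
        win = np.exp(-(t**2) / (2.0 * sigma_t**2))
        kernel = win * np.exp(2j * np.pi * f * t)
        kernel /= np.sum(win)  # unit response to e^{j2*pi*f*t}
        mags[:, j] = np.abs(_convolve_same_reflect(x, kernel))
    times = np.arange(x.size) / fs
    return Spectrogram(times=times, freqs=freqs, magnitudes=mags)
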