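"""Synthetic data with known ground truth.

Generates (a) impedance spectra from circuit presets with optional
proportional complex noise, and (b) multichannel iEEG-like recordings:
1/f^beta background plus Gabor-enveloped FR bursts, passed per channel
through an electrode transfer function and contaminated with thermal
(Johnson) and amplifier noise.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from the spec; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.signal import windows

from .circuits import (
    DEFAULT_SHUNT,
    PRESETS,
    CircuitParams,
    ConfigurationError,
    ImpedanceSpectrum,
    ShuntSpec,
    circuit_impedance,
    log_grid,
)

__all__ = [
    "BackgroundSpec",
    "EventTruth",
    "FREventSpec",
    "NoiseSpec",
    "ChannelSpec",
    "RecordingSpec",
    "Recording",
    "GroundTruth",
    "gen_background",
    "gen_fr_event",
    "render_recording",
    "gen_eis",
    "paper_like_scenario",
]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class FREventSpec:
    """One fast-ripple burst: a sinusoid under a smooth envelope."""

    center_time: float  # s
    freq: float         # Hz, within 200-600
    n_cycles: int       # >= 4
    amplitude: float    # signal units (peak)
    envelope: Literal["gaussian", "tukey"] = "gaussian"

    def __post_init__(self) -> None:
        if not 200.0 <= self.freq <= 600.0:
            raise ConfigurationError("FR event frequency must lie in 200-600 Hz")
        if self.n_cycles < 4:
            raise ConfigurationError("FR events need >= 4 cycles")
        if self.amplitude <= 0:
            raise ConfigurationError("amplitude must be > 0")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.freq


@dataclass(frozen=True)
class NoiseSpec:
    enable_thermal: bool = False
    temperature_K: float = 310.0
    amplifier_rms: float = 0.0


@dataclass(frozen=True)
class ChannelSpec:
    """One recording channel: either a circuit + shunt defining H(jw), a
    flat broadband gain in dB, or neither (ideal unity channel)."""

    name: str
    circuit: Optional[CircuitParams] = None
    shunt: ShuntSpec = DEFAULT_SHUNT
    gain_db: Optional[float] = None
    noise: NoiseSpec = NoiseSpec()


@dataclass(frozen=True)
class BackgroundSpec:
    one_over_f_exponent: float = 1.0  # beta in PSD ~ 1/f^beta
    total_rms: float = 50e-6          # signal units

    def __post_init__(self) -> None:
        if not 0.0 <= self.one_over_f_exponent <= 2.0:
            raise ConfigurationError("background exponent beta must lie in [0, 2]")
        if self.total_rms < 0:
            raise ConfigurationError("total_rms must be >= 0")


@dataclass(frozen=True)
class RecordingSpec:
    fs: float = 2048.0
    duration: float = 60.0
    background: BackgroundSpec = BackgroundSpec()
    events: tuple[FREventSpec, ...] = ()
    channels: tuple[ChannelSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 1200.0:
            raise ConfigurationError("fs must exceed 1200 Hz (Nyquist for 600 Hz)")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")


@dataclass(frozen=True)
class Recording:
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    channel_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EventTruth:
    event_id: str
    onset_s: float
    offset_s: float
    freq: float
    amplitude: float
    channel_gain_db: dict[str, float]  # |H| at the event frequency, per channel


@dataclass(frozen=True)
class GroundTruth:
    events: tuple[EventTruth, ...]


def gen_background(
    n_samples: int,
    fs: float,
    beta: float = 1.0,
    total_rms: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean Gaussian noise with power spectral density ~ 1/f^beta,
    scaled to the requested total RMS."""
    if not 0.0 <= beta <= 2.0:
        raise ConfigurationError("beta must lie in [0, 2]")
    if total_rms == 0:
        return np.zeros(n_samples)
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n_samples)
    x -= x.mean()
    rms = math.sqrt(float(np.mean(x**2)))
    return x * (total_rms / rms)


def gen_fr_event(event: FREventSpec, fs: float) -> tuple[np.ndarray, int, int, int]:
    """Render one burst on its local sample grid.

    Returns ``(waveform, center_index, onset_rel, offset_rel)`` where the
    relative onset/offset are the half-maximum crossings of the envelope
    (half-open, in samples from the start of the waveform).
    """
    d = event.duration
    if event.envelope == "gaussian":
        half = int(round(1.5 * d * fs)) + 1
        t = np.arange(-half, half + 1) / fs
        sigma = d / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM = duration
        env = np.exp(-(t**2) / (2.0 * sigma**2))
    elif event.envelope == "tukey":
        n = max(int(round(d * fs)), 3)
        n += 1 - n % 2  # odd length, peak centered
        half = n // 2
        t = np.arange(-half, half + 1) / fs
        env = windows.tukey(n, alpha=0.5)
    else:
        raise ConfigurationError(f"unknown envelope {event.envelope!r}")
    waveform = event.amplitude * env * np.cos(2.0 * math.pi * event.freq * t)
    center = half
    above = np.nonzero(env >= 0.5 * env.max())[0]
    return waveform, center, int(above[0]), int(above[-1]) + 1


def _apply_transfer(
    neural: np.ndarray,
    fs: float,
    channel: ChannelSpec,
    pad_s: float = 1.0,
) -> np.ndarray:
    """Filter the neural signal by the channel's voltage-divider transfer
    function in the frequency domain (reflect-padded to suppress circular
    artifacts)."""
    if channel.gain_db is not None:
        return neural * 10.0 ** (channel.gain_db / 20.0)
    if channel.circuit is None:
        return neural.copy()
    pad = min(int(round(pad_s * fs)), neural.size - 1)
    x = np.concatenate([neural[pad:0:-1], neural, neural[-2 : -2 - pad : -1]])
    spectrum = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    h = np.ones_like(f, dtype=complex)
    pos = f > 0
    z = circuit_impedance(channel.circuit, f[pos]).impedances
    h[pos] = 1.0 / (1j * 2.0 * math.pi * f[pos] * channel.shunt.Cs * z + 1.0)
    y = np.fft.irfft(spectrum * h, n=x.size)
    return y[pad : pad + neural.size]


def _channel_gain_db(channel: ChannelSpec, freq: float) -> float:
    if channel.gain_db is not None:
        return channel.gain_db
    if channel.circuit is None:
        return 0.0
    z = circuit_impedance(channel.circuit, np.array([freq])).impedances[0]
    h = 1.0 / (1j * 2.0 * math.pi * freq * channel.shunt.Cs * z + 1.0)
    return float(20.0 * math.log10(abs(h)))


def _thermal_rms(channel: ChannelSpec, fs: float) -> float:
    """Johnson-noise RMS over the recording bandwidth fs/2, using the
    median real impedance over 1 Hz-1 kHz as the effective resistance."""
    if channel.circuit is None:
        return 0.0
    f = log_grid(1.0, 1e3, 20)
    r_eff = float(np.median(circuit_impedance(channel.circuit, f).impedances.real))
    return math.sqrt(4.0 * BOLTZMANN * channel.noise.temperature_K * max(r_eff, 0.0) * fs / 2.0)


def render_recording(spec: RecordingSpec) -> tuple[Recording, GroundTruth]:
    """Render the full multichannel recording and its ground truth.

    Channel order of operations: shared neural signal (background +
    bursts) -> per-channel transfer function -> additive thermal and
    amplifier noise.  Ground truth stores the envelope half-maximum
    onset/offset of every burst and each channel's gain at the burst
    frequency.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    neural = gen_background(
        n, spec.fs, spec.background.one_over_f_exponent, spec.background.total_rms, rng
    )
    truths = []
    for i, event in enumerate(spec.events):
        waveform, center, on_rel, off_rel = gen_fr_event(event, spec.fs)
        c = int(round(event.center_time * spec.fs))
        a = c - center
        b = a + waveform.size
        if a < 0 or b > n:
            raise ConfigurationError(
                f"event {i} at {event.center_time}s extends beyond the recording"
            )
        neural[a:b] += waveform
        truths.append(
            EventTruth(
                event_id=f"ev{i:03d}",
                onset_s=(a + on_rel) / spec.fs,
                offset_s=(a + off_rel) / spec.fs,
                freq=event.freq,
                amplitude=event.amplitude,
                channel_gain_db={
                    ch.name: _channel_gain_db(ch, event.freq) for ch in spec.channels
                },
            )
        )
    channels = spec.channels or (ChannelSpec(name="0"),)
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        y = _apply_transfer(neural, spec.fs, ch)
        if ch.noise.enable_thermal:
            y = y + _thermal_rms(ch, spec.fs) * rng.standard_normal(n)
        if ch.noise.amplifier_rms > 0:
            y = y + ch.noise.amplifier_rms * rng.standard_normal(n)
        data[i] = y
    rec = Recording(fs=spec.fs, data=data, channel_names=tuple(c.name for c in channels))
    return rec, GroundTruth(events=tuple(truths))


def gen_eis(
    params: CircuitParams,
    freqs: np.ndarray,
    noise_fraction: float = 0.0,
    seed: Optional[int] = None,
    coated_form: str = "parallel",
) -> ImpedanceSpectrum:
    """Circuit impedance with independent proportional complex Gaussian
    noise of relative scale ``noise_fraction``."""
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    spectrum = circuit_impedance(params, freqs, coated_form=coated_form)
    if noise_fraction == 0:
        return spectrum
    rng = np.random.default_rng(seed)
    g = (rng.standard_normal(len(spectrum)) + 1j * rng.standard_normal(len(spectrum))) / math.sqrt(2.0)
    z = spectrum.impedances * (1.0 + noise_fraction * g)
    return ImpedanceSpectrum(spectrum.frequencies, z)


def paper_like_scenario(
    seed: int = 0,
    duration: float = 60.0,
    n_events: int = 20,
    fs: float = 2048.0,
) -> RecordingSpec:
    """Default two-channel study scenario: 1/f background at 50 uV RMS,
    FR bursts uniform in 220-550 Hz and 4-12 cycles, channel A behind the
    bare-gold electrode and channel B behind the polymer-coated one, both
    with a 3 nF shunt and thermal + amplifier noise."""
    rng = np.random.default_rng(seed)
    margin = 0.5
    slots = np.linspace(margin, duration - margin, n_events)
    jitter = min((duration - 2 * margin) / (4.0 * n_events), margin / 2.0)
    centers = np.clip(
        slots + rng.uniform(-jitter, jitter, n_events), margin, duration - margin
    )
    events = tuple(
        FREventSpec(
            center_time=float(c),
            freq=float(rng.uniform(220.0, 550.0)),
            n_cycles=int(rng.integers(4, 13)),
            amplitude=float(rng.uniform(120e-6, 300e-6)),
        )
        for c in centers
    )
    noise = NoiseSpec(enable_thermal=True, temperature_K=310.0, amplifier_rms=1e-6)
    channels = (
        ChannelSpec(name="au", circuit=PRESETS["au"], shunt=DEFAULT_SHUNT, noise=noise),
        ChannelSpec(
            name="au_pedot", circuit=PRESETS["au_pedot"], shunt=DEFAULT_SHUNT, noise=noise
        ),
    )
    return RecordingSpec(
        fs=fs,
        duration=duration,
        background=BackgroundSpec(one_over_f_exponent=1.0, total_rms=50e-6),
        events=events,
        channels=channels,
        seed=int(seed),
    )
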