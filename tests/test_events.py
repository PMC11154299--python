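"""FR detection, segmentation, validation, energies and channel comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frobs.bands import band_decompose, compute_spectrogram
from frobs.events import (
    CandidateWindow,
    EnergyRecord,
    FRValidation,
    NoEventError,
    SegmentedFR,
    compare_channels,
    detect_candidates,
    event_energy,
    robust_rms,
    segment_event,
    validate_event,
)
from frobs.synth import FREventSpec, gen_background, gen_fr_event


def embed(events, fs, duration_s=2.0, background=None):
    """Place bursts in a (possibly zero) background; return signal + truths."""
    n = int(duration_s * fs)
    sig = np.zeros(n) if background is None else background.copy()
    truths = []
    for event in events:
        waveform, center, on, off = gen_fr_event(event, fs)
        a = int(event.center_time * fs) - center
        sig[a : a + waveform.size] += waveform
        truths.append((a + on, a + off))
    return sig, truths


class TestDetectCandidates:
    def test_zero_signal_gives_no_windows(self, fs):
        assert detect_candidates(np.zeros(2048), fs) == []

    def test_single_burst_gives_one_window_containing_center(self, bank, fs, rng):
        bg = gen_background(int(10 * fs), fs, 1.0, 50e-6, rng)
        fr_bg = band_decompose(bg, bank, fs)["fr"]
        amp = 10 * robust_rms(fr_bg)
        event = FREventSpec(center_time=5.0, freq=250.0, n_cycles=8, amplitude=amp)
        sig, _ = embed([event], fs, 10.0, bg)
        fr = band_decompose(sig, bank, fs)["fr"]
        windows = detect_candidates(fr, fs, k=3.0)
        assert len(windows) == 1
        assert windows[0].start <= int(5.0 * fs) < windows[0].end

    def test_two_separated_bursts_give_two_windows(self, bank, fs, rng):
        bg = gen_background(int(10 * fs), fs, 1.0, 50e-6, rng)
        fr_bg = band_decompose(bg, bank, fs)["fr"]
        amp = 10 * robust_rms(fr_bg)
        events = [
            FREventSpec(center_time=c, freq=250.0, n_cycles=8, amplitude=amp)
            for c in (4.75, 5.25)
        ]
        sig, _ = embed(events, fs, 10.0, bg)
        windows = detect_candidates(band_decompose(sig, bank, fs)["fr"], fs, k=3.0)
        assert len(windows) == 2
        assert windows[0].end <= windows[1].start


class TestSegmentEvent:
    def test_single_burst_onset_offset_near_half_maximum(self, bank, fs):
        event = FREventSpec(center_time=0.5, freq=300.0, n_cycles=12, amplitude=1.0)
        sig, truths = embed([event], fs, 1.0)
        fr = band_decompose(sig, bank, fs)["fr"]
        spec = compute_spectrogram(fr, fs)
        seg = segment_event(
            spec, CandidateWindow("0", int(0.35 * fs), int(0.65 * fs)), fs
        )
        on_true, off_true = truths[0]
        assert abs(seg.onset - on_true) / fs <= 0.010
        assert abs(seg.offset - off_true) / fs <= 0.010
        assert abs(seg.peak_freq - 300.0) <= 10.0

    def test_two_bursts_selects_higher_energy_basin(self, bank, fs):
        strong = FREventSpec(center_time=0.9, freq=300.0, n_cycles=8, amplitude=1.0)
        weak = FREventSpec(center_time=1.1, freq=420.0, n_cycles=8, amplitude=0.5)
        sig, truths = embed([strong, weak], fs, 2.0)
        fr = band_decompose(sig, bank, fs)["fr"]
        spec = compute_spectrogram(fr, fs)
        seg = segment_event(
            spec, CandidateWindow("0", int(0.7 * fs), int(1.3 * fs)), fs
        )
        assert abs(seg.peak_freq - 300.0) <= 15.0
        assert abs(seg.peak_time - 0.9) <= 0.02
        # offset stays clear of the weaker burst
        assert seg.offset < int(1.05 * fs)

    def test_all_zero_window_raises(self, fs):
        spec = compute_spectrogram(np.zeros(1024), fs)
        with pytest.raises(NoEventError):
            segment_event(spec, CandidateWindow("0", 100, 600), fs)


class TestValidateEvent:
    def _setup(self, fs, bank, n_cycles, amp_factor=3.0, rng_seed=9):
        rng = np.random.default_rng(rng_seed)
        bg = gen_background(int(4 * fs), fs, 1.0, 50e-6, rng)
        decomp = band_decompose(bg, bank, fs)
        bg_rms = robust_rms(decomp["background"])
        event = FREventSpec(
            center_time=2.0, freq=250.0, n_cycles=n_cycles, amplitude=amp_factor * bg_rms
        )
        sig, truths = embed([event], fs, 4.0, bg)
        d = band_decompose(sig, bank, fs)
        seg = SegmentedFR(onset=truths[0][0], offset=truths[0][1], peak_freq=250.0,
                          peak_time=2.0)
        return seg, d

    def test_four_cycle_event_above_background_is_valid(self, bank, fs):
        seg, d = self._setup(fs, bank, n_cycles=6)
        v = validate_event(seg, d["fr"], d["ripple"], d["background"], fs)
        assert v.n_oscillations >= 4
        assert v.amplitude_ratio >= 2.0
        assert not v.is_harmonic
        assert v.valid

    def test_too_few_oscillations_invalid(self, bank, fs):
        # a 3-cycle burst cannot satisfy the four-oscillation criterion
        rng = np.random.default_rng(9)
        bg = gen_background(int(4 * fs), fs, 1.0, 50e-6, rng)
        decomp = band_decompose(bg, bank, fs)
        bg_rms = robust_rms(decomp["background"])
        waveform_t = np.arange(-128, 129) / fs
        env = np.exp(-(waveform_t**2) / (2 * (3.0 / 250.0 / 2.355) ** 2))
        burst = 3.0 * bg_rms * env * np.cos(2 * np.pi * 250.0 * waveform_t)
        sig = bg.copy()
        a = int(2.0 * fs) - 128
        sig[a : a + burst.size] += burst
        d = band_decompose(sig, bank, fs)
        half = np.nonzero(env >= 0.5)[0]
        seg = SegmentedFR(onset=a + half[0], offset=a + half[-1] + 1,
                          peak_freq=250.0, peak_time=2.0)
        v = validate_event(seg, d["fr"], d["ripple"], d["background"], fs)
        assert v.n_oscillations < 4
        assert not v.valid

    def test_low_amplitude_event_invalid(self, bank, fs):
        seg, d = self._setup(fs, bank, n_cycles=6, amp_factor=0.5)
        v = validate_event(seg, d["fr"], d["ripple"], d["background"], fs)
        assert v.amplitude_ratio < 2.0
        assert not v.valid

    def test_harmonic_of_ripple_rejected(self, bank, fs):
        # strong 150 Hz ripple with a weaker 300 Hz harmonic
        t = np.arange(int(4 * fs)) / fs
        win = np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))
        sig = 1.0 * win * np.sin(2 * np.pi * 150.0 * t)
        sig += 0.3 * win * np.sin(2 * np.pi * 300.0 * t)
        d = band_decompose(sig, bank, fs)
        a, b = int(1.97 * fs), int(2.03 * fs)
        seg = SegmentedFR(onset=a, offset=b, peak_freq=300.0, peak_time=2.0)
        v = validate_event(seg, d["fr"], d["ripple"], d["background"], fs)
        assert v.is_harmonic
        assert not v.valid

    def test_amplitude_scaling_never_invalidates(self, bank, fs):
        seg, d = self._setup(fs, bank, n_cycles=6)
        base = validate_event(seg, d["fr"], d["ripple"], d["background"], fs)
        assert base.valid
        for scale in (2.0, 5.0, 20.0):
            v = validate_event(
                seg, scale * d["fr"], scale * d["ripple"], d["background"], fs
            )
            assert v.valid

    def test_degenerate_segment_invalid(self, bank, fs):
        seg = SegmentedFR(onset=10, offset=12, peak_freq=300.0, peak_time=0.0)
        x = np.zeros(100)
        v = validate_event(seg, x, x, x, fs)
        assert not v.valid

    def test_validation_flag_consistency_enforced(self):
        with pytest.raises(ValueError):
            FRValidation(n_oscillations=5, amplitude_ratio=3.0, is_harmonic=False,
                         valid=False)


class TestEventEnergy:
    def test_zero_and_constant_signals(self):
        assert event_energy(np.zeros(100), 0, 100) == 0.0
        assert event_energy(np.ones(100), 0, 100) == pytest.approx(100.0)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(500)
        assert event_energy(2 * x, 50, 400) == pytest.approx(
            4 * event_energy(x, 50, 400), rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        bounds=st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).map(sorted),
        seed=st.integers(0, 2**16),
    )
    def test_additivity_over_adjacent_intervals(self, bounds, seed):
        a, b, c = bounds
        if not a < b < c:
            return
        x = np.random.default_rng(seed).standard_normal(200)
        assert event_energy(x, a, b) + event_energy(x, b, c) == pytest.approx(
            event_energy(x, a, c), rel=1e-9
        )

    def test_bad_indices_rejected(self):
        x = np.zeros(10)
        for onset, offset in [(-1, 5), (5, 5), (5, 11), (7, 3)]:
            with pytest.raises(ValueError):
                event_energy(x, onset, offset)


class TestCompareChannels:
    def _records(self, energies, channel):
        return [
            EnergyRecord(event_id=f"ev{i}", channel=channel, energy_fr=e,
                         energy_background=1.0)
            for i, e in enumerate(energies)
        ]

    def test_identical_records_null_result(self):
        e = [1.0, 2.0, 3.0]
        comp = compare_channels(self._records(e, "a"), self._records(e, "b"))
        assert comp.median_diff_db == 0.0
        assert comp.t_statistic == 0.0
        assert comp.p_one_tailed == 0.5

    def test_fourfold_energy_is_six_db(self):
        e = [1.0, 2.0, 5.0]
        comp = compare_channels(
            self._records(e, "a"), self._records([4 * x for x in e], "b")
        )
        assert comp.median_diff_db == pytest.approx(10 * math.log10(4), rel=1e-9)

    def test_six_db_difference_with_jitter_is_significant(self, rng):
        # 55 paired events with a true 6 dB log-energy difference, 1 dB jitter
        n = 55
        log_e_a = rng.uniform(-1, 1, n)
        diff_db = 6.0 + 1.0 * rng.standard_normal(n)
        log_e_b = log_e_a + diff_db / 10.0
        comp = compare_channels(
            self._records(list(10.0**log_e_a), "a"),
            self._records(list(10.0**log_e_b), "b"),
        )
        assert comp.p_one_tailed < 1e-5
        assert comp.median_diff_db == pytest.approx(6.0, abs=1.0)

    def test_too_few_or_mismatched_events_rejected(self):
        with pytest.raises(ValueError):
            compare_channels(self._records([1.0], "a"), self._records([1.0], "b"))
        bad_b = self._records([1.0, 2.0], "b")
        bad_b[0] = EnergyRecord("other", "b", 1.0, 1.0)
        with pytest.raises(ValueError):
            compare_channels(self._records([1.0, 2.0], "a"), bad_b)


def test_robust_rms_matches_mad_definition(rng):
    x = rng.standard_normal(10000)
    expected = 1.4826 * np.median(np.abs(x - np.median(x)))
    assert robust_rms(x) == pytest.approx(expected, rel=1e-12)
    # close to the ordinary RMS for Gaussian data
    assert robust_rms(x) == pytest.approx(np.std(x), rel=0.05)
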