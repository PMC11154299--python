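"""File formats: EIS CSV, recordings (raw float32 + JSON sidecar, EDF
read-only via mne), event tables and comparison reports."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .circuits import ImpedanceSpectrum
from .events import DayComparison, EnergyRecord, FRValidation, SegmentedFR
from .synth import GroundTruth, Recording

__all__ = [
    "FormatError",
    "read_eis",
    "write_eis",
    "read_recording",
    "write_recording",
    "write_event_table",
    "read_event_table",
    "write_comparison",
    "write_ground_truth",
]

Dialect = Literal["rect", "polar"]

RECT_COLUMNS = ["freq_hz", "z_real_ohm", "z_imag_ohm"]
POLAR_COLUMNS = ["freq_hz", "z_mod_ohm", "z_phase_deg"]

EVENT_COLUMNS = [
    "event_id",
    "channel",
    "onset_s",
    "offset_s",
    "peak_freq_hz",
    "n_oscillations",
    "amplitude_ratio",
    "valid",
    "energy_fr",
    "energy_background",
    "ratio_db",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def write_eis(spectrum: ImpedanceSpectrum, path: Path | str, dialect: Dialect = "rect") -> None:
    path = Path(path)
    z = spectrum.impedances
    if dialect == "rect":
        df = pd.DataFrame(
            {"freq_hz": spectrum.frequencies, "z_real_ohm": z.real, "z_imag_ohm": z.imag}
        )
    elif dialect == "polar":
        df = pd.DataFrame(
            {
                "freq_hz": spectrum.frequencies,
                "z_mod_ohm": np.abs(z),
                "z_phase_deg": np.degrees(np.angle(z)),
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, float_format="%.12g")


def read_eis(path: Path | str, dialect: Dialect = "rect") -> ImpedanceSpectrum:
    """Read an EIS CSV and canonicalize (ascending frequency, complex Z)."""
    path = Path(path)
    expected = RECT_COLUMNS if dialect == "rect" else POLAR_COLUMNS
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: header must be {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if any(not math.isfinite(float(v)) for v in row):
            raise FormatError(f"{path}: malformed row at line {i}")
    if dialect == "rect":
        z = df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy()
    else:
        phase = np.radians(df["z_phase_deg"].to_numpy())
        z = df["z_mod_ohm"].to_numpy() * np.exp(1j * phase)
    f = df["freq_hz"].to_numpy(dtype=float)
    order = np.argsort(f, kind="stable")
    return ImpedanceSpectrum(f[order], z[order])


def write_recording(recording: Recording, stem: Path | str) -> tuple[Path, Path]:
    """Write a recording as little-endian float32 ``<stem>.bin`` plus a
    JSON sidecar ``<stem>.json`` (fs_hz, n_channels, channel_names)."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    recording.data.astype("<f4").tofile(bin_path)
    sidecar = {
        "fs_hz": recording.fs,
        "n_channels": recording.data.shape[0],
        "channel_names": list(recording.channel_names),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return bin_path, json_path


def _read_raw(bin_path: Path) -> Recording:
    json_path = bin_path.with_suffix(".json")
    if not json_path.exists():
        raise FormatError(f"missing sidecar {json_path}")
    try:
        sidecar = json.loads(json_path.read_text())
        fs = float(sidecar["fs_hz"])
        n_ch = int(sidecar["n_channels"])
        names = tuple(str(c) for c in sidecar["channel_names"])
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad sidecar {json_path}: {exc}") from exc
    if len(names) != n_ch:
        raise FormatError(f"{json_path}: channel_names length != n_channels")
    flat = np.fromfile(bin_path, dtype="<f4")
    if n_ch == 0 or flat.size % n_ch:
        raise FormatError(f"{bin_path}: size not divisible by n_channels={n_ch}")
    return Recording(fs=fs, data=flat.reshape(n_ch, -1).astype(float), channel_names=names)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    return Recording(fs=fs, data=raw.get_data(), channel_names=tuple(raw.ch_names))


def read_recording(path: Path | str) -> Recording:
    """Read a recording from ``.edf`` or raw ``.bin`` + ``.json`` sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix == ".json":
        path = path.with_suffix(".bin")
    if not path.exists():
        raise FormatError(f"no such recording {path}")
    return _read_raw(path)


def write_event_table(
    rows: list[dict],
    path: Path | str,
) -> None:
    """Write the per-event CSV table (one row per event per channel)."""
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    for col in ("onset_s", "offset_s"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_event_table(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(f"{path}: unexpected event-table header")
    return df


def event_row(
    event_id: str,
    channel: str,
    segment: SegmentedFR,
    validation: FRValidation,
    record: EnergyRecord,
    fs: float,
) -> dict:
    return {
        "event_id": event_id,
        "channel": channel,
        "onset_s": segment.onset / fs,
        "offset_s": segment.offset / fs,
        "peak_freq_hz": segment.peak_freq,
        "n_oscillations": validation.n_oscillations,
        "amplitude_ratio": validation.amplitude_ratio,
        "valid": validation.valid,
        "energy_fr": record.energy_fr,
        "energy_background": record.energy_background,
        "ratio_db": record.ratio_db,
    }


def write_comparison(comparisons: list[DayComparison], path: Path | str, meta: dict | None = None) -> None:
    payload = {
        "meta": meta or {},
        "days": [
            {
                "day": c.day,
                "median_diff_db": c.median_diff_db,
                "t_statistic": c.t_statistic,
                "p_one_tailed": c.p_one_tailed,
                "n_events": c.n_events,
            }
            for c in comparisons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_ground_truth(truth: GroundTruth, path: Path | str, channel_names: tuple[str, ...]) -> None:
    rows = []
    for ev in truth.events:
        row = {
            "event_id": ev.event_id,
            "onset_s": f"{ev.onset_s:.6f}",
            "offset_s": f"{ev.offset_s:.6f}",
            "freq_hz": ev.freq,
            "amplitude": ev.amplitude,
        }
        for name in channel_names:
            row[f"{name}_gain_db"] = ev.channel_gain_db.get(name, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
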