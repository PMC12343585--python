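"""Epoch-level EEG band power.

Continuous multichannel EEG is cut into reading epochs at ROWS (epoch start)
and ROWE (epoch end) event markers, each epoch's power spectral density is
estimated per channel with Welch's method (Hanning window, 50% overlap,
segment length tied to epoch duration), the PSD is integrated over the five
canonical frequency bands with the trapezoidal rule, and per-band powers are
averaged over channels — one row of five band powers per epoch.

The consumed EEG is assumed already preprocessed (filtered, downsampled,
bad channels excluded upstream); no re-referencing or artifact rejection is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = ["BANDS", "Recording", "EventTable", "EpochSignal", "BandPowerRow",
           "extract_epochs", "welch_psd", "band_power", "epoch_band_row",
           "compute_band_power_table", "EpochingError"]

logger = logging.getLogger(__name__)

#: Canonical frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)


class EpochingError(ValueError):
    """Malformed ROWS/ROWE event structure."""


@dataclass
class Recording:
    """Continuous preprocessed EEG: channels × samples."""

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    participant_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if np.isnan(self.data).any():
            raise ValueError("NaNs in EEG data after load")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def drop_channels(self, excluded: list[str]) -> "Recording":
        keep = [i for i, ch in enumerate(self.channel_names) if ch not in set(excluded)]
        if not keep:
            raise ValueError("channel exclusion removed every channel")
        return Recording(self.data[keep], self.sfreq,
                         [self.channel_names[i] for i in keep],
                         self.participant_id, self.run_id)


@dataclass
class EventTable:
    """Rows of (sample_index, label in {ROWS, ROWE}, unit_id)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sample_index", "label", "unit_id"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        bad = set(self.table["label"]) - {"ROWS", "ROWE"}
        if bad:
            raise EpochingError(f"unknown event labels: {sorted(bad)}")
        idx = self.table["sample_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            k = int(np.argmax(np.diff(idx) <= 0))
            raise EpochingError(
                "event sample indices not strictly increasing: "
                f"row {k + 1} (unit {self.table['unit_id'].iloc[k + 1]!r}, "
                f"sample {idx[k + 1]}) follows sample {idx[k]}")


@dataclass
class EpochSignal:
    """One reading epoch: channels × samples slice between ROWS and ROWE."""

    unit_id: str
    data: np.ndarray
    sfreq: float

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sfreq


@dataclass
class BandPowerRow:
    unit_id: str
    participant_id: str
    run_id: str
    duration_s: float
    powers: dict[str, float] = field(default_factory=dict)


def extract_epochs(rec: Recording, events: EventTable,
                   min_duration_s: float = 0.5) -> list[EpochSignal]:
    """One epoch per ROWS/ROWE pair; samples taken half-open [start, end).

    Epochs shorter than ``min_duration_s`` (the minimum Welch window) are
    dropped with a logged count.  Unmatched or interleaved markers raise
    :class:`EpochingError` naming the offending unit_ids.
    """
    df = events.table
    epochs: list[EpochSignal] = []
    open_unit: tuple[str, int] | None = None
    problems: list[str] = []
    n_short = 0
    for rec_row in df.itertuples(index=False):
        s, label, uid = int(rec_row.sample_index), rec_row.label, str(rec_row.unit_id)
        if label == "ROWS":
            if open_unit is not None:
                problems.append(f"ROWS for {uid!r} while {open_unit[0]!r} still open")
                continue
            if s >= rec.n_samples:
                problems.append(f"ROWS for {uid!r} at sample {s} beyond recording")
                continue
            open_unit = (uid, s)
        else:  # ROWE
            if open_unit is None or open_unit[0] != uid:
                problems.append(f"ROWE for {uid!r} without matching ROWS")
                open_unit = None
                continue
            start = open_unit[1]
            end = min(s, rec.n_samples)
            open_unit = None
            seg = rec.data[:, start:end]
            if seg.shape[1] / rec.sfreq < min_duration_s:
                n_short += 1
                continue
            epochs.append(EpochSignal(unit_id=uid, data=seg, sfreq=rec.sfreq))
    if open_unit is not None:
        problems.append(f"ROWS for {open_unit[0]!r} never closed by ROWE")
    if problems:
        raise EpochingError("malformed event structure: " + "; ".join(problems))
    if n_short:
        logger.info("dropped %d epochs shorter than %.2f s", n_short, min_duration_s)
    return epochs


def welch_psd(ep: EpochSignal, win_min_s: float = 0.5, win_max_s: float = 1.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch PSD with a duration-adaptive segment length.

    The segment length in seconds is ``clamp(duration, win_min_s, win_max_s)``:
    epochs shorter than the maximum window use one full-epoch segment (never
    below the minimum), longer epochs are averaged over ``win_max_s`` segments
    overlapping by ``overlap``.  Hanning window, constant detrend, one-sided
    density.  Returns (freqs, psd of shape (n_channels, n_freqs)).
    """
    dur = ep.duration_s
    if dur < win_min_s:
        raise ValueError(
            f"epoch {ep.unit_id!r} ({dur:.3f} s) shorter than the minimum "
            f"Welch window {win_min_s} s")
    seg_s = min(max(dur, win_min_s), win_max_s)
    nperseg = min(int(round(seg_s * ep.sfreq)), ep.data.shape[1])
    noverlap = int(nperseg * overlap)
    freqs, psd = sps.welch(ep.data, fs=ep.sfreq, window="hann",
                           nperseg=nperseg, noverlap=noverlap,
                           detrend="constant", scaling="density", axis=-1)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray,
               bands: dict[str, tuple[float, float]] = BANDS) -> pd.DataFrame:
    """Trapezoidal integral of the PSD over each band, per channel.

    Grid frequencies equal to a shared band edge are included in both
    adjacent bands (inclusive masks on the PSD grid).
    """
    freqs = np.asarray(freqs)
    psd = np.atleast_2d(psd)
    nyq = freqs[-1]
    out = {}
    for name, (lo, hi) in bands.items():
        if hi > nyq + 1e-9:
            raise ValueError(f"band {name!r} upper edge {hi} Hz beyond Nyquist {nyq} Hz")
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"band {name!r}: fewer than 2 PSD grid points in [{lo}, {hi}] Hz; "
                "frequency resolution too coarse")
        out[name] = np.trapezoid(psd[:, mask], freqs[mask], axis=-1)
    return pd.DataFrame(out)


def epoch_band_row(ep: EpochSignal, bands: dict[str, tuple[float, float]] = BANDS,
                   participant_id: str = "", run_id: str = "",
                   win_min_s: float = 0.5, win_max_s: float = 1.0,
                   overlap: float = 0.5) -> BandPowerRow:
    """Channel-averaged band powers of one epoch."""
    freqs, psd = welch_psd(ep, win_min_s=win_min_s, win_max_s=win_max_s,
                           overlap=overlap)
    per_channel = band_power(freqs, psd, bands)
    powers = {b: float(per_channel[b].mean()) for b in bands}
    return BandPowerRow(unit_id=ep.unit_id, participant_id=participant_id,
                        run_id=run_id, duration_s=ep.duration_s, powers=powers)


def compute_band_power_table(rec: Recording, events: EventTable,
                             bands: dict[str, tuple[float, float]] = BANDS,
                             win_min_s: float = 0.5, win_max_s: float = 1.0,
                             overlap: float = 0.5) -> pd.DataFrame:
    """Band-power table for a recording: one row per ROWS/ROWE epoch."""
    rows = []
    for ep in extract_epochs(rec, events, min_duration_s=win_min_s):
        row = epoch_band_row(ep, bands, participant_id=rec.participant_id,
                             run_id=rec.run_id, win_min_s=win_min_s,
                             win_max_s=win_max_s, overlap=overlap)
        rows.append({"unit_id": row.unit_id, "participant_id": row.participant_id,
                     "run_id": row.run_id, "duration_s": row.duration_s,
                     **row.powers})
    cols = ["unit_id", "participant_id", "run_id", "duration_s", *bands]
    return pd.DataFrame(rows, columns=cols)
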