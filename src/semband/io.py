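"""File formats and configuration.

EEG travels as a ``.npz`` archive (data, sfreq, channel_names, ids) or as an
EDF file (read through MNE when available); events and units are UTF-8 TSV;
embeddings live in a per-material ``.npz`` archive keyed by unit_id; all
outputs are plain CSV with '.' decimal separators regardless of locale.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg import EventTable, Recording

__all__ = ["read_eeg", "write_eeg_npz", "read_events_tsv", "read_units_tsv",
           "read_embedding_archive", "write_embedding_archive",
           "load_config", "derive_seed", "CONFIG_KEYS"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from one master seed."""
    h = hashlib.blake2b(f"{int(master_seed)}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") & 0x7FFFFFFF


def write_eeg_npz(path: str | Path, data: np.ndarray, sfreq: float,
                  channel_names: list[str], participant_id: str = "",
                  run_id: str = "") -> Path:
    path = Path(path)
    np.savez(path, data=np.asarray(data, dtype=float), sfreq=float(sfreq),
             channel_names=np.asarray(channel_names, dtype="U"),
             participant_id=str(participant_id), run_id=str(run_id))
    return path


def _read_eeg_npz(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(data=z["data"], sfreq=float(z["sfreq"]),
                         channel_names=[str(c) for c in z["channel_names"]],
                         participant_id=str(z["participant_id"]),
                         run_id=str(z["run_id"]))


def _read_eeg_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install semband[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(data=raw.get_data(), sfreq=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def read_eeg(path: str | Path, excluded_channels: list[str] | None = None,
             participant_id: str | None = None,
             run_id: str | None = None) -> Recording:
    """Load continuous EEG from a .npz archive or an EDF file.

    ``excluded_channels`` are dropped after load (montage-specific exclusion
    lists are configuration, not code).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EEG file not found: {path}")
    if path.suffix.lower() == ".edf":
        rec = _read_eeg_edf(path)
    elif path.suffix.lower() == ".npz":
        rec = _read_eeg_npz(path)
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r} (use .npz or .edf)")
    if participant_id is not None:
        rec.participant_id = participant_id
    if run_id is not None:
        rec.run_id = run_id
    if excluded_channels:
        rec = rec.drop_channels(excluded_channels)
    return rec


def read_events_tsv(path: str | Path) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str, "label": str})
    df["sample_index"] = df["sample_index"].astype(int)
    return EventTable(df)


def read_units_tsv(path: str | Path) -> pd.DataFrame:
    """Units table: unit_id, text (+ optional material, run_id columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"units file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"unit_id", "text"} - set(df.columns)
    if missing:
        raise ValueError(f"units TSV missing columns: {sorted(missing)}")
    return df


def write_embedding_archive(path: str | Path,
                            archive: dict[str, dict[str, np.ndarray]]) -> Path:
    """One .npz per material: per-unit token list, token matrix, unit vector."""
    payload = {}
    for uid, entry in archive.items():
        payload[f"{uid}::tokens"] = np.asarray(entry["tokens"], dtype="U")
        payload[f"{uid}::M"] = np.asarray(entry["M"], dtype=float)
        payload[f"{uid}::unit_vector"] = np.asarray(entry["unit_vector"], dtype=float)
    np.savez(Path(path), **payload)
    return Path(path)


def read_embedding_archive(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding archive not found: {path}")
    archive: dict[str, dict[str, np.ndarray]] = {}
    with np.load(path, allow_pickle=False) as z:
        for key in z.files:
            uid, field = key.rsplit("::", 1)
            entry = archive.setdefault(uid, {})
            entry[field] = [str(t) for t in z[key]] if field == "tokens" else z[key]
    return archive


#: Recognised configuration keys (unknown keys are rejected).
CONFIG_KEYS: dict[str, set[str]] = {
    "paths": {"eeg_dir", "events_dir", "units", "embeddings", "outdir"},
    "eeg_power": {"win_min_s", "win_max_s", "overlap", "excluded_channels",
                  "bands"},
    "features": {"d", "encoder", "pca_mode"},
    "surprisal": {"log_base", "floor", "vocab_size", "lm_sharpness"},
    "stats": {"bands", "outlier_sd", "interactions", "material_col",
              "bh_correction", "zscore_features", "log_power"},
    "simulate": {"n_participants", "n_runs", "n_units_per_run", "d",
                 "token_count_range", "step_scale_log_mean", "step_scale_log_sd",
                 "unit_vector_noise", "beta", "effect_band", "participant_sd",
                 "run_sd", "residual_sd", "band_targets", "sfreq", "n_channels",
                 "epoch_duration_range", "gap_duration_s", "vocab_size",
                 "lm_sharpness", "power_floor"},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config, rejecting unknown sections or keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for section, value in cfg.items():
        if section == "seed":
            continue
        if section not in CONFIG_KEYS:
            raise ValueError(f"unknown config section {section!r}")
        unknown = set(value or {}) - CONFIG_KEYS[section]
        if unknown:
            raise ValueError(f"unknown keys in config section {section!r}: "
                             f"{sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg
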