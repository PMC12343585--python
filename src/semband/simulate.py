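"""Synthetic study generator with known ground truth.

Emulates the structure of a naturalistic-reading EEG study — participants ×
runs × reading units — end to end:

* per-unit token embeddings as Gaussian random walks (adjacent-step magnitude
  controllable per unit), from which the geometry features are computed with
  the same code used on real embeddings;
* per-epoch band powers obeying the linear mixed model the linkage stage
  assumes: baseline + Σ β·feature + participant intercept + run intercept +
  residual, with the effect planted on one named band and the remaining bands
  pure noise;
* band-limited multichannel EEG time series realizing those target powers
  (band-passed white noise rescaled to exact variance), concatenated with
  inter-epoch gaps and ROWS/ROWE markers.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg import BANDS, BAND_NAMES
from .encoders import HashMaskedLM
from .features import (EmbeddingMatrix, UnitVector, features_from_embeddings,
                       FEATURE_TABLE_COLUMNS)
from .surprisal import cumulative_surprisal

__all__ = ["SimConfig", "GroundTruth", "gen_embedding_walk", "gen_power_table",
           "synthesize_eeg", "synthesize_run_recording", "simulate_dataset"]

#: Baseline channel-averaged band powers (arbitrary µV²-like units),
#: descending with frequency as in resting spectra.
DEFAULT_BAND_TARGETS: dict[str, float] = {
    "delta": 20.0, "theta": 12.0, "alpha": 8.0, "beta": 6.0, "gamma": 5.0,
}

#: Planted fixed effect: gamma power decreases with cumulative surprisal.
#: Surprisal is the one feature whose partial effect stays identifiable under
#: the near-singular collinearity the geometry features exhibit (adjacent-step
#: totals correlate at r > 0.999, as with real embeddings); its design partial
#: SE at the default 10 × 10 × 30 layout is ≈ 0.003, so −0.022 puts the
#: expected Wald |z| near 7 before, and ≈ 6 after, the EEG round trip, while
#: shifting gamma power by well under its baseline.
DEFAULT_BETA: dict[str, float] = {"cumulative_surprisal": -0.022}


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset."""

    seed: int = 0
    n_participants: int = 10
    n_runs: int = 10
    n_units_per_run: int = 30
    d: int = 768
    token_count_range: tuple[int, int] = (3, 10)
    step_scale_log_mean: float = 0.0       # per-unit step scale ~ lognormal
    step_scale_log_sd: float = 0.4
    unit_vector_noise: float = 0.5         # direct unit encoding = mean + noise·g
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    effect_band: str = "gamma"
    participant_sd: float = 1.0
    run_sd: float = 0.5
    residual_sd: float = 1.0
    band_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_TARGETS))
    sfreq: float = 256.0
    n_channels: int = 2
    epoch_duration_range: tuple[float, float] = (1.0, 4.0)
    gap_duration_s: float = 0.25
    vocab_size: int = 100
    lm_sharpness: float = 2.0
    power_floor: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_runs, self.n_units_per_run) < 1:
            raise ValueError("all counts must be >= 1")
        if min(self.participant_sd, self.run_sd, self.residual_sd) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.effect_band not in self.band_targets:
            raise ValueError(f"effect_band {self.effect_band!r} not a known band")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    beta: dict[str, float]
    effect_band: str
    baseline: dict[str, float]
    participant_intercepts: pd.DataFrame   # participant_id × band
    run_intercepts: pd.DataFrame           # run_id × band
    unit_features: pd.DataFrame            # one row per unit_id
    target_powers: pd.DataFrame            # per (participant, run, unit) × band
    embedding_archive: dict = field(default_factory=dict)  # unit_id -> arrays


def gen_embedding_walk(n_tokens: int, d: int, step_scale: float,
                       seed: int | np.random.Generator,
                       unit_id: str = "u0",
                       vocab_size: int = 100) -> EmbeddingMatrix:
    """Random-walk token embeddings: row_{i+1} = row_i + step_scale · g_i.

    The start row is standard normal; steps are independent standard normal
    vectors scaled by ``step_scale``, so the expected adjacent Euclidean step
    is step_scale · E‖g‖ (the chi_d mean).  Token strings are drawn from a
    synthetic vocabulary so the masked-LM path has real inputs.
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = np.empty((n_tokens, d))
    rows[0] = rng.standard_normal(d)
    if n_tokens > 1:
        steps = step_scale * rng.standard_normal((n_tokens - 1, d))
        rows[1:] = rows[0] + np.cumsum(steps, axis=0)
    tokens = [f"w{k:03d}" for k in rng.integers(0, vocab_size, size=n_tokens)]
    return EmbeddingMatrix(unit_id=unit_id, tokens=tokens, M=rows,
                           source="token_encoder")


def _gen_unit(cfg: SimConfig, rng: np.random.Generator, unit_id: str):
    """One unit: embedding walk, direct unit vector, feature row."""
    n_tok = int(rng.integers(cfg.token_count_range[0], cfg.token_count_range[1] + 1))
    step = float(np.exp(cfg.step_scale_log_mean +
                        cfg.step_scale_log_sd * rng.standard_normal()))
    M = gen_embedding_walk(n_tok, cfg.d, step, rng, unit_id=unit_id,
                           vocab_size=cfg.vocab_size)
    v_direct = M.M.mean(axis=0) + cfg.unit_vector_noise * rng.standard_normal(cfg.d)
    uv = UnitVector(unit_id=unit_id, v=v_direct, provenance="direct_unit_encoding")
    feats = features_from_embeddings(M, uv)
    lm = HashMaskedLM(vocab_size=cfg.vocab_size, seed=cfg.seed,
                      sharpness=cfg.lm_sharpness)
    feats.cumulative_surprisal = cumulative_surprisal(
        M.tokens, lm, unit_id=unit_id).cumulative
    return M, uv, feats


def gen_power_table(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Crossed analysis table with a linear-model response on one band.

    Units are nested in runs and shared across participants (all participants
    read the same text), so features repeat per participant while intercepts
    and residuals differ — the crossed random-effects layout the linkage
    model assumes.  The effect band's power is
    ``baseline + Σ β·feature + b_participant + b_run + ε``; other bands get
    intercepts and noise only.  Powers are floored at a small positive value.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_units, rng_re, rng_eps = [np.random.default_rng(s) for s in ss.spawn(3)]

    unknown = set(cfg.beta) - set(FEATURE_TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"beta refers to unknown features: {sorted(unknown)}")

    unit_rows, archive = [], {}
    for r in range(cfg.n_runs):
        run_id = f"run{r:02d}"
        for u in range(cfg.n_units_per_run):
            unit_id = f"{run_id}_u{u:03d}"
            M, uv, feats = _gen_unit(cfg, rng_units, unit_id)
            row = feats.as_dict()
            row["run_id"] = run_id
            unit_rows.append(row)
            archive[unit_id] = {"tokens": M.tokens, "M": M.M, "unit_vector": uv.v}
    units = pd.DataFrame(unit_rows)

    participants = [f"p{i:02d}" for i in range(cfg.n_participants)]
    runs = sorted(units["run_id"].unique())
    b_part = pd.DataFrame(
        cfg.participant_sd * rng_re.standard_normal((cfg.n_participants, len(BANDS))),
        index=participants, columns=list(BAND_NAMES))
    b_run = pd.DataFrame(
        cfg.run_sd * rng_re.standard_normal((len(runs), len(BANDS))),
        index=runs, columns=list(BAND_NAMES))

    feat_effect = np.zeros(len(units))
    for f, b in cfg.beta.items():
        feat_effect = feat_effect + b * units[f].to_numpy(dtype=float)

    nU = len(units)
    part_idx = np.repeat(np.arange(cfg.n_participants), nU)
    run_codes = pd.Categorical(units["run_id"], categories=runs).codes
    run_idx = np.tile(run_codes, cfg.n_participants)
    powers = pd.DataFrame({
        "participant_id": np.repeat(participants, nU),
        "run_id": np.tile(units["run_id"].to_numpy(), cfg.n_participants),
        "unit_id": np.tile(units["unit_id"].to_numpy(), cfg.n_participants),
    })
    for band in BAND_NAMES:
        mu = (cfg.band_targets[band]
              + b_part[band].to_numpy()[part_idx]
              + b_run[band].to_numpy()[run_idx])
        if band == cfg.effect_band:
            mu = mu + np.tile(feat_effect, cfg.n_participants)
        eps = cfg.residual_sd * rng_eps.standard_normal(len(powers))
        powers[band] = np.maximum(mu + eps, cfg.power_floor)

    feature_cols = [c for c in FEATURE_TABLE_COLUMNS if c != "unit_id"]
    table = powers.merge(units[["unit_id", "run_id"] + feature_cols],
                         on=["unit_id", "run_id"], how="left")
    truth = GroundTruth(beta=dict(cfg.beta), effect_band=cfg.effect_band,
                        baseline=dict(cfg.band_targets),
                        participant_intercepts=b_part, run_intercepts=b_run,
                        unit_features=units,
                        target_powers=powers,
                        embedding_archive=archive)
    return table, truth


def _bandlimited_noise(n: int, band: tuple[float, float], sfreq: float,
                       rng: np.random.Generator, pad_s: float = 1.0) -> np.ndarray:
    """Unit-variance noise confined to one frequency band (zero-phase IIR)."""
    pad = int(pad_s * sfreq)
    x = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    y = sps.sosfiltfilt(sos, x)[pad:pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def synthesize_eeg(target_powers: dict[str, float], duration_s: float,
                   sfreq: float, n_channels: int,
                   seed: int | np.random.Generator,
                   bands: dict[str, tuple[float, float]] = BANDS) -> np.ndarray:
    """EEG-like epoch whose per-band variances equal the target band powers.

    Each channel is an independent sum over bands of band-passed white noise
    rescaled so its variance equals that band's target; the targets are
    common across channels.  Returns channels × samples.
    """
    if duration_s < 0.5:
        raise ValueError("epoch duration must be >= 0.5 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sfreq))
    data = np.zeros((n_channels, n))
    for ch in range(n_channels):
        for band_name, edges in bands.items():
            target = float(target_powers[band_name])
            if target <= 0:
                continue
            comp = _bandlimited_noise(n, edges, sfreq, rng)
            data[ch] += np.sqrt(target) * comp
    return data


def synthesize_run_recording(power_rows: pd.DataFrame, cfg: SimConfig,
                             rng: np.random.Generator
                             ) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """Continuous recording for one (participant, run): epochs + gaps + markers.

    Returns (data channels × samples, events table, per-unit durations).
    Epoch durations are drawn uniformly from ``cfg.epoch_duration_range`` to
    exercise the duration-adaptive Welch window across its range.  For speed,
    each band's noise is generated as one continuous filtered stream per
    channel; every epoch slice is then rescaled so its per-channel variance
    equals that epoch's target band power (the same measurement model as
    :func:`synthesize_eeg`, one filter pass per band instead of per epoch).
    """
    gap = int(round(cfg.gap_duration_s * cfg.sfreq))
    lo, hi = cfg.epoch_duration_range
    events, durations, spans = [], {}, []
    cursor = gap
    for row in power_rows.itertuples(index=False):
        n = int(round(float(rng.uniform(lo, hi)) * cfg.sfreq))
        events.append({"sample_index": cursor, "label": "ROWS",
                       "unit_id": row.unit_id})
        events.append({"sample_index": cursor + n, "label": "ROWE",
                       "unit_id": row.unit_id})
        spans.append((cursor, cursor + n,
                      {b: float(getattr(row, b)) for b in BAND_NAMES}))
        durations[row.unit_id] = n / cfg.sfreq
        cursor += n + gap
    total = cursor
    data = np.zeros((cfg.n_channels, total))
    pad = int(cfg.sfreq)  # discard filter transients at the stream edges
    for band_name, edges in BANDS.items():
        sos = sps.butter(4, edges, btype="bandpass", fs=cfg.sfreq, output="sos")
        noise = rng.standard_normal((cfg.n_channels, total + 2 * pad))
        stream = sps.sosfiltfilt(sos, noise, axis=-1)[:, pad:pad + total]
        for start, end, targets in spans:
            target = targets[band_name]
            if target <= 0:
                continue
            seg = stream[:, start:end]
            sd = seg.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            data[:, start:end] += np.sqrt(target) * seg / sd
    return data, pd.DataFrame(events), pd.Series(durations, name="duration_s")


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study to ``outdir``.

    Files: units.tsv, embeddings.npz, features_truth.csv, ground_truth.json,
    and per-(participant, run) EEG archives eeg/<p>_<run>.npz with matching
    events/<p>_<run>.tsv.  Returns the written paths.
    """
    import json

    from . import io as sbio

    outdir = Path(outdir)
    (outdir / "eeg").mkdir(parents=True, exist_ok=True)
    (outdir / "events").mkdir(parents=True, exist_ok=True)

    table, truth = gen_power_table(cfg)
    archive = truth.embedding_archive

    units = truth.unit_features[["unit_id", "run_id", "n_tokens"]].copy()
    units["material"] = "synthetic"
    texts = {uid: " ".join(archive[uid]["tokens"]) for uid in units["unit_id"]}
    units["text"] = units["unit_id"].map(texts)
    units_path = outdir / "units.tsv"
    units[["unit_id", "material", "run_id", "text"]].to_csv(
        units_path, sep="\t", index=False)

    emb_path = outdir / "embeddings.npz"
    sbio.write_embedding_archive(emb_path, archive)

    feat_path = outdir / "features_truth.csv"
    truth.unit_features[list(FEATURE_TABLE_COLUMNS)].to_csv(feat_path, index=False)

    ss = np.random.SeedSequence([cfg.seed, 2**20])  # independent of table draw
    eeg_rngs = ss.spawn(cfg.n_participants * len(truth.run_intercepts))
    written = {"units": units_path, "embeddings": emb_path, "features": feat_path}
    i = 0
    for p, psub in truth.target_powers.groupby("participant_id", sort=True):
        for r, rows in psub.groupby("run_id", sort=True):
            data, events, _ = synthesize_run_recording(
                rows, cfg, np.random.default_rng(eeg_rngs[i]))
            i += 1
            stem = f"{p}_{r}"
            eeg_path = outdir / "eeg" / f"{stem}.npz"
            sbio.write_eeg_npz(eeg_path, data, cfg.sfreq,
                               [f"ch{c:02d}" for c in range(cfg.n_channels)],
                               participant_id=str(p), run_id=str(r))
            ev_path = outdir / "events" / f"{stem}.tsv"
            events.to_csv(ev_path, sep="\t", index=False)
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({
            "beta": truth.beta,
            "effect_band": truth.effect_band,
            "baseline": truth.baseline,
            "participant_intercepts": truth.participant_intercepts.to_dict(),
            "run_intercepts": truth.run_intercepts.to_dict(),
            "config": {k: v for k, v in asdict(cfg).items()},
        }, fh, indent=1, default=str)
    written["ground_truth"] = truth_path
    return written
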