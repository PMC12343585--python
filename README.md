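# semband

**Do geometric properties of contextual embeddings track EEG band power
during naturalistic reading?** `semband` is a tested, reusable pipeline for
asking that question. It computes fourteen per-unit features from token
embedding matrices, turns marker-epoched EEG into per-epoch band powers, and
links the two with per-band linear mixed models. A synthetic-data generator
with known ground truth stands in for real recordings and live language-model
inference, so every stage is validated end to end, offline.

It is written for researchers in computational neurolinguistics / EEG signal
analysis who have (a) reading units and per-token contextual embeddings (from
any encoder) and (b) continuous preprocessed EEG with ROWS/ROWE epoch
markers.

## The model

For each reading unit *u* (a short text segment), fourteen features are
computed from its token embedding matrix `M_u ∈ R^{n×d}`:

- cumulative adjacent-token distances
  `Σ_i dist(m_i, m_{i+1})` for Euclidean, cosine (`1 − cos θ`), Manhattan and
  Chebyshev metrics;
- L2/L1/L∞ norms of the mean-of-tokens vector and of a direct unit-level
  encoding;
- convex-hull geometry of the per-unit 2-D PCA projection of the tokens:
  reading-order neighbour distance sum, hull perimeter, hull area;
- cumulative masked-LM surprisal `Σ_i −log p(token_i | rest)`.

For each epoch (unit × participant × run), channel-averaged band power is the
trapezoidal integral of the Welch PSD (Hanning window, 50% overlap, segment
length `clamp(duration, 0.5 s, 1 s)`) over delta 1–4, theta 4–8, alpha 8–13,
beta 13–30 and gamma 30–50 Hz.

The linkage is one linear mixed model per band, fitted by REML after a
2.5 SD extreme-value screen:

```
power_b = β0 + Σ_k β_k · feature_k + u_participant + v_run + ε
u ~ N(0, σ²_p),  v ~ N(0, σ²_r)   (crossed random intercepts)
```

with Wald `z = β/SE`, `p = 2(1 − Φ(|z|))`, flags at α = 0.05 and a reported
tier at p < 0.1, and no multiplicity correction by default.

## Worked example

Simulate a small study, run every stage, and fit the per-band models:

```python
import pandas as pd
from semband import (SimConfig, gen_power_table, BandPowerLinkage)

cfg = SimConfig(seed=1)              # 10 participants x 10 runs x 30 units;
                                     # plants beta = -0.022 on gamma via
                                     # cumulative surprisal
table, truth = gen_power_table(cfg)  # analysis table + ground truth
model = BandPowerLinkage(table, bands=["gamma", "theta"])
results = model.fit()
print(results.summary())
```

prints (abridged):

```
== gamma band  (n_obs=2840, excluded=160) ==
   var(participant)=1.097  var(run)=0.1904  var(residual)=0.9741
   design: cond=664, max |r|=0.99997 (total_euclidean~total_manhattan)
   * Intercept              beta=    4.8418 SE=   0.7627 z=  6.349 p=0.0000
     total_euclidean        beta=    0.0291 SE=   0.0337 z=  0.863 p=0.3881
   * total_chebyshev        beta=    0.0742 SE=   0.0277 z=  2.681 p=0.0073
   ...
   * cumulative_surprisal   beta=   -0.0192 SE=   0.0028 z= -6.767 p=0.0000
== theta band  (n_obs=2836, excluded=164) ==
   ...
     cumulative_surprisal   beta=    0.0034 SE=   0.0028 z=  1.205 p=0.2283
flags: '*' p < 0.05, '.' p < 0.1 (no correction applied)
```

Reading this output: the planted gamma effect on cumulative surprisal is
recovered (β̂ = −0.019 ± 0.003 against a true −0.022, within 2 SE) and is
absent from theta, where nothing was planted. The estimated variance
components track the generator's σ²_participant = 1 and σ²_run = 0.25. Two
cautions the output itself surfaces: the worst feature correlation is
r = 0.99997 (`total_euclidean ~ total_manhattan`) — with embedding-derived
features this collinearity is a fact of the design, so individual β
magnitudes of those features are unstable — and with 14 uncorrected tests
per band, occasional chance flags appear (here `total_chebyshev` in gamma, a
null feature; pass `bh_correction=True` for an adjusted-p column).

The same analysis runs from the shell on files:

```bash
semband simulate --out study --seed 1
semband compute-power --eeg-dir study/eeg --events-dir study/events --out power.csv
semband extract-features --units study/units.tsv --embeddings study/embeddings.npz --out features.csv
semband fit-models --features features.csv --power power.csv --out results/
# or all of the above from one YAML config:
semband pipeline --config config.yaml --out run1/
```

## Layout

- `src/semband/features.py` — embedding-geometry features
- `src/semband/surprisal.py` — masked-LM cumulative surprisal
- `src/semband/eeg.py` — epoching, Welch PSD, band powers
- `src/semband/linkage.py` — `BandPowerLinkage` / `LinkageResults` mixed models
- `src/semband/simulate.py` — ground-truthed synthetic studies
- `src/semband/encoders.py` — encoder / masked-LM protocols and mocks
- `src/semband/io.py`, `src/semband/cli.py` — formats, config, CLI
- `docs/methods.md` — full methods note (assumptions, parameters, limits)
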