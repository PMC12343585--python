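# Methods

## Scientific setting

`semband` implements a sentence-level (more precisely, *unit*-level: a short
presentation segment of text, e.g. ≤ 10 Chinese characters or one English
sentence) linkage between two measurement streams recorded during
naturalistic reading:

1. **Text-side features.** Each unit's tokens are mapped to contextual
   embedding vectors (one row per token, dimensionality `d`, default 768).
   Fourteen scalar features summarise the unit:
   - *Cumulative distances* — the sum over adjacent token pairs of the
     Euclidean, cosine, Manhattan and Chebyshev distances. Cosine distance is
     defined as `1 − u·v/(‖u‖‖v‖)` (range [0, 2]); the other three inherit
     the elementwise chain `chebyshev ≤ euclidean ≤ manhattan ≤ d·chebyshev`.
   - *Unit-vector norms* — L2, L1 and L∞ norms of two unit-level vectors:
     the columnwise mean of the token matrix (`*_tok`) and a direct
     unit-level encoding from a second, sentence-level encoder (`*_unit`).
   - *Convex-hull geometry* — the token matrix is centered and projected
     onto its own top two principal components (plain SVD, fitted per unit so
     the features are intrinsic to the unit); reported are the perimeter and
     area of the convex hull of the projected points and the sum of distances
     between consecutive tokens in reading order within that plane.
   - *Cumulative surprisal* — each position is masked in turn, a masked LM
     predicts the vocabulary distribution at that position, and
     `−log p(true token)` is summed over positions (nats by default; a
     `base=2` option yields bits; probabilities are floored at 1e-12).

2. **EEG-side band power.** Continuous preprocessed EEG is epoched at
   ROWS/ROWE markers (half-open sample intervals, 0-based). Per epoch and
   channel, the PSD is estimated by Welch's method with a Hanning window,
   constant detrend, 50% overlap and a duration-adaptive segment length
   `clamp(duration, 0.5 s, 1 s)` — epochs shorter than 1 s form a single
   full-epoch segment, longer epochs are averaged over 1 s segments. The PSD
   is integrated (trapezoidal rule, inclusive band-edge masks) over
   delta 1–4, theta 4–8, alpha 8–13, beta 13–30 and gamma 30–50 Hz, then
   averaged over channels. Epochs shorter than 0.5 s are dropped with a
   logged count. No re-referencing, filtering or artifact correction is
   performed: the input is assumed to be an already-preprocessed release.

3. **Linkage.** One linear mixed model per band,
   `power ~ 1 + 14 features + (1 | participant) + (1 | run)`,
   fitted by REML with *crossed* random intercepts (implemented in
   statsmodels as two variance components over a single all-encompassing
   group). Before each fit, rows deviating more than 2.5 sample SDs from the
   column mean in the response or any feature are excluded; moments are
   computed once on the full table, so screening is order-independent.
   Inference is Wald: `z = β/SE`, `p = 2(1 − Φ(|z|))`; effects are flagged at
   α = 0.05 (strict inequality) and additionally reported at p < 0.1.
   No multiple-comparison correction is applied by default; a
   Benjamini–Hochberg column is available behind a flag. An optional
   combined-material mode adds material and material × feature fixed effects
   and fits a reduced model without them alongside.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `d` | 768 | – | width of BERT-base-class encoders; any `d ≥ 2` works |
| bands | delta…gamma as above | Hz | canonical EEG band edges |
| `win_min_s`, `win_max_s` | 0.5, 1.0 | s | Welch segment-length clamp |
| `overlap` | 0.5 | fraction | Welch overlap |
| `outlier_sd` | 2.5 | SD | extreme-value screen threshold |
| surprisal floor | 1e-12 | prob. | keeps degenerate LMs finite |
| log base | e | – | nats; base 2 gives bits (pure rescaling of one feature) |

## The synthetic study

The generator emulates the *structure* of a naturalistic-reading EEG study
with known ground truth at every stage. Its defaults are the package's study
conditions and are used by the validation suite:

- layout 10 participants × 10 runs × 30 units (crossed: every participant
  reads the same units, so features repeat across participants while
  intercepts and residuals differ);
- token counts uniform on 3–10 per unit (short logographic reading units),
  `d = 768`;
- token embeddings are Gaussian random walks, `row_{i+1} = row_i +
  s·g_i` with standard-normal `g_i` and a per-unit step scale `s` drawn
  lognormal(0, 0.4), giving realistic spread in the distance features; the
  direct unit-level vector is the token mean plus isotropic noise (SD 0.5);
- per-epoch band powers follow the linear mixed model the linkage stage
  assumes: baseline (20/12/8/6/5 µV²-like units for delta…gamma) + Σ β·feature
  + participant intercept (SD 1.0) + run intercept (SD 0.5) + residual
  (SD 1.0), floored at 1e-6; bands other than the effect band are pure noise;
- EEG epochs are sums over bands of 4th-order Butterworth band-passed white
  noise (zero-phase, filtered as one continuous stream per run) rescaled so
  each epoch's per-channel variance equals its target band power; 2 channels,
  256 Hz, epoch durations uniform on 1–4 s (exercising the adaptive Welch
  window across its range), 0.25 s silent gaps carrying the ROWS/ROWE markers;
- mock encoders and the mock masked LM are deterministic functions of
  (seed, input): token vectors are seeded-hash normals with a contextual
  component, LM distributions are softmaxes of seeded-hash normals.

**Planted effect.** The default planted fixed effect is
`β(cumulative_surprisal) = −0.022` on gamma. The geometry features inherit
the near-singular collinearity seen with real embeddings (the Euclidean and
Manhattan totals correlate above r = 0.999 here, and the diagnostics expose
exactly this), so partial effects on those features are effectively
unidentifiable at desk scale; surprisal is the one feature with substantial
independent variation (max |r| ≈ 0.65). The magnitude was chosen from the
design alone: the feature's partial SE at the default layout is ≈ 0.003, so
−0.022 puts the expected Wald |z| near 7 in a direct fit and ≈ 6 after the
EEG round trip, while shifting gamma power by well under its baseline.

**What the generator does not emulate:** 1/f background spectra, artifacts,
eye movements, volume conduction or channel covariance, autocorrelated
residuals, semantic structure in the token walks, or a real language model's
probability estimates. Passing tests therefore demonstrate that the
*pipeline* measures what it claims (spectral calibration, estimator
correctness, type-I control, recovery of effects that are present) — not
that any particular effect exists in real recordings.

## Numerical choices and degenerate inputs

- Per-unit PCA uses an economy SVD of the centered token matrix; with fewer
  than 3 tokens or rank < 2 the missing components are zero-filled and the
  projection flagged degenerate. Hull features are invariant to component
  sign flips by construction.
- Hull degeneracies: 1 point → (0, 0, 0); 2 points at distance `delta` →
  (`delta`, `2·delta`, 0); collinear clouds → area 0 and perimeter twice the
  maximal pairwise extent (Qhull failures are caught and routed here).
- Cosine distance raises an explicit degenerate-input error on zero-norm
  rows instead of returning NaN.
- Band integration demands at least two PSD grid points per band and rejects
  bands beyond Nyquist; shared band edges are included in both neighbouring
  bands, so the five bands are exactly additive on edge-aligned grids.
- The mixed-model fit tries L-BFGS and falls back to Powell; non-convergence
  raises a structured error, as does a rank-deficient design (the aliased
  columns are named). Zero-variance screen columns are skipped with a
  warning. p-values are recomputed from `z` so the Wald identity holds
  exactly.
- All CSV output is UTF-8 with '.' decimals and deterministic row order
  (participant, run, unit); a single master seed derives per-stage seeds.

## Design choices where the procedure was genuinely open

- *Per-unit PCA* (not corpus-wide): hull features should describe the unit's
  own token cloud; a corpus-wide projection would couple every unit's
  features to the corpus composition.
- *Reading-order neighbour sum*: "distances between neighbouring points" is
  taken as consecutive tokens in reading order within the 2-D plane —
  a hull-vertex reading would duplicate the perimeter.
- *Screen columns*: the 2.5 SD rule is applied to the response and all
  feature columns of each model, with global (not per-participant) moments.
- *Crossed, not nested, random intercepts*: runs are text segments shared by
  all participants.
- *Raw feature scales* (no standardisation) and *raw power* (no log
  transform) by default, with flags for both.
- *Token/subword handling* is delegated to the encoder or LM tokenizer;
  special sequence markers are excluded from matrices and never masked.

## Known limitations

- Wald z inference carries no small-sample (Satterthwaite/Kenward-Roger)
  correction; with few participants/runs p-values are approximate.
- The extreme collinearity among the geometry features makes individual β
  magnitudes unstable in any analysis of this design (the condition number
  and worst feature correlation are reported per fit precisely because of
  this); effect *presence* on well-identified features is what the recovery
  suite validates.
- Band-limited synthesis leaks a few percent of variance across band edges
  (4th-order Butterworth rolloff), so recovered powers are multiplicatively
  attenuated by band (delta most, ≈ 10–15%); this rescales β estimates
  without affecting inference.
- The EDF reader returns volts (MNE convention) while `.npz` archives are
  unit-agnostic; band powers scale accordingly (all inference is
  scale-invariant per band).
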