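"""Linking unit features to EEG band power with linear mixed models.

The analysis table has one row per (participant, run, unit): the 14
embedding-derived features plus the five channel-averaged band powers.  For
each frequency band a linear mixed model is fitted by REML,

    power_band ~ 1 + feature_1 + ... + feature_14
                 + (1 | participant) + (1 | run)

with crossed random intercepts for participants and runs, after a one-pass
2.5-SD screen for extreme values.  Inference on the fixed effects is by Wald
z with two-sided normal p-values; the significance threshold is α = 0.05,
with effects at p < 0.1 additionally reported as marginal.  No
multiple-comparison correction is applied by default (a Benjamini–Hochberg
column is available behind a flag).

The public surface follows the model/results idiom: build a
:class:`BandPowerLinkage` from data, call :meth:`~BandPowerLinkage.fit`, and
read estimates, variance components and diagnostics off the returned
:class:`LinkageResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .eeg import BAND_NAMES
from .features import FEATURE_NAMES

__all__ = ["exclude_outliers", "fit_band_lmm", "BandPowerLinkage",
           "LinkageResults", "BandLmmResult", "ConvergenceError",
           "RankDeficiencyError"]


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


class RankDeficiencyError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


def exclude_outliers(table: pd.DataFrame, columns: list[str],
                     k: float = 2.5) -> tuple[pd.DataFrame, int]:
    """Drop rows deviating more than ``k`` sample SDs from a column mean.

    Moments are computed once on the full table (no iterative re-screening),
    so the retained set is independent of row order.  Zero-variance columns
    are skipped with a warning.  Returns (filtered table, n_excluded).
    """
    if k <= 0:
        raise ValueError("outlier threshold k must be positive")
    keep = np.ones(len(table), dtype=bool)
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"outlier screen: column {col!r} has zero variance; skipped",
                          stacklevel=2)
            continue
        keep &= np.abs(x - x.mean()) <= k * sd
    filtered = table.loc[keep]
    return filtered, int((~keep).sum())


@dataclass
class LmmSpec:
    """Specification of one per-band mixed model."""

    response: str
    fixed: list[str]
    outlier_sd: float = 2.5
    material_col: str | None = None      # adds material + material×feature terms
    reml: bool = True

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if not self.fixed:
            raise ValueError("at least one fixed-effect feature is required")


@dataclass
class BandLmmResult:
    """Per-band fixed-effect table plus variance components and diagnostics."""

    band: str
    params: pd.DataFrame            # feature, beta, se, z, p, sig_05, sig_10
    vcomp: dict[str, float]         # participant_var, run_var, residual_var
    n_obs: int
    n_excluded: int
    converged: bool
    diagnostics: dict[str, float | str] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.params[self.params["p"] < alpha]


def _alias_groups(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in exact linear dependences (QR diagonal check)."""
    _, r = np.linalg.qr(X)
    tol = np.abs(np.diag(r)).max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in range(min(X.shape)) if abs(r[j, j]) <= tol]


def _design_diagnostics(table: pd.DataFrame, fixed: list[str]) -> dict:
    """Condition number and worst pairwise correlation of the features."""
    X = table[fixed].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    cond = float(np.linalg.cond(np.column_stack([np.ones(len(Xs)), Xs])))
    diag = {"condition_number": cond}
    if len(fixed) >= 2:
        C = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices_from(C, k=1)
        j = int(np.argmax(np.abs(C[iu])))
        diag["max_abs_corr"] = float(np.abs(C[iu])[j])
        diag["max_corr_pair"] = f"{fixed[iu[0][j]]}~{fixed[iu[1][j]]}"
    return diag


def fit_band_lmm(table: pd.DataFrame, spec: LmmSpec) -> BandLmmResult:
    """Fit one band's mixed model with crossed participant/run intercepts.

    The 2.5-SD screen is applied to the response and every feature column of
    this model.  Crossed random intercepts are implemented as two variance
    components over a single all-encompassing group; estimation is REML and
    fixed-effect inference is Wald z with p = 2·(1 − Φ(|z|)).
    """
    cols = [spec.response] + list(spec.fixed)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"analysis table missing columns: {missing}")
    data, n_excluded = exclude_outliers(table, cols, k=spec.outlier_sd)
    if data["participant_id"].nunique() < 2 or data["run_id"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 runs after exclusion")

    X = np.column_stack([np.ones(len(data))] +
                        [data[f].to_numpy(dtype=float) for f in spec.fixed])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _alias_groups(X, ["Intercept"] + list(spec.fixed))
        raise RankDeficiencyError(
            f"band {spec.response!r}: design matrix rank deficient; "
            f"aliased columns: {aliased}")

    df = data.copy()
    df["_group"] = 1
    fixed_terms = list(spec.fixed)
    if spec.material_col:
        fixed_terms = [f"C({spec.material_col})"] + fixed_terms + \
            [f"C({spec.material_col}):{f}" for f in spec.fixed]
    formula = f"{spec.response} ~ " + " + ".join(fixed_terms)
    vc = {"participant": "0 + C(participant_id)", "run": "0 + C(run_id)"}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups="_group", vc_formula=vc)
        fit = model.fit(reml=spec.reml, method="lbfgs", maxiter=200)
        if not fit.converged:
            fit = model.fit(reml=spec.reml, method="powell", maxiter=500)
    if not fit.converged:
        raise ConvergenceError(
            f"band {spec.response!r}: REML optimisation did not converge "
            f"(optimizer bfgs/powell, {len(df)} rows, "
            f"{len(fixed_terms)} fixed terms)")

    k_fe = model.k_fe
    names = model.exog_names[:k_fe]
    beta = np.asarray(fit.fe_params, dtype=float)
    se = np.asarray(fit.bse_fe, dtype=float)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame({
        "feature": names, "beta": beta, "se": se, "z": z, "p": p,
        "sig_05": p < 0.05, "sig_10": p < 0.10,
    })
    vc_order = sorted(vc)  # statsmodels orders variance components by name
    vcomp_map = dict(zip(vc_order, np.asarray(fit.vcomp, dtype=float)))
    vcomp = {"participant_var": float(vcomp_map["participant"]),
             "run_var": float(vcomp_map["run"]),
             "residual_var": float(fit.scale)}
    diag = _design_diagnostics(data, list(spec.fixed))
    return BandLmmResult(band=spec.response, params=params, vcomp=vcomp,
                         n_obs=len(df), n_excluded=n_excluded,
                         converged=bool(fit.converged), diagnostics=diag)


class BandPowerLinkage:
    """Mixed-model linkage of unit features to per-epoch EEG band power.

    Parameters
    ----------
    data : analysis table, one row per (participant, run, unit), holding the
        feature columns, the band-power columns, and participant_id / run_id
        (plus a material column when interactions are requested).
    features : fixed-effect columns (default: the 14 canonical features).
    bands : response columns, one model per band.
    outlier_sd : k of the one-pass k-SD extreme-value screen (default 2.5).
    interactions : if True, add material and material × feature fixed effects
        (requires ``material_col``); a reduced model without them is fitted
        alongside.
    zscore_features : standardize features before fitting (off by default;
        features enter on their raw scales).
    log_power : model log10 band power instead of raw power.
    bh_correction : append a Benjamini–Hochberg adjusted p column per band
        (flags remain based on raw p).
    """

    def __init__(self, data: pd.DataFrame,
                 features: list[str] | None = None,
                 bands: list[str] | None = None,
                 outlier_sd: float = 2.5,
                 interactions: bool = False,
                 material_col: str | None = None,
                 zscore_features: bool = False,
                 log_power: bool = False,
                 bh_correction: bool = False):
        self.features = list(features) if features is not None else list(FEATURE_NAMES)
        self.bands = list(bands) if bands is not None else list(BAND_NAMES)
        if not self.features:
            raise ValueError("empty feature set")
        req = set(self.features) | set(self.bands) | {"participant_id", "run_id"}
        missing = req - set(data.columns)
        if missing:
            raise KeyError(f"analysis table missing columns: {sorted(missing)}")
        if data[self.features + self.bands].isna().any().any():
            raise ValueError("missing values in analysis table after join")
        self.outlier_sd = float(outlier_sd)
        self.interactions = bool(interactions)
        self.material_col = material_col
        if self.interactions and not material_col:
            raise ValueError("interactions=True requires material_col")
        self.zscore_features = bool(zscore_features)
        self.log_power = bool(log_power)
        self.bh_correction = bool(bh_correction)

        data = data.sort_values(["participant_id", "run_id", "unit_id"]
                                if "unit_id" in data.columns
                                else ["participant_id", "run_id"]).reset_index(drop=True)
        if self.zscore_features:
            data = data.copy()
            for f in self.features:
                x = data[f].to_numpy(dtype=float)
                data[f] = (x - x.mean()) / x.std(ddof=1)
        if self.log_power:
            data = data.copy()
            for b in self.bands:
                data[b] = np.log10(np.maximum(data[b].to_numpy(dtype=float), 1e-300))
        self.data = data

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_frames(cls, features: pd.DataFrame, power: pd.DataFrame,
                    units: pd.DataFrame | None = None, **kwargs) -> "BandPowerLinkage":
        """Join a unit-level feature table to an epoch-level power table.

        ``features`` carries one row per unit_id; ``power`` one row per
        (participant, run, unit).  ``units`` may supply a material column.
        Orphaned unit_ids on either side raise with the ids named.
        """
        f_ids = set(features["unit_id"].astype(str))
        p_ids = set(power["unit_id"].astype(str))
        orphans = sorted(p_ids - f_ids)
        if orphans:
            raise KeyError(
                f"{len(orphans)} epoch unit_ids lack feature rows: "
                f"{orphans[:10]}{'...' if len(orphans) > 10 else ''}")
        feat = features.copy()
        feat["unit_id"] = feat["unit_id"].astype(str)
        pw = power.copy()
        pw["unit_id"] = pw["unit_id"].astype(str)
        # ids and sizes travel on the epoch table; features are unit-level
        drop = [c for c in ("n_tokens", "participant_id", "run_id", "material",
                            "duration_s") if c in feat.columns]
        merged = pw.merge(feat.drop(columns=drop),
                          on="unit_id", how="left", validate="many_to_one")
        if units is not None and "material" in units.columns:
            u = units[["unit_id", "material"]].copy()
            u["unit_id"] = u["unit_id"].astype(str)
            merged = merged.merge(u, on="unit_id", how="left", validate="many_to_one")
        return cls(merged, **kwargs)

    @classmethod
    def from_csv(cls, features_csv: str | Path, power_csv: str | Path,
                 units_tsv: str | Path | None = None, **kwargs) -> "BandPowerLinkage":
        features = pd.read_csv(features_csv)
        power = pd.read_csv(power_csv)
        units = pd.read_csv(units_tsv, sep="\t") if units_tsv else None
        return cls.from_frames(features, power, units=units, **kwargs)

    # -- estimation --------------------------------------------------------
    def fit(self, reml: bool = True) -> "LinkageResults":
        """Fit one mixed model per band; returns a :class:`LinkageResults`."""
        results: dict[str, BandLmmResult] = {}
        reduced: dict[str, BandLmmResult] = {}
        for band in self.bands:
            spec = LmmSpec(response=band, fixed=self.features,
                           outlier_sd=self.outlier_sd, reml=reml,
                           material_col=self.material_col if self.interactions else None)
            results[band] = fit_band_lmm(self.data, spec)
            if self.interactions:
                red = LmmSpec(response=band, fixed=self.features,
                              outlier_sd=self.outlier_sd, reml=reml)
                reduced[band] = fit_band_lmm(self.data, red)
        if self.bh_correction:
            for res in results.values():
                res.params["p_bh"] = _benjamini_hochberg(res.params["p"].to_numpy())
        return LinkageResults(model=self, band_results=results,
                              reduced_results=reduced or None)

    def feature_correlations(self) -> pd.DataFrame:
        """Pearson correlation matrix of the feature columns."""
        return self.data[self.features].corr()


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LinkageResults:
    """Fitted per-band mixed models: estimates, variances, diagnostics."""

    model: BandPowerLinkage
    band_results: dict[str, BandLmmResult]
    reduced_results: dict[str, BandLmmResult] | None = None

    def __getitem__(self, band: str) -> BandLmmResult:
        return self.band_results[band]

    def params_frame(self) -> pd.DataFrame:
        """Long-format fixed-effects table over all bands."""
        frames = []
        for band, res in self.band_results.items():
            t = res.params.copy()
            t.insert(0, "band", band)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def vcomp_frame(self) -> pd.DataFrame:
        rows = [{"band": b, **r.vcomp, "n_obs": r.n_obs,
                 "n_excluded": r.n_excluded} for b, r in self.band_results.items()]
        return pd.DataFrame(rows)

    def summary(self, alpha: float = 0.05, report: float = 0.10) -> str:
        """Human-readable per-band report (α = 0.05; p < 0.1 reported)."""
        lines = []
        for band, res in self.band_results.items():
            lines.append(f"== {band} band  (n_obs={res.n_obs}, "
                         f"excluded={res.n_excluded}) ==")
            lines.append(
                f"   var(participant)={res.vcomp['participant_var']:.4g}  "
                f"var(run)={res.vcomp['run_var']:.4g}  "
                f"var(residual)={res.vcomp['residual_var']:.4g}")
            if "max_abs_corr" in res.diagnostics:
                lines.append(
                    f"   design: cond={res.diagnostics['condition_number']:.3g}, "
                    f"max |r|={res.diagnostics['max_abs_corr']:.5f} "
                    f"({res.diagnostics['max_corr_pair']})")
            for row in res.params.itertuples(index=False):
                flag = "*" if row.p < alpha else ("." if row.p < report else " ")
                lines.append(f"   {flag} {row.feature:<22s} beta={row.beta:>10.4f} "
                             f"SE={row.se:>9.4f} z={row.z:>7.3f} p={row.p:.4f}")
        lines.append("flags: '*' p < 0.05, '.' p < 0.1 (no correction applied)")
        return "\n".join(lines)

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write per-band results, variance components and the feature
        correlation matrix; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}
        for band, res in self.band_results.items():
            p = outdir / f"lmm_{band}.csv"
            res.params.to_csv(p, index=False)
            written[f"lmm_{band}"] = p
        vp = outdir / "variance_components.csv"
        self.vcomp_frame().to_csv(vp, index=False)
        written["variance_components"] = vp
        cp = outdir / "feature_correlations.csv"
        self.model.feature_correlations().to_csv(cp)
        written["feature_correlations"] = cp
        return written

    def plot_feature_correlations(self, ax=None):
        """Heatmap of the feature correlation matrix."""
        import matplotlib.pyplot as plt

        C = self.model.feature_correlations()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(C.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(C)), C.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(C)), C.index, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title("Feature correlations")
        return ax


def run_full_analysis(features_csv: str | Path, power_csv: str | Path,
                      outdir: str | Path, units_tsv: str | Path | None = None,
                      **kwargs) -> LinkageResults:
    """Join, screen, fit the five per-band models and write result CSVs."""
    model = BandPowerLinkage.from_csv(features_csv, power_csv,
                                      units_tsv=units_tsv, **kwargs)
    results = model.fit()
    results.to_csv(outdir)
    return results
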