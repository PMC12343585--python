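"""Embedding-geometry features of reading units.

Given the per-token contextual embedding matrix of one reading unit (a short
Chinese segment or an English sentence), this module computes the thirteen
geometry features used as fixed effects downstream:

* four cumulative distances between adjacent token vectors
  (Euclidean, cosine, Manhattan, Chebyshev),
* three norms (L2, L1, L-infinity) of the mean-of-tokens unit vector and the
  same three norms of a direct unit-level encoding,
* three convex-hull features of the PCA projection of the token vectors onto
  the plane of their top two principal components: reading-order neighbour
  distance sum, hull perimeter, hull area.

The fourteenth feature, cumulative masked-LM surprisal, lives in
:mod:`semband.surprisal`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .encoders import TokenEncoder, UnitEncoder

__all__ = [
    "FEATURE_NAMES",
    "GEOMETRY_FEATURE_NAMES",
    "EmbeddingMatrix",
    "UnitVector",
    "Projection2D",
    "UnitFeatures",
    "encode_unit",
    "cumulative_distance",
    "unit_vector_from_tokens",
    "vector_norms",
    "project_2d",
    "hull_features",
    "compute_unit_features",
    "compute_feature_table",
    "feature_table_from_archive",
]

#: The 13 geometry features, in output-column order.
GEOMETRY_FEATURE_NAMES: tuple[str, ...] = (
    "total_euclidean", "total_cosine", "total_manhattan", "total_chebyshev",
    "norm_euclid_tok", "norm_manhattan_tok", "norm_chebyshev_tok",
    "norm_euclid_unit", "norm_manhattan_unit", "norm_chebyshev_unit",
    "hull_neighbor_sum", "hull_perimeter", "hull_area",
)

#: All 14 fixed-effect features (geometry + cumulative surprisal).
FEATURE_NAMES: tuple[str, ...] = GEOMETRY_FEATURE_NAMES + ("cumulative_surprisal",)

_METRICS = ("euclidean", "cosine", "manhattan", "chebyshev")


@dataclass
class EmbeddingMatrix:
    """Per-token embedding rows of one unit, in reading order."""

    unit_id: str
    tokens: list[str]
    M: np.ndarray  # (n_tokens, d)
    source: str = "token_encoder"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (n_tokens, d)")
        if self.M.shape[0] != len(self.tokens):
            raise ValueError("one embedding row per token required")
        if self.M.shape[0] < 1:
            raise ValueError("at least one token required")
        if self.M.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.M)):
            raise ValueError(f"non-finite embedding entries in unit {self.unit_id!r}")

    @property
    def n_tokens(self) -> int:
        return self.M.shape[0]

    @property
    def d(self) -> int:
        return self.M.shape[1]


@dataclass
class UnitVector:
    """A single unit-level embedding vector."""

    unit_id: str
    v: np.ndarray
    provenance: str  # "mean_of_tokens" | "direct_unit_encoding"

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float).ravel()
        if not np.all(np.isfinite(self.v)):
            raise ValueError(f"non-finite unit vector for {self.unit_id!r}")


@dataclass
class Projection2D:
    """Token embeddings projected onto their top two principal components."""

    unit_id: str
    P: np.ndarray  # (n_tokens, 2)
    explained_variance: tuple[float, float]
    degenerate: bool = False  # fewer than 2 informative components


@dataclass
class UnitFeatures:
    """The named per-unit feature values (one fixed-effect design row)."""

    unit_id: str
    n_tokens: int
    total_euclidean: float
    total_cosine: float
    total_manhattan: float
    total_chebyshev: float
    norm_euclid_tok: float
    norm_manhattan_tok: float
    norm_chebyshev_tok: float
    norm_euclid_unit: float
    norm_manhattan_unit: float
    norm_chebyshev_unit: float
    hull_neighbor_sum: float
    hull_perimeter: float
    hull_area: float
    cumulative_surprisal: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"unit_id": self.unit_id, "n_tokens": self.n_tokens}
        for name in FEATURE_NAMES:
            d[name] = getattr(self, name)
        return d


def encode_unit(text: str, encoder: TokenEncoder, unit_id: str = "") -> EmbeddingMatrix:
    """Encode one unit of text into its per-token embedding matrix.

    Special sequence-start/end markers are the encoder's responsibility to
    exclude: the contract is one row per reading token.
    """
    if not text or not text.strip():
        raise ValueError(f"unit {unit_id!r}: empty text")
    tokens, M = encoder.encode(text)
    if len(tokens) == 0:
        raise ValueError(f"unit {unit_id!r}: encoder returned zero tokens")
    return EmbeddingMatrix(unit_id=unit_id, tokens=list(tokens), M=M,
                           source="token_encoder")


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm embedding row")
    return 1.0 - float(np.dot(u, v)) / (nu * nv)


def cumulative_distance(M: EmbeddingMatrix | np.ndarray, metric: str) -> float:
    """Sum of distances between adjacent token vectors within a unit.

    Returns 0 for a single-token unit.  Cosine distance is
    ``1 - u.v / (|u||v|)`` (range [0, 2]) and raises on zero-norm rows.
    """
    A = M.M if isinstance(M, EmbeddingMatrix) else np.asarray(M, dtype=float)
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    if A.shape[0] < 2:
        return 0.0
    if metric == "cosine":
        return float(sum(_cosine_distance(A[i], A[i + 1]) for i in range(A.shape[0] - 1)))
    steps = np.diff(A, axis=0)
    if metric == "euclidean":
        return float(np.linalg.norm(steps, axis=1).sum())
    if metric == "manhattan":
        return float(np.abs(steps).sum())
    return float(np.abs(steps).max(axis=1).sum())  # chebyshev


def unit_vector_from_tokens(M: EmbeddingMatrix) -> UnitVector:
    """Average the token rows into one unit-level vector."""
    return UnitVector(unit_id=M.unit_id, v=M.M.mean(axis=0),
                      provenance="mean_of_tokens")


def vector_norms(v: UnitVector | np.ndarray) -> tuple[float, float, float]:
    """Return (Euclidean, Manhattan, Chebyshev) norms of a unit vector."""
    x = v.v if isinstance(v, UnitVector) else np.asarray(v, dtype=float).ravel()
    return (float(np.linalg.norm(x)),
            float(np.abs(x).sum()),
            float(np.abs(x).max()) if x.size else 0.0)


def project_2d(M: EmbeddingMatrix) -> Projection2D:
    """Project token embeddings onto their top two principal components.

    The PCA is fit on this unit's own (centered) token matrix, so the hull
    features derived from the projection are intrinsic to the unit.  With
    fewer than three tokens or a rank-deficient cloud the missing components
    are zero-filled and the projection flagged degenerate.
    """
    X = M.M - M.M.mean(axis=0, keepdims=True)
    n = X.shape[0]
    P = np.zeros((n, 2))
    ev = [0.0, 0.0]
    degenerate = True
    if n >= 2:
        # top-2 right singular vectors of the centered matrix
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
        k = min(2, int(np.sum(s > tol)))
        if k > 0:
            P[:, :k] = U[:, :k] * s[:k]
            ev[:k] = list((s[:k] ** 2) / (n - 1))
        degenerate = k < 2 or n < 3
    return Projection2D(unit_id=M.unit_id, P=P,
                        explained_variance=(ev[0], ev[1]), degenerate=degenerate)


def _collinear_extent(P: np.ndarray) -> float:
    """Max pairwise distance of an (effectively) collinear 2-D point set."""
    c = P - P.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(c, full_matrices=False)
    t = c @ Vt[0]
    return float(t.max() - t.min())


def hull_features(P: Projection2D | np.ndarray) -> tuple[float, float, float]:
    """(neighbor_sum, perimeter, area) of the projected token cloud.

    ``neighbor_sum`` sums Euclidean distances between consecutive tokens in
    reading order within the 2-D plane; ``perimeter`` and ``area`` describe
    the convex hull of all projected points.  Degenerate clouds: one point →
    (0, 0, 0); two points at distance d → (d, 2d, 0); collinear n ≥ 3 →
    area 0 and perimeter twice the maximal pairwise distance.
    """
    pts = P.P if isinstance(P, Projection2D) else np.asarray(P, dtype=float)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("empty point set")
    neighbor_sum = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if n == 1:
        return 0.0, 0.0, 0.0
    if n == 2:
        d = float(np.linalg.norm(pts[1] - pts[0]))
        return neighbor_sum, 2.0 * d, 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # coincident or collinear points: flat hull
        extent = _collinear_extent(pts)
        return neighbor_sum, 2.0 * extent, 0.0
    # In 2-D, Qhull's "area" is the perimeter and "volume" the enclosed area.
    return neighbor_sum, float(hull.area), float(hull.volume)


def compute_unit_features(
    text: str,
    token_encoder: TokenEncoder,
    unit_encoder: UnitEncoder,
    unit_id: str = "",
) -> UnitFeatures:
    """Compute the 13 geometry features of one unit.

    The ``cumulative_surprisal`` field is left unset; the surprisal module
    fills it.  Sub-operation failures are re-raised with the unit_id attached.
    """
    try:
        M = encode_unit(text, token_encoder, unit_id=unit_id)
        u_direct = UnitVector(unit_id=unit_id, v=unit_encoder.encode_unit(text),
                              provenance="direct_unit_encoding")
        return features_from_embeddings(M, u_direct)
    except ValueError as exc:
        raise ValueError(f"unit {unit_id!r}: {exc}") from exc


def features_from_embeddings(M: EmbeddingMatrix,
                             unit_direct: UnitVector) -> UnitFeatures:
    """Geometry features from a precomputed token matrix and unit vector."""
    u_mean = unit_vector_from_tokens(M)
    e_tok, m_tok, c_tok = vector_norms(u_mean)
    e_unit, m_unit, c_unit = vector_norms(unit_direct)
    nbr, per, area = hull_features(project_2d(M))
    return UnitFeatures(
        unit_id=M.unit_id,
        n_tokens=M.n_tokens,
        total_euclidean=cumulative_distance(M, "euclidean"),
        total_cosine=cumulative_distance(M, "cosine"),
        total_manhattan=cumulative_distance(M, "manhattan"),
        total_chebyshev=cumulative_distance(M, "chebyshev"),
        norm_euclid_tok=e_tok, norm_manhattan_tok=m_tok, norm_chebyshev_tok=c_tok,
        norm_euclid_unit=e_unit, norm_manhattan_unit=m_unit, norm_chebyshev_unit=c_unit,
        hull_neighbor_sum=nbr, hull_perimeter=per, hull_area=area,
    )


#: Exact output column order of the features table.
FEATURE_TABLE_COLUMNS: tuple[str, ...] = (
    "unit_id", "n_tokens",
    "total_euclidean", "total_cosine", "total_manhattan", "total_chebyshev",
    "norm_euclid_tok", "norm_manhattan_tok", "norm_chebyshev_tok",
    "norm_euclid_unit", "norm_manhattan_unit", "norm_chebyshev_unit",
    "hull_neighbor_sum", "hull_perimeter", "hull_area", "cumulative_surprisal",
)


def compute_feature_table(
    units: pd.DataFrame,
    token_encoder: TokenEncoder,
    unit_encoder: UnitEncoder,
    masked_lm=None,
    surprisal_base: float | None = None,
) -> pd.DataFrame:
    """Feature rows for a table of units (columns: unit_id, text).

    If ``masked_lm`` is given the cumulative_surprisal column is filled via
    the surprisal module; otherwise it is NaN.
    """
    from .surprisal import cumulative_surprisal  # local import: avoid cycle

    rows = []
    for rec in units.itertuples(index=False):
        uf = compute_unit_features(rec.text, token_encoder, unit_encoder,
                                   unit_id=str(rec.unit_id))
        if masked_lm is not None:
            tokens, _ = token_encoder.encode(rec.text)
            kwargs = {} if surprisal_base is None else {"base": surprisal_base}
            uf.cumulative_surprisal = cumulative_surprisal(
                tokens, masked_lm, unit_id=str(rec.unit_id), **kwargs).cumulative
        rows.append(uf.as_dict())
    out = pd.DataFrame(rows)
    return out[list(FEATURE_TABLE_COLUMNS)]


def feature_table_from_archive(
    units: pd.DataFrame,
    archive: dict[str, dict[str, np.ndarray]],
    masked_lm=None,
    surprisal_base: float | None = None,
) -> pd.DataFrame:
    """Feature rows for units whose embeddings were precomputed to an archive.

    ``archive`` maps unit_id to {tokens, M, unit_vector} as written by the
    embedding-archive writer; no encoder is invoked.
    """
    from .surprisal import cumulative_surprisal  # local import: avoid cycle

    rows = []
    for uid in units["unit_id"].astype(str):
        if uid not in archive:
            raise KeyError(f"unit_id {uid!r} missing from embedding archive")
        entry = archive[uid]
        M = EmbeddingMatrix(unit_id=uid, tokens=list(entry["tokens"]),
                            M=entry["M"], source="token_encoder")
        uv = UnitVector(unit_id=uid, v=entry["unit_vector"],
                        provenance="direct_unit_encoding")
        uf = features_from_embeddings(M, uv)
        if masked_lm is not None:
            kwargs = {} if surprisal_base is None else {"base": surprisal_base}
            uf.cumulative_surprisal = cumulative_surprisal(
                M.tokens, masked_lm, unit_id=uid, **kwargs).cumulative
        rows.append(uf.as_dict())
    out = pd.DataFrame(rows)
    return out[list(FEATURE_TABLE_COLUMNS)]
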