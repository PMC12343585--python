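"""Shared fixtures and independently coded oracles.

The oracles here deliberately avoid the code paths they check: distances use
scipy.spatial.distance element functions in explicit Python loops, the hull
oracle is a Jarvis-march (gift wrapping) plus the shoelace formula, and the
EDF writer emits the 16-bit container byte by byte.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import distance as ssd


# ---------------------------------------------------------------- distances
def loop_cumulative_distance(A: np.ndarray, metric: str) -> float:
    """Adjacent-pair distance sum via scipy's scalar distance functions."""
    fn = {"euclidean": ssd.euclidean, "manhattan": ssd.cityblock,
          "chebyshev": ssd.chebyshev, "cosine": ssd.cosine}[metric]
    return float(sum(fn(A[i], A[i + 1]) for i in range(len(A) - 1)))


def loop_norms(v: np.ndarray) -> tuple[float, float, float]:
    e = sum(float(x) ** 2 for x in v) ** 0.5
    m = sum(abs(float(x)) for x in v)
    c = max(abs(float(x)) for x in v)
    return e, m, c


# ------------------------------------------------------------------- hulls
def gift_wrap_hull(pts: np.ndarray) -> np.ndarray:
    """Convex hull vertices in CCW order by Jarvis march (O(n*h))."""
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return pts
    start = min(range(n), key=lambda i: (pts[i, 1], pts[i, 0]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = 0 if cur != 0 else 1
        for j in range(n):
            if j == cur:
                continue
            a, b = pts[cand] - pts[cur], pts[j] - pts[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            if cand == cur or cross < 0 or (
                    cross == 0 and
                    np.linalg.norm(pts[j] - pts[cur]) >
                    np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return pts[hull]


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def hull_perimeter_oracle(vertices: np.ndarray) -> float:
    d = vertices - np.roll(vertices, -1, axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


# ---------------------------------------------------------------------- EDF
def write_minimal_edf(path, data: np.ndarray, sfreq: int, ch_names: list[str],
                      phys_range: tuple[float, float] = (-1000.0, 1000.0)):
    """Write a minimal valid EDF file (16-bit, 1-s data records)."""
    data = np.asarray(data, dtype=float)
    nch, nsamp = data.shape
    spr = int(sfreq)
    ndr = int(np.ceil(nsamp / spr))
    d = np.concatenate([data, np.zeros((nch, ndr * spr - nsamp))], axis=1)
    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767
    dig = np.clip(np.round((d - pmin) * (dmax - dmin) / (pmax - pmin) + dmin),
                  dmin, dmax).astype("<i2")

    def f(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = f(0, 8) + f("X X X X", 80) + f("X X X", 80)
    hdr += f("01.01.00", 8) + f("00.00.00", 8)
    hdr += f(256 * (nch + 1), 8) + f("", 44) + f(ndr, 8) + f("1", 8) + f(nch, 4)
    hdr += b"".join(f(c, 16) for c in ch_names)
    hdr += b"".join(f("", 80) for _ in range(nch))
    hdr += b"".join(f("uV", 8) for _ in range(nch))
    hdr += b"".join(f("%g" % pmin, 8) for _ in range(nch))
    hdr += b"".join(f("%g" % pmax, 8) for _ in range(nch))
    hdr += b"".join(f(dmin, 8) for _ in range(nch))
    hdr += b"".join(f(dmax, 8) for _ in range(nch))
    hdr += b"".join(f("", 80) for _ in range(nch))
    hdr += b"".join(f(spr, 8) for _ in range(nch))
    hdr += b"".join(f("", 32) for _ in range(nch))
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(ndr):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())
    return path


# ------------------------------------------------------------------ fixtures
@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_sim_config():
    """Small but structurally complete study for fast end-to-end tests."""
    from semband.simulate import SimConfig

    return SimConfig(seed=7, n_participants=3, n_runs=3, n_units_per_run=8,
                     d=32, n_channels=2)
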