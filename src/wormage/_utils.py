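"""Shared numeric helpers: seeded substreams and exact-df spline bases."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.interpolate import BSpline


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an RNG for a named stage, derived deterministically from one seed.

    Every stochastic stage draws from its own substream so that re-running a
    single stage reproduces its output regardless of what ran before it.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from (seed, name)."""
    tag = zlib.crc32(name.encode("utf-8"))
    return int((int(seed) * 1_000_003 + tag) % (2**31 - 1))


def spline_basis(x: np.ndarray, df: int, x_eval: np.ndarray | None = None) -> np.ndarray:
    """Cubic B-spline regression basis with exactly ``df`` columns.

    Interior knots are placed at quantiles of ``x``; the basis spans cubic
    polynomials (so lines and cubics are reproduced exactly by least squares)
    and includes the constant. ``df`` must be >= 4; df=4 is the plain cubic
    polynomial space.
    """
    x = np.asarray(x, dtype=float)
    if df < 4:
        raise ValueError("spline basis requires df >= 4 (cubic)")
    n_interior = df - 4
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate abscissa for spline basis")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)
    xe = np.clip(xe, lo, hi)
    return BSpline.design_matrix(xe, t, 3, extrapolate=False).toarray()


def fit_spline(x: np.ndarray, y: np.ndarray, df: int):
    """Least-squares fit of an exact-df cubic spline; returns a callable.

    ``y`` may be 1-D or (n_series, n_points); the callable evaluates all
    series at once. Evaluation outside [min(x), max(x)] is linear
    continuation from the boundary (constant slope), which keeps projections
    of out-of-range samples finite.
    """
    x = np.asarray(x, dtype=float)
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    B = spline_basis(x, df)
    coef, *_ = np.linalg.lstsq(B, y2.T, rcond=None)  # (df, n_series)
    lo, hi = float(np.min(x)), float(np.max(x))
    eps = (hi - lo) * 1e-6

    def evaluate(xq: np.ndarray) -> np.ndarray:
        xq = np.asarray(xq, dtype=float)
        xc = np.clip(xq, lo, hi)
        Bq = spline_basis(x, df, x_eval=xc)
        out = (Bq @ coef).T  # (n_series, n_query)
        below, above = xq < lo, xq > hi
        if below.any():
            s = ((spline_basis(x, df, x_eval=np.array([lo + eps])) -
                  spline_basis(x, df, x_eval=np.array([lo]))) @ coef).T / eps
            out[:, below] += s * (xq[below] - lo)
        if above.any():
            s = ((spline_basis(x, df, x_eval=np.array([hi])) -
                  spline_basis(x, df, x_eval=np.array([hi - eps]))) @ coef).T / eps
            out[:, above] += s * (xq[above] - hi)
        return out if np.asarray(y).ndim > 1 else out[0]

    return evaluate
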