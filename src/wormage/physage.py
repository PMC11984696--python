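"""Physiological-age estimation by projection onto a principal curve.

The time-series samples trace the average aging trajectory in PC space. A
principal curve (Hastie-Stuetzle) is fit through them; every sample —
time-course and biomarker-sorted alike — is projected to its nearest point
on the curve, and physiological age is read off proportional to arc length,
calibrated so that the mean arc positions of the youngest and oldest
chronological days map to those day values. The residual (distance from the
curve) measures expression variation orthogonal to the aging trajectory;
its sign is taken along a configurable reference component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA
from sklearn.isotonic import IsotonicRegression

from ._utils import fit_spline

log = logging.getLogger("wormage")


@dataclass
class PCAModel:
    loadings: pd.DataFrame     # gene x component
    scores: pd.DataFrame       # sample x component
    explained_variance_ratio: np.ndarray
    center: pd.Series          # per-gene mean


def pca(X: pd.DataFrame, n_components: int = 3) -> PCAModel:
    """PCA of a gene x sample expression matrix (samples as observations).

    Genes are centered, not scaled. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    if X.shape[1] < n_components + 1:
        raise ValueError("need more samples than components")
    M = X.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(M.std(axis=0), 0):
        raise ValueError("constant expression matrix")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(M)
    loadings = model.components_.T  # genes x comp
    for c in range(n_components):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=X.index, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        center=pd.Series(M.mean(axis=0), index=X.index),
    )


@dataclass
class PrincipalCurve:
    vertices: np.ndarray       # (n_points, d) dense polyline
    arc: np.ndarray            # cumulative arc length per vertex
    df: int
    converged: bool
    n_iter: int
    msd: float                 # mean squared projection distance at the end


def _project_polyline(vertices: np.ndarray, arc: np.ndarray,
                      points: np.ndarray):
    """Nearest point on a polyline for each query point.

    Returns (arc positions, residual distances, residual vectors). Ties are
    broken toward the smaller arc position (segments scanned in order; a
    later segment must be strictly closer to win).
    """
    P = np.atleast_2d(points)
    seg_a = vertices[:-1]
    seg_v = vertices[1:] - seg_a
    seg_len2 = (seg_v**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    # (m, K-1) parameter of the orthogonal projection, clipped to the segment
    t = np.einsum("mkd,kd->mk", P[:, None, :] - seg_a[None, :, :], seg_v) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = seg_a[None, :, :] + t[:, :, None] * seg_v[None, :, :]
    d2 = ((P[:, None, :] - proj) ** 2).sum(axis=2)
    # strict-improvement argmin => first (smallest-arc) minimizer wins
    best = np.zeros(len(P), dtype=int)
    bd = d2[:, 0].copy()
    for k in range(1, d2.shape[1]):
        better = d2[:, k] < bd - 1e-15
        best[better] = k
        bd[better] = d2[better, k]
    tb = t[np.arange(len(P)), best]
    arcpos = arc[best] + tb * np.sqrt(seg_len2[best])
    nearest = proj[np.arange(len(P)), best]
    resid_vec = P - nearest
    resid = np.sqrt((resid_vec**2).sum(axis=1))
    return arcpos, resid, resid_vec


def fit_principal_curve(scores: np.ndarray | pd.DataFrame, df: int = 4,
                        tol: float = 1e-6, max_iter: int = 50,
                        n_points: int = 512) -> PrincipalCurve:
    """Hastie-Stuetzle principal curve through a point cloud.

    The latent parameter is initialized by projection onto the first
    coordinate axis; each iteration smooths every coordinate against the
    parameter (cubic spline, ``df`` degrees of freedom), resamples the curve
    densely, reparameterizes by cumulative arc length, and re-projects the
    points. Convergence is declared when the relative change in mean squared
    projection distance drops below ``tol``.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2:
        raise ValueError("scores must be 2-D")
    n, d = S.shape
    if n < 2 * df:
        raise ValueError(f"need at least {2 * df} samples to fit the curve")
    lam = S[:, 0].copy()
    msd_prev = np.inf
    converged = False
    vertices = arc = None
    it = 0
    for it in range(1, max_iter + 1):
        if np.ptp(lam) <= 0:
            lam = lam + np.linspace(0, 1e-9, n)
        grid = np.linspace(lam.min(), lam.max(), n_points)
        f = fit_spline(lam, S.T, df=df)
        vertices = f(grid).T  # (n_points, d)
        steps = np.sqrt(((np.diff(vertices, axis=0)) ** 2).sum(axis=1))
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        lam, resid, _ = _project_polyline(vertices, arc, S)
        msd = float((resid**2).mean())
        if msd_prev > 0 and abs(msd_prev - msd) / max(msd_prev, 1e-300) < tol:
            converged = True
            msd_prev = msd
            break
        msd_prev = msd
    if not converged:
        log.warning("principal curve did not converge in %d iterations", max_iter)
    return PrincipalCurve(vertices=vertices, arc=arc, df=df,
                          converged=converged, n_iter=it, msd=msd_prev)


def project(curve: PrincipalCurve, point, ref_axis: int = 1):
    """Project point(s) onto the curve.

    Returns (arc position, residual distance, signed residual) — the sign is
    that of the residual vector's component along ``ref_axis`` (default the
    second PC).
    """
    P = np.atleast_2d(np.asarray(point, dtype=float))
    if P.shape[1] != curve.vertices.shape[1]:
        raise ValueError("point dimension does not match curve")
    arcpos, resid, vec = _project_polyline(curve.vertices, curve.arc, P)
    signed = resid * np.sign(vec[:, ref_axis] + (vec[:, ref_axis] == 0))
    if np.asarray(point).ndim == 1:
        return float(arcpos[0]), float(resid[0]), float(signed[0])
    return arcpos, resid, signed


@dataclass
class AgeMap:
    """Monotone map from arc-length position to days."""

    mode: str
    anchors_arc: np.ndarray
    anchors_day: np.ndarray
    slope: float
    intercept: float

    def __call__(self, arc) -> np.ndarray:
        arc = np.asarray(arc, dtype=float)
        if self.mode == "proportional":
            return self.intercept + self.slope * arc
        # monotone: piecewise-linear through isotonic anchors, linear beyond
        x, y = self.anchors_arc, self.anchors_day
        out = np.interp(arc, x, y)
        lo_slope = (y[1] - y[0]) / (x[1] - x[0]) if len(x) > 1 and x[1] > x[0] else self.slope
        hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2]) if len(x) > 1 and x[-1] > x[-2] else self.slope
        below, above = arc < x[0], arc > x[-1]
        out[below] = y[0] + lo_slope * (arc[below] - x[0])
        out[above] = y[-1] + hi_slope * (arc[above] - x[-1])
        return out


def calibrate_age_map(curve: PrincipalCurve, tc_scores: np.ndarray,
                      tc_days: np.ndarray, mode: str = "proportional") -> AgeMap:
    """Calibrate arc length to days from the time-course samples.

    Proportional mode: a linear map fixed by the mean arc positions of the
    youngest and oldest chronological days. Monotone mode: isotonic fit of
    day against arc position, linearly interpolated, linear beyond the
    anchors. Both extrapolate linearly.
    """
    tc_days = np.asarray(tc_days, dtype=float)
    days = np.unique(tc_days)
    if len(days) < 2:
        raise ValueError("time course must span at least two distinct ages")
    arcpos, _, _ = _project_polyline(curve.vertices, curve.arc, np.asarray(tc_scores))
    day_lo, day_hi = days[0], days[-1]
    arc_lo = float(arcpos[tc_days == day_lo].mean())
    arc_hi = float(arcpos[tc_days == day_hi].mean())
    if arc_hi == arc_lo:
        raise ValueError("youngest and oldest anchor arc positions coincide")
    slope = (day_hi - day_lo) / (arc_hi - arc_lo)
    intercept = day_lo - slope * arc_lo
    if mode == "proportional":
        return AgeMap("proportional", np.array([arc_lo, arc_hi]),
                      np.array([day_lo, day_hi]), slope, intercept)
    if mode == "monotone":
        increasing = slope > 0
        order = np.argsort(arcpos, kind="stable")
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        fit_days = iso.fit_transform(arcpos[order], tc_days[order])
        xs, idx = np.unique(arcpos[order], return_index=True)
        ys = fit_days[idx]
        if not increasing:
            xs, ys = xs[::-1] * -1, ys[::-1]  # interp needs ascending x
            return AgeMap("monotone", xs, ys, slope, intercept)
        return AgeMap("monotone", xs, ys, slope, intercept)
    raise ValueError(f"unknown calibration mode {mode!r}")


def calibrate_and_estimate(curve: PrincipalCurve, meta: pd.DataFrame,
                           scores: pd.DataFrame, mode: str = "proportional",
                           ref_axis: int = 1) -> pd.DataFrame:
    """Physiological-age estimates for every sample.

    ``scores`` holds PC scores for all samples (rows = sample ids);
    ``meta`` identifies the time-course samples and their chronological
    ages, which calibrate the arc-length-to-days map.
    """
    meta = meta.set_index("sample_id")
    tc_ids = [s for s in scores.index if meta.loc[s, "group"] == "timecourse"]
    if not tc_ids:
        raise ValueError("no time-course samples to calibrate against")
    tc_days = meta.loc[tc_ids, "age_days"].to_numpy(dtype=float)
    amap = calibrate_age_map(curve, scores.loc[tc_ids].to_numpy(), tc_days, mode=mode)
    S = scores.to_numpy(dtype=float)
    arcpos, resid, vec = _project_polyline(curve.vertices, curve.arc, S)
    if amap.mode == "monotone" and amap.slope < 0:
        phys = amap(-arcpos)
    else:
        phys = amap(arcpos)
    signed = resid * np.sign(vec[:, ref_axis] + (vec[:, ref_axis] == 0))
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "arc": arcpos,
            "phys_age_days": phys,
            "residual": resid,
            "signed_residual": signed,
            "group": meta.loc[scores.index, "group"].to_numpy(),
        }
    ).set_index("sample_id")
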