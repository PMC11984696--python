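"""Count filtering, normalization, and negative-binomial differential expression.

The model per gene is an NB GLM with log link and library-size offset:

    log mu_j = log s_j + b0 + b1*age_j + b2*age_j^2 + b3*age_j^3
               + b_marker * x_marker_j + batch terms

where age is chronological or estimated physiological age (centered and
scaled before taking powers, one shared centering for all three terms), and
the marker term is either one pooled column coded +1 / -1 / 0 (predicted
long-lived / short-lived / time-course) or one column per biomarker.
Coefficients are estimated by IRLS vectorized across genes; significance by
Wald test against the normal reference with Benjamini-Hochberg adjustment
per coefficient across genes.

Dispersion is method-of-moments per gene, shrunk toward a fitted mean-
dispersion trend alpha(mu) = a0/mu + a1; the trend's asymptotic dispersion
a1 also parameterizes the closed-form variance-stabilizing transformation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("wormage")

ALPHA_MIN, ALPHA_MAX = 1e-8, 10.0
RIDGE = 1e-6
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


def align_meta(meta: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Reorder metadata rows to match a count matrix's sample columns."""
    out = meta.set_index("sample_id").reindex(list(sample_ids))
    if out.isna().all(axis=1).any():
        missing = out.index[out.isna().all(axis=1)].tolist()
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return out.rename_axis("sample_id").reset_index()


# ---------------------------------------------------------------- filtering

def detection_filter(counts: pd.DataFrame, min_count: int = 5,
                     min_fraction: float = 0.75) -> pd.DataFrame:
    """Keep genes detected (count >= min_count) in at least ceil(min_fraction
    * n_samples) samples; gene order is preserved."""
    n = counts.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (counts.to_numpy() >= min_count).sum(axis=1) >= need
    return counts.loc[keep]


# ------------------------------------------------------------ normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over genes with a
    nonzero count in every sample; if no such gene exists, falls back to
    genes positive in at least half the samples (warned).
    """
    Y = counts.to_numpy(dtype=float)
    all_pos = (Y > 0).all(axis=1)
    if not all_pos.any():
        log.warning("no gene is nonzero in all samples; "
                    "size factors use genes positive in >= half the samples")
        all_pos = (Y > 0).mean(axis=1) >= 0.5
        if not all_pos.any():
            raise ValueError("cannot compute size factors: counts too sparse")
    sub = Y[all_pos]
    with np.errstate(divide="ignore"):
        logs = np.log(sub)
    logs[~np.isfinite(logs)] = np.nan
    geo = np.nanmean(logs, axis=1)
    ratios = logs - geo[:, None]
    s = np.exp(np.nanmedian(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Per-gene NB dispersions plus the fitted mean-dispersion trend."""

    alpha: pd.Series              # final shrunk per-gene dispersion
    alpha_raw: pd.Series          # method-of-moments estimate (may be <= 0)
    a0: float                     # trend alpha(mu) = a0/mu + a1
    a1: float
    shrinkage_weight: float = 0.5

    def trend(self, mu) -> np.ndarray:
        return self.a0 / np.asarray(mu, dtype=float) + self.a1


def estimate_dispersions(counts: pd.DataFrame, s: pd.Series,
                         design: "DesignMatrix | pd.DataFrame | None" = None,
                         shrinkage_weight: float = 0.5) -> DispersionModel:
    """Method-of-moments dispersions with trend shrinkage.

    Per gene: regress normalized counts on the design by OLS, take the
    residual variance v and mean normalized count m, and set
    alpha_raw = (v - mean(1/s) * m) / m^2. A robust trend a0/mu + a1 is fit
    in log space over genes with positive alpha_raw; the final dispersion is
    the log-scale convex combination of raw and trend (weight 0.5), clamped
    to [1e-8, 10]. Genes with non-positive raw estimates are consistent with
    Poisson noise and get the lower clamp.
    """
    X = design.X.to_numpy() if isinstance(design, DesignMatrix) else (
        np.ones((counts.shape[1], 1)) if design is None else np.asarray(design))
    Y = counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom for dispersion estimation")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    v = (resid**2).sum(axis=0) / (n - p)
    m = Y.mean(axis=1)
    xim = float(np.mean(1.0 / s.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - xim * m) / m**2
    raw[~np.isfinite(raw)] = 0.0

    ok = (raw > 0) & (m > 0)
    if not ok.any():
        log.warning("all moment dispersion estimates <= 0; Poisson fallback")
        alpha = np.full(len(raw), ALPHA_MIN)
        return DispersionModel(
            alpha=pd.Series(alpha, index=counts.index, name="alpha"),
            alpha_raw=pd.Series(raw, index=counts.index, name="alpha_raw"),
            a0=0.0, a1=ALPHA_MIN, shrinkage_weight=shrinkage_weight,
        )
    mu_ok, raw_ok = m[ok], np.clip(raw[ok], ALPHA_MIN, ALPHA_MAX)

    def resid_log(theta):
        a0, a1 = theta
        return np.log(a0 / mu_ok + a1) - np.log(raw_ok)

    x0 = [max(float(np.median(raw_ok * mu_ok)), 1e-6),
          max(float(np.median(raw_ok)), 1e-6)]
    fit = least_squares(resid_log, x0=x0, bounds=([0.0, ALPHA_MIN], [np.inf, ALPHA_MAX]),
                        loss="soft_l1", f_scale=1.0)
    a0, a1 = float(fit.x[0]), float(fit.x[1])

    w = shrinkage_weight
    trend = a0 / np.clip(m, 1e-12, None) + a1
    alpha = np.full(len(raw), ALPHA_MIN)
    pos = raw > 0
    alpha[pos] = np.exp(
        w * np.log(np.clip(trend[pos], ALPHA_MIN, ALPHA_MAX))
        + (1 - w) * np.log(np.clip(raw[pos], ALPHA_MIN, ALPHA_MAX))
    )
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    return DispersionModel(
        alpha=pd.Series(alpha, index=counts.index, name="alpha"),
        alpha_raw=pd.Series(raw, index=counts.index, name="alpha_raw"),
        a0=a0, a1=a1, shrinkage_weight=shrinkage_weight,
    )


def vst(counts: pd.DataFrame, s: pd.Series,
        dispersion: DispersionModel | float) -> pd.DataFrame:
    """Closed-form NB variance-stabilizing transform of normalized counts.

    x = (2 / sqrt(a1)) * asinh(sqrt(a1 * y / s)), with a1 the trend's
    asymptotic dispersion; as a1 -> 0 this converges to 2*sqrt(y/s). Falls
    back to log2(y/s + 1) when a1 <= 0 (warned).
    """
    a1 = dispersion.a1 if isinstance(dispersion, DispersionModel) else float(dispersion)
    Y = counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    if a1 <= 0:
        log.warning("non-positive asymptotic dispersion; using log2(y/s + 1)")
        X = np.log2(Y + 1.0)
    else:
        X = (2.0 / math.sqrt(a1)) * np.arcsinh(np.sqrt(a1 * Y))
    return pd.DataFrame(X, index=counts.index, columns=counts.columns)


def remove_batch(X: pd.DataFrame, meta: pd.DataFrame,
                 protect: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subtract the per-gene OLS batch component from an expression matrix.

    The fit includes the protected design columns (age polynomial, marker)
    so that signal correlated with them is not absorbed into the batch term;
    only the batch component is subtracted. A single batch returns the input
    unchanged.
    """
    batches = meta["batch"].astype(str).to_numpy()
    levels = sorted(set(batches))
    if len(levels) < 2:
        return X.copy()
    B = np.column_stack([(batches == lv).astype(float) for lv in levels[1:]])
    P = (protect.to_numpy() if protect is not None
         else np.ones((X.shape[1], 1)))
    if protect is not None and "intercept" not in getattr(protect, "columns", []):
        P = np.column_stack([np.ones(X.shape[1]), P])
    D = np.column_stack([P, B])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(
            "batch indicators are confounded with protected design columns"
        )
    coef, *_ = np.linalg.lstsq(D, X.to_numpy().T, rcond=None)
    batch_part = B @ coef[-B.shape[1]:, :]
    out = X.to_numpy() - batch_part.T
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ------------------------------------------------------------------ design

@dataclass
class DesignMatrix:
    """Sample x covariate design with named columns and the age scaling used."""

    X: pd.DataFrame
    age_mean: float
    age_sd: float
    pruned: list = field(default_factory=list)

    @property
    def columns(self):
        return list(self.X.columns)


def build_design(meta: pd.DataFrame, age_source: str = "chronological",
                 marker_coding: str = "pooled",
                 phys_ages: pd.Series | None = None,
                 markers: list | None = None) -> DesignMatrix:
    """Build the regression design for either model variant.

    Age (chronological, or supplied physiological estimates) is centered to
    mean 0 and scaled to SD 1, then raised to powers 1-3 sharing that one
    scaling. ``pooled`` coding emits a single marker column holding the
    -1/0/+1 predicted-longevity code; ``per_marker`` emits one column per
    biomarker coded by measured level (+1 marker-high, -1 marker-low, 0
    elsewhere). Batch is one-hot with the first level as reference.
    Degenerate (constant) columns are pruned with a warning.
    """
    sids = meta["sample_id"].to_numpy()
    if age_source == "chronological":
        age = meta["age_days"].to_numpy(dtype=float)
    elif age_source == "physiological":
        if phys_ages is None:
            raise ValueError("physiological age source requires phys_ages")
        missing = [s for s in sids if s not in phys_ages.index]
        if missing:
            raise ValueError(f"phys_ages missing samples: {missing[:5]}")
        age = phys_ages.loc[sids].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown age_source {age_source!r}")

    mean, sd = float(np.mean(age)), float(np.std(age))
    if sd == 0:
        raise ValueError("age has zero variance")
    a = (age - mean) / sd
    cols = {"intercept": np.ones(len(a)), "age1": a, "age2": a**2, "age3": a**3}

    if marker_coding == "pooled":
        cols["marker"] = meta["marker_code"].to_numpy(dtype=float)
    elif marker_coding == "per_marker":
        present = [m for m in meta["marker"].unique() if m != "none"]
        use = list(markers) if markers is not None else sorted(present)
        unknown = [m for m in use if m not in present]
        if unknown:
            raise ValueError(f"unknown marker name(s) {unknown}")
        for m in use:
            code = np.where(
                (meta["marker"] == m) & (meta["group"] == "marker-high"), 1.0,
                np.where((meta["marker"] == m) & (meta["group"] == "marker-low"),
                         -1.0, 0.0),
            )
            cols[f"marker_{m}"] = code
    else:
        raise ValueError(f"unknown marker_coding {marker_coding!r}")

    batches = meta["batch"].astype(str).to_numpy()
    for lv in sorted(set(batches))[1:]:
        cols[f"batch_{lv}"] = (batches == lv).astype(float)

    X = pd.DataFrame(cols, index=sids)
    pruned = [c for c in X.columns if c != "intercept" and X[c].nunique() == 1]
    if pruned:
        log.warning("pruning degenerate design column(s): %s", pruned)
        X = X.drop(columns=pruned)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after pruning")
    return DesignMatrix(X=X, age_mean=mean, age_sd=sd, pruned=pruned)


# --------------------------------------------------------------------- GLM

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (gamma-Poisson parameterization)."""
    from scipy.special import gammaln

    inv = 1.0 / alpha
    return float(np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(alpha * mu / (1 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    ))


def fit_nb_glm_many(Y: np.ndarray, X: np.ndarray, s: np.ndarray,
                    alpha: np.ndarray):
    """IRLS NB GLM fits for all genes at once.

    Y: (G, n) counts; X: (n, p) design; s: (n,) size factors; alpha: (G,)
    dispersions. Returns (beta (G,p), se (G,p), converged (G,), mu (G,n)).
    Standard errors come from the inverse Fisher information X'WX at the
    optimum; a ridge of 1e-6 stabilizes each solve.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    s = np.asarray(s, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    offset = np.log(s)[None, :]

    mu = (Y + Y.mean(axis=1, keepdims=True)) / 2.0 + 0.1
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p)

    for _ in range(IRLS_MAX_ITER):
        w = mu / (1.0 + alpha[:, None] * mu)          # (G, n)
        z = (eta - offset) + (Y - mu) / mu            # working response
        A = np.einsum("ji,gj,jk->gik", X, w, X) + RIDGE * eye[None, :, :]
        b = np.einsum("ji,gj->gi", X, w * z)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        lin = np.clip(beta @ X.T, -30.0, 30.0)
        eta = offset + lin
        mu = np.clip(np.exp(eta), 1e-10, None)
        newly = delta < IRLS_TOL
        converged |= newly
        if newly.all():
            break

    w = mu / (1.0 + alpha[:, None] * mu)
    info = np.einsum("ji,gj,jk->gik", X, w, X) + RIDGE * eye[None, :, :]
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0, None))
    return beta, se, converged, mu


def fit_nb_glm(y: np.ndarray, design: DesignMatrix | np.ndarray,
               s: np.ndarray, alpha: float):
    """Single-gene NB GLM fit; see fit_nb_glm_many."""
    X = design.X.to_numpy() if isinstance(design, DesignMatrix) else np.asarray(design)
    beta, se, conv, _ = fit_nb_glm_many(
        np.asarray(y, dtype=float)[None, :], X, np.asarray(s, dtype=float),
        np.array([alpha]),
    )
    return beta[0], se[0], bool(conv[0])


def wald_bh(beta: np.ndarray, se: np.ndarray):
    """Two-sided Wald p-values against the normal reference and BH q-values.

    Zero or non-finite standard errors yield NaN p and are excluded from the
    BH adjustment (their q is NaN too).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    p = np.full(beta.shape, np.nan)
    ok = np.isfinite(se) & (se > 0) & np.isfinite(beta)
    p[ok] = 2.0 * stats.norm.sf(np.abs(beta[ok] / se[ok]))
    q = np.full(beta.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return p, q


# ------------------------------------------------------------- DGE driver

def run_dge(counts: pd.DataFrame, meta: pd.DataFrame,
            age_source: str = "chronological", marker_coding: str = "pooled",
            phys_ages: pd.Series | None = None,
            s: pd.Series | None = None,
            dispersion: DispersionModel | None = None) -> pd.DataFrame:
    """Fit the NB GLM for every gene and tabulate per-coefficient statistics.

    Returns a DGETable: one row per gene with columns base_mean, converged,
    and beta_/se_/p_/q_<coefficient> for every design column. BH adjustment
    is per coefficient across genes.
    """
    meta = align_meta(meta, counts.columns)
    design = build_design(meta, age_source=age_source,
                          marker_coding=marker_coding, phys_ages=phys_ages)
    if s is None:
        s = size_factors(counts)
    s = s.loc[counts.columns]
    if dispersion is None:
        dispersion = estimate_dispersions(counts, s, design)
    alpha = dispersion.alpha.loc[counts.index].to_numpy()

    beta, se, conv, mu = fit_nb_glm_many(
        counts.to_numpy(), design.X.to_numpy(), s.to_numpy(), alpha)
    if not conv.all():
        log.warning("%d/%d gene fits did not converge", (~conv).sum(), len(conv))

    out = {"base_mean": (counts.to_numpy() / s.to_numpy()[None, :]).mean(axis=1),
           "converged": conv, "alpha": alpha}
    for j, name in enumerate(design.columns):
        p, q = wald_bh(beta[:, j], se[:, j])
        out[f"beta_{name}"] = beta[:, j]
        out[f"se_{name}"] = se[:, j]
        out[f"p_{name}"] = p
        out[f"q_{name}"] = q
    table = pd.DataFrame(out, index=counts.index)
    table.attrs["design_columns"] = design.columns
    table.attrs["age_source"] = age_source
    table.attrs["marker_coding"] = marker_coding
    return table
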