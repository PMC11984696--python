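"""Signature comparison, gene classification, and enrichment.

Signature similarity: Pearson correlation between per-gene coefficient
vectors (one per biomarker plus the linear age term), reproducing the
pairwise comparison of lifespan signatures against each other and against
aging. Gene classification splits the detected genes, at an FDR threshold,
into physiological-age-specific, marker-specific, and intersection sets
using the physiological-age regression; marker-specific genes in cluster 0
(no average time trend) are the age-orthogonal signature. Enrichment is a
weighted Kolmogorov-Smirnov GSEA with a set-size-preserving gene-sampling
null, plus an upper-tail hypergeometric over-representation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def compare_signatures(dge_age: pd.DataFrame, dge_markers: pd.DataFrame,
                       age_coef: str = "age1") -> pd.DataFrame:
    """Pearson correlation matrix across coefficient vectors.

    Rows/columns: every per-marker coefficient in ``dge_markers`` plus the
    age coefficient from ``dge_age``. Correlations use pairwise-complete
    genes from the shared gene universe; genes whose GLM fit was flagged
    non-converged (unbounded coefficients under quasi-separation) are
    excluded from both tables.
    """
    marker_cols = [c for c in dge_markers.columns if c.startswith("beta_marker")]
    if not marker_cols:
        raise ValueError("marker DGE table has no per-marker coefficients")
    if "converged" in dge_age.columns:
        dge_age = dge_age.loc[dge_age["converged"].astype(bool)]
    if "converged" in dge_markers.columns:
        dge_markers = dge_markers.loc[dge_markers["converged"].astype(bool)]
    shared = dge_age.index.intersection(dge_markers.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between the tables")
    vectors = {c.removeprefix("beta_"): dge_markers.loc[shared, c] for c in marker_cols}
    vectors[age_coef] = dge_age.loc[shared, f"beta_{age_coef}"]
    df = pd.DataFrame(vectors)
    return df.corr(method="pearson", min_periods=3)


@dataclass
class GeneClassification:
    table: pd.DataFrame       # per gene: class, flags
    alpha: float

    @property
    def counts(self) -> dict:
        c = self.table["class"].value_counts()
        return {k: int(c.get(k, 0)) for k in
                ("age_specific", "marker_specific", "intersection", "neither")}


def classify_genes(dge_phys: pd.DataFrame, alpha: float = 1e-4,
                   clusters: pd.Series | None = None,
                   marker_coef: str = "marker") -> GeneClassification:
    """Classify genes by which terms of the physiological-age model explain them.

    age flag: any physiological-age term (age1..age3) at q < alpha;
    marker flag: the marker term at q < alpha. Classes: age_specific
    (age only), marker_specific (marker only), intersection (both), neither.
    If cluster labels are supplied, marker-specific genes in cluster 0 are
    flagged as the age-orthogonal signature.
    """
    qcols = [c for c in ("q_age1", "q_age2", "q_age3") if c in dge_phys.columns]
    mcol = f"q_{marker_coef}"
    if not qcols or mcol not in dge_phys.columns:
        raise ValueError("phys-age DGE table lacks required q columns")
    age_flag = (dge_phys[qcols] < alpha).any(axis=1)
    marker_flag = dge_phys[mcol] < alpha
    cls = np.where(
        age_flag & marker_flag, "intersection",
        np.where(age_flag, "age_specific",
                 np.where(marker_flag, "marker_specific", "neither")),
    )
    table = pd.DataFrame(
        {"class": cls, "age_flag": age_flag, "marker_flag": marker_flag},
        index=dge_phys.index,
    )
    if clusters is not None:
        in0 = clusters.reindex(dge_phys.index).eq(0).fillna(False)
        table["cluster0"] = in0
        table["orthogonal"] = (table["class"] == "marker_specific") & in0
    return GeneClassification(table=table, alpha=alpha)


def rank_genes(dge: pd.DataFrame, coefficient: str) -> pd.DataFrame:
    """Rank all genes by signed significance of one coefficient.

    score = sign(beta) * -log10(q), with q floored at the smallest positive
    normal float; descending order, ties broken by gene id.
    """
    bcol, qcol = f"beta_{coefficient}", f"q_{coefficient}"
    if bcol not in dge.columns or qcol not in dge.columns:
        raise ValueError(f"coefficient {coefficient!r} not in DGE table")
    q = dge[qcol].to_numpy(dtype=float)
    q = np.clip(q, np.finfo(float).tiny, 1.0)
    score = np.sign(dge[bcol].to_numpy()) * (-np.log10(q))
    out = pd.DataFrame({"score": score}, index=dge.index)
    out["_gid"] = out.index  # deterministic tie-break within equal scores
    return (out.sort_values(["score", "_gid"], ascending=[False, True],
                            kind="mergesort").drop(columns="_gid"))


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    size: int
    q: float = math.nan
    signed_score: float = math.nan

    @property
    def direction(self) -> str:
        return "positive" if self.es >= 0 else "negative"


def _running_es(scores: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Weighted KS enrichment score for one set on a descending ranked list."""
    n = len(scores)
    k = int(in_set.sum())
    if k == 0 or k == n:
        return 0.0
    w = np.abs(scores) ** weight
    nr = w[in_set].sum()
    if nr == 0:
        hit = np.where(in_set, 1.0 / k, 0.0)
    else:
        hit = np.where(in_set, w / nr, 0.0)
    miss = np.where(in_set, 0.0, 1.0 / (n - k))
    run = np.cumsum(hit - miss)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea(ranked: pd.DataFrame, gene_set, name: str = "set", weight: float = 1.0,
         n_perm: int = 1000, seed: int | None = 0,
         rng: np.random.Generator | None = None) -> EnrichmentResult:
    """GSEA of one gene set against a ranked list.

    The null distribution is built by drawing ``n_perm`` random gene sets of
    the same effective size from the ranked universe. NES normalizes ES by
    the mean |null ES| of matching sign; the permutation p-value is
    (1 + #{same-sign nulls with |ES_null| >= |ES|}) / (n_same_sign + 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = ranked["score"].to_numpy(dtype=float)
    universe = ranked.index
    members = [g for g in set(gene_set) if g in universe]
    if not members:
        raise ValueError(f"gene set {name!r} is entirely outside the universe")
    in_set = universe.isin(members)
    es = _running_es(scores, in_set, weight)
    k = int(in_set.sum())
    n = len(scores)

    idx = np.argsort(
        rng.random((n_perm, n)), axis=1)[:, :k]  # k distinct indices per perm
    null = np.empty(n_perm)
    flags = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        flags[:] = False
        flags[idx[b]] = True
        null[b] = _running_es(scores, flags, weight)
    same = null >= 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    if n_same:
        nes = es / np.abs(null[same]).mean()
        p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (n_same + 1)
    else:
        nes, p = math.nan, 1.0 / (n_perm + 1)
    return EnrichmentResult(name=name, es=es, nes=float(nes), p=float(p), size=k)


def gsea_collection(ranked: pd.DataFrame, sets: dict, weight: float = 1.0,
                    n_perm: int = 1000, seed: int | None = 0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """GSEA over a gene-set collection with BH adjustment across sets.

    Signed score = sign(ES) * -log10(q) with q floored at 1/(n_perm + 1) so
    the display score stays finite. Sets with no member in the universe are
    skipped with a warning.
    """
    import logging

    if rng is None:
        rng = np.random.default_rng(seed)
    results = []
    for name, members in sets.items():
        try:
            results.append(gsea(ranked, members, name=name, weight=weight,
                                n_perm=n_perm, rng=rng))
        except ValueError:
            logging.getLogger("wormage").warning(
                "gene set %r skipped: no members in universe", name)
    if not results:
        raise ValueError("no gene set overlaps the ranked universe")
    q = multipletests([r.p for r in results], method="fdr_bh")[1]
    floor = 1.0 / (n_perm + 1)
    rows = []
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.signed_score = float(np.sign(r.es) * -np.log10(max(qi, floor)))
        rows.append({"set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
                     "p": r.p, "q": r.q, "signed_score": r.signed_score,
                     "direction": r.direction})
    return pd.DataFrame(rows).set_index("set")


def hypergeom_overrep(hits, annotation, universe) -> float:
    """Upper-tail hypergeometric probability of at least the observed overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    annotation = set(annotation) & universe
    overlap = len(hits & annotation)
    N, K, n = len(universe), len(annotation), len(hits)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))
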