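"""Pipeline orchestration: ordered stages over an artifact directory.

Stages (in order): simulate -> filter -> normalize -> dge -> cluster ->
physage -> dge_phys -> decompose -> enrich -> survival. Each stage reads
its upstream artifacts from the output directory, writes its own tables,
and logs its parameters and seed, so any stage can be re-run from
intermediates. All randomness flows from the single config ``seed`` through
named substreams.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import dge as _dge
from . import io as _io
from . import physage as _physage
from . import signatures as _sig
from . import survival as _surv
from . import trajclust as _tc
from ._utils import child_seed

log = logging.getLogger("wormage")

STAGE_ORDER = [
    "simulate", "filter", "normalize", "dge", "cluster",
    "physage", "dge_phys", "decompose", "enrich", "survival",
]
STOCHASTIC_STAGES = {"simulate", "enrich"}


class StageDependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


def _require(out: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise StageDependencyError(
            f"stage {stage!r} requires missing artifact(s) {missing}; "
            f"run the upstream stage(s) first"
        )


def _cohort_params(config: dict) -> _cohort.CohortParams:
    over = dict(config.get("cohort", {}))
    if "markers" in over:
        over["markers"] = tuple(
            _cohort.MarkerSpec(**m) if isinstance(m, dict) else m
            for m in over["markers"]
        )
    for key in ("archetype_fractions", "timepoints", "amplitude_range",
                "baseline_range", "dispersion_range"):
        if key in over:
            over[key] = tuple(over[key])
    return _cohort.CohortParams(seed=child_seed(config["seed"], "simulate"), **over)


# ------------------------------------------------------------------ stages

def stage_simulate(config: dict, out: Path) -> None:
    params = _cohort_params(config)
    counts, meta, survival, truth = _cohort.generate_dataset(params)
    _io.write_counts(counts, out / "counts.tsv")
    _io.write_meta(meta, out / "samples.tsv")
    _io.write_survival(survival, out / "survival.csv")
    _io.write_truth(truth, out / "truth.json")
    sets = {}
    for a in _cohort.ARCHETYPES:
        members = [g.id for g in truth.genes if g.archetype == a and not g.orthogonal_flag]
        if members:
            sets[f"archetype_{a}"] = members
    orth = [g.id for g in truth.genes if g.orthogonal_flag]
    if orth:
        sets["orthogonal_planted"] = orth
    _io.write_gmt(sets, out / "genesets.gmt")
    log.info("simulate: %d genes x %d samples, %d individuals",
             counts.shape[0], counts.shape[1], params.n_individuals)


def stage_filter(config: dict, out: Path) -> None:
    _require(out, "filter", "counts.tsv")
    counts = _io.read_counts(out / "counts.tsv")
    fcfg = config.get("filter", {})
    detected = _dge.detection_filter(
        counts, min_count=fcfg.get("min_count", 5),
        min_fraction=fcfg.get("min_fraction", 0.75))
    _io.write_counts(detected, out / "counts_detected.tsv")
    log.info("filter: %d/%d genes detected", detected.shape[0], counts.shape[0])


def stage_normalize(config: dict, out: Path) -> None:
    _require(out, "normalize", "counts_detected.tsv", "samples.tsv")
    counts = _io.read_counts(out / "counts_detected.tsv")
    meta = _dge.align_meta(_io.read_meta(out / "samples.tsv", counts), counts.columns)
    s = _dge.size_factors(counts)
    design = _dge.build_design(meta, marker_coding="pooled")
    disp = _dge.estimate_dispersions(counts, s, design)
    X = _dge.vst(counts, s, disp)
    protect = design.X[[c for c in design.columns if not c.startswith("batch_")]]
    Xc = _dge.remove_batch(X, meta, protect=protect)
    s.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
    pd.DataFrame({"alpha": disp.alpha, "alpha_raw": disp.alpha_raw}).to_csv(
        out / "dispersions.tsv", sep="\t")
    with open(out / "dispersion_trend.json", "w") as fh:
        json.dump({"a0": disp.a0, "a1": disp.a1,
                   "shrinkage_weight": disp.shrinkage_weight}, fh)
    _io.write_table(X, out / "vst.tsv")
    _io.write_table(Xc, out / "vst_corrected.tsv")
    log.info("normalize: trend a0=%.4g a1=%.4g", disp.a0, disp.a1)


def _load_dge_inputs(out: Path):
    counts = _io.read_counts(out / "counts_detected.tsv")
    meta = _dge.align_meta(_io.read_meta(out / "samples.tsv", counts), counts.columns)
    s = pd.read_csv(out / "size_factors.tsv", sep="\t", index_col=0)["size_factor"]
    return counts, meta, s.loc[counts.columns]


def stage_dge(config: dict, out: Path) -> None:
    _require(out, "dge", "counts_detected.tsv", "samples.tsv", "size_factors.tsv")
    counts, meta, s = _load_dge_inputs(out)
    pooled = _dge.run_dge(counts, meta, age_source="chronological",
                          marker_coding="pooled", s=s)
    _io.write_table(pooled, out / "dge_chrono.tsv")
    per = _dge.run_dge(counts, meta, age_source="chronological",
                       marker_coding="per_marker", s=s)
    _io.write_table(per, out / "dge_markers.tsv")
    log.info("dge: chronological-age models fit for %d genes", counts.shape[0])


def stage_cluster(config: dict, out: Path) -> None:
    _require(out, "cluster", "vst_corrected.tsv", "samples.tsv", "dge_chrono.tsv")
    X = _io.read_table(out / "vst_corrected.tsv")
    meta = _io.read_meta(out / "samples.tsv")
    dge_chrono = _io.read_table(out / "dge_chrono.tsv")
    ccfg = config.get("cluster", {})
    traj = _tc.average_by_timepoint(X, meta)
    traj = _tc.smooth_standardize(traj, df=ccfg.get("spline_df", 5))
    assign = _tc.cluster_trajectories(
        traj, dge_chrono, k=ccfg.get("k", 5),
        alpha0=ccfg.get("alpha0", 0.01), window=ccfg.get("window", 1))
    assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    rows = [
        {"cluster": label, "day": float(day), "z": float(v)}
        for label, centroid in sorted(assign.centroids.items())
        for day, v in zip(assign.ages, centroid)
    ]
    pd.DataFrame(rows).to_csv(out / "centroids.tsv", sep="\t", index=False)
    sizes = assign.labels.value_counts().sort_index()
    log.info("cluster: sizes %s", sizes.to_dict())


def stage_physage(config: dict, out: Path) -> None:
    _require(out, "physage", "vst_corrected.tsv", "samples.tsv")
    X = _io.read_table(out / "vst_corrected.tsv")
    meta = _io.read_meta(out / "samples.tsv")
    pcfg = config.get("physage", {})
    model = _physage.pca(X, n_components=pcfg.get("n_components", 3))
    tc_ids = meta.loc[meta["group"] == "timecourse", "sample_id"]
    curve = _physage.fit_principal_curve(
        model.scores.loc[tc_ids].to_numpy(), df=pcfg.get("df", 4))
    est = _physage.calibrate_and_estimate(
        curve, meta, model.scores, mode=pcfg.get("mode", "proportional"),
        ref_axis=pcfg.get("ref_axis", 1))
    est.to_csv(out / "physage.tsv", sep="\t")
    pd.DataFrame(curve.vertices,
                 columns=model.scores.columns).assign(arc=curve.arc).to_csv(
        out / "curve.tsv", sep="\t", index=False)
    log.info("physage: curve converged=%s msd=%.4g", curve.converged, curve.msd)


def stage_dge_phys(config: dict, out: Path) -> None:
    _require(out, "dge_phys", "counts_detected.tsv", "samples.tsv",
             "size_factors.tsv", "physage.tsv")
    counts, meta, s = _load_dge_inputs(out)
    phys = pd.read_csv(out / "physage.tsv", sep="\t", index_col=0)["phys_age_days"]
    table = _dge.run_dge(counts, meta, age_source="physiological",
                         marker_coding="pooled", phys_ages=phys, s=s)
    _io.write_table(table, out / "dge_phys.tsv")
    log.info("dge_phys: physiological-age model fit for %d genes", counts.shape[0])


def stage_decompose(config: dict, out: Path) -> None:
    _require(out, "decompose", "dge_phys.tsv", "dge_markers.tsv",
             "dge_chrono.tsv", "clusters.tsv")
    dge_phys = _io.read_table(out / "dge_phys.tsv")
    dge_markers = _io.read_table(out / "dge_markers.tsv")
    dge_chrono = _io.read_table(out / "dge_chrono.tsv")
    clusters = _io.read_table(out / "clusters.tsv")["cluster"]
    alpha = config.get("classify", {}).get("alpha", 1e-4)
    cls = _sig.classify_genes(dge_phys, alpha=alpha, clusters=clusters)
    cls.table.to_csv(out / "classification.tsv", sep="\t")
    venn = cls.counts
    venn["orthogonal"] = int(cls.table.get("orthogonal", pd.Series(dtype=bool)).sum())
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh)
    corr = _sig.compare_signatures(dge_chrono, dge_markers)
    corr.to_csv(out / "signature_correlations.tsv", sep="\t")
    log.info("decompose: venn %s", venn)


def stage_enrich(config: dict, out: Path) -> None:
    _require(out, "enrich", "dge_phys.tsv")
    ecfg = config.get("enrich", {})
    gmt = ecfg.get("geneset_file", out / "genesets.gmt")
    if not Path(gmt).exists():
        raise StageDependencyError(f"enrich: gene-set file {gmt} not found")
    sets = _io.read_gmt(gmt)
    dge_phys = _io.read_table(out / "dge_phys.tsv")
    n_perm = ecfg.get("n_perm", 1000)
    weight = ecfg.get("weight", 1.0)
    rng = np.random.default_rng(child_seed(config["seed"], "enrich"))
    for coef, fname in (("age1", "enrichment_phys.tsv"),
                        ("marker", "enrichment_marker.tsv")):
        ranked = _sig.rank_genes(dge_phys, coef)
        table = _sig.gsea_collection(ranked, sets, weight=weight,
                                     n_perm=n_perm, rng=rng)
        table.to_csv(out / fname, sep="\t")
    log.info("enrich: %d sets tested against %d genes", len(sets), len(dge_phys))


def stage_survival(config: dict, out: Path) -> None:
    _require(out, "survival", "survival.csv")
    table = _io.read_survival(out / "survival.csv")
    markers = sorted({g.rsplit("-", 1)[0] for g in table["group"].unique()})
    stats, rows = [], []
    for m in markers:
        ga, gb = f"{m}-high", f"{m}-low"
        if ga not in set(table["group"]) or gb not in set(table["group"]):
            continue
        stats.append({"marker": m, **_surv.compare_groups(table, ga, gb)})
        for g in (ga, gb):
            c = _surv.km_curve(table, g)
            rows.extend({"group": g, "time": float(t), "survival": float(sv),
                         "at_risk": float(ar)}
                        for t, sv, ar in zip(c.times, c.survival, c.at_risk))
    with open(out / "survival_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1)
    pd.DataFrame(rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    log.info("survival: %d marker contrasts", len(stats))


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "normalize": stage_normalize,
    "dge": stage_dge,
    "cluster": stage_cluster,
    "physage": stage_physage,
    "dge_phys": stage_dge_phys,
    "decompose": stage_decompose,
    "enrich": stage_enrich,
    "survival": stage_survival,
}


def run_pipeline(config: dict, outdir, stages=None) -> Path:
    """Run the requested stages (default: all) in canonical order."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = STAGE_ORDER if stages is None else [s for s in STAGE_ORDER if s in set(stages)]
    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    if any(s in STOCHASTIC_STAGES for s in wanted) and "seed" not in config:
        raise ValueError("config must set 'seed' to run stochastic stages")

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        log.info("run_pipeline stages=%s seed=%s config=%s",
                 wanted, config.get("seed"), json.dumps(config, default=str))
        for name in wanted:
            log.info("stage %s: start", name)
            STAGES[name](config, out)
            log.info("stage %s: done", name)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
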