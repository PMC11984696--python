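"""Synthetic aging-cohort generator.

Emulates the study design this package analyzes: a synchronized, isogenic
population of individuals that all follow one average transcriptional aging
trajectory but proceed along it at heterogeneous rates. Each individual i has

* an aging rate ``r_i`` (lognormal around 1): its physiological age after t
  chronological days is ``r_i * t``;
* a latent factor ``q_i ~ N(0,1)`` independent of ``r_i``, standing for a
  transcriptional state correlated with future lifespan but orthogonal to
  position along the aging trajectory;
* one fluorescence level per biomarker, each loading on a shared "health"
  axis ``u_i = -w_r (r_i - 1)/sigma_r + w_q q_i`` with a marker-specific sign
  (positive-sign markers are brighter in prospectively long-lived animals);
* a lifespan ``base_lifespan / r_i`` up to lognormal noise, so biomarkers
  predict lifespan through their loading on r.

Bulk RNA-seq samples pool many individuals: per-gene means are averaged over
the pool on the natural scale and a single negative-binomial library is drawn
per sample, with per-gene batch factors and per-sample library-size factors.
Day-5 samples sorted into the top/bottom tenth percentile of one biomarker
emulate the microfluidic decile sorting of the study; their marker code is
+1 for the predicted long-lived group and -1 for predicted short-lived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import substream

ARCHETYPES = ("flat", "up", "down", "early_peak", "late_peak", "mid_trough")

_DAY_LO, _DAY_HI = 2.0, 12.0
_PEAK_EARLY, _PEAK_LATE, _TROUGH_MID = 4.0, 9.0, 7.0
_BUMP_WIDTH = 1.5


def archetype_profile(archetype: str, phys_age) -> np.ndarray:
    """Dimensionless temporal profile f(phys_age) of one trajectory archetype.

    Ramps are normalized to span one unit over days 2-12 (and continue
    linearly outside, keeping them monotone); peaks are unit-height Gaussian
    bumps centered at day 4 (early) or day 9 (late); the mid trough is the
    negated bump centered at day 7.
    """
    t = np.asarray(phys_age, dtype=float)
    ramp = (t - _DAY_LO) / (_DAY_HI - _DAY_LO)
    if archetype == "flat":
        return np.zeros_like(t)
    if archetype == "up":
        return ramp
    if archetype == "down":
        return -ramp
    if archetype == "early_peak":
        return np.exp(-0.5 * ((t - _PEAK_EARLY) / _BUMP_WIDTH) ** 2)
    if archetype == "late_peak":
        return np.exp(-0.5 * ((t - _PEAK_LATE) / _BUMP_WIDTH) ** 2)
    if archetype == "mid_trough":
        return -np.exp(-0.5 * ((t - _TROUGH_MID) / _BUMP_WIDTH) ** 2)
    raise ValueError(f"unknown archetype {archetype!r}")


@dataclass(frozen=True)
class MarkerSpec:
    """One lifespan-predictive biomarker: its name, direction, and noise."""

    name: str
    sign: int  # +1: brighter = longer-lived; -1: brighter = shorter-lived
    sigma_b: float = 0.5

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("marker sign must be +1 or -1")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")


DEFAULT_MARKERS = (
    MarkerSpec("lin4", +1),
    MarkerSpec("mir243", +1),
    MarkerSpec("mir240_786", -1),
    MarkerSpec("autofl", -1),
)

DEFAULT_ARCHETYPE_FRACTIONS = {
    "flat": 0.20,
    "up": 0.28,
    "down": 0.28,
    "early_peak": 0.08,
    "late_peak": 0.08,
    "mid_trough": 0.08,
}


@dataclass(frozen=True)
class CohortParams:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int
    n_individuals: int = 1000
    sigma_r: float = 0.25
    w_r: float = 1.0
    w_q: float = 1.0
    sigma_b: float = 0.5
    marker_sign: int = +1
    markers: tuple[MarkerSpec, ...] = DEFAULT_MARKERS
    base_lifespan: float = 15.0
    lifespan_noise_sd: float = 0.15
    n_genes: int = 3000
    archetype_fractions: tuple[float, ...] = tuple(
        DEFAULT_ARCHETYPE_FRACTIONS[a] for a in ARCHETYPES
    )
    n_orthogonal: int = 150
    effect_size_orth: float = 0.8
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    dispersion_range: tuple[float, float] = (0.01, 0.4)
    n_batches: int = 2
    batch_sd: float = 0.1
    pool_size: int = 50
    timepoints: tuple[float, ...] = tuple(float(d) for d in range(2, 13))
    reps: int = 3
    sort_day: float = 5.0
    censor_rate: float = 0.05
    library_size_sd: float = 0.15

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_genes <= 0 or self.n_batches <= 0:
            raise ValueError("counts must be positive")
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be > 0")
        if self.dispersion_range[0] <= 0:
            raise ValueError("dispersion alpha_min must be > 0")
        if self.n_orthogonal > self.n_genes:
            raise ValueError("n_orthogonal exceeds n_genes")
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-12:
            raise ValueError("archetype fractions must sum to 1")
        if any(f < 0 for f in self.archetype_fractions):
            raise ValueError("archetype fractions must be non-negative")
        if self.marker_sign not in (+1, -1):
            raise ValueError("marker_sign must be +1 or -1")
        if self.pool_size <= 0 or self.reps <= 0:
            raise ValueError("pool_size and reps must be positive")


@dataclass(frozen=True)
class Individual:
    id: str
    r: float
    q: float
    b: dict  # marker name -> fluorescence level
    lifespan: float

    def __post_init__(self):
        if self.r <= 0 or self.lifespan <= 0:
            raise ValueError("aging rate and lifespan must be positive")


@dataclass(frozen=True)
class GeneSpec:
    id: str
    archetype: str
    baseline: float
    amplitude: float
    orthogonal_flag: bool
    gamma: float
    dispersion: float

    def __post_init__(self):
        if self.baseline <= 0 or self.dispersion <= 0:
            raise ValueError("baseline and dispersion must be positive")
        if self.orthogonal_flag and self.archetype != "flat":
            raise ValueError("orthogonal genes must be flat-archetype")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery checks downstream."""

    individuals: list
    genes: list
    sample_composition: dict  # sample_id -> list of individual ids
    params: CohortParams = None

    def individual_by_id(self):
        return {ind.id: ind for ind in self.individuals}

    def true_mean_phys_age(self, meta: pd.DataFrame) -> pd.Series:
        """Per-sample pooled mean physiological age, mean_i(r_i) * age_days."""
        by_id = self.individual_by_id()
        out = {}
        for sid, age in zip(meta["sample_id"], meta["age_days"]):
            members = self.sample_composition[sid]
            out[sid] = float(np.mean([by_id[m].r for m in members]) * age)
        return pd.Series(out, name="true_phys_age")

    def true_mean_q(self, meta: pd.DataFrame) -> pd.Series:
        by_id = self.individual_by_id()
        return pd.Series(
            {
                sid: float(np.mean([by_id[m].q for m in self.sample_composition[sid]]))
                for sid in meta["sample_id"]
            },
            name="true_mean_q",
        )


def simulate_individuals(params: CohortParams) -> list:
    """Draw the cohort: aging rates, latent factor, biomarkers, lifespans.

    r_i = exp(N(0, sigma_r^2)); q_i ~ N(0,1) independent of r_i;
    b_i = sign * (-w_r (r_i-1)/sigma_r + w_q q_i) + N(0, sigma_b^2 noise SD);
    lifespan_i = base_lifespan / r_i * exp(N(0, lifespan_noise_sd^2)).
    """
    rng = substream(params.seed, "individuals")
    n = params.n_individuals
    r = np.exp(rng.normal(0.0, params.sigma_r, size=n))
    q = rng.normal(0.0, 1.0, size=n)
    u = -params.w_r * (r - 1.0) / params.sigma_r + params.w_q * q
    levels = {}
    for m in params.markers:
        levels[m.name] = m.sign * u + rng.normal(0.0, m.sigma_b, size=n)
    lifespan = params.base_lifespan / r * np.exp(
        rng.normal(0.0, params.lifespan_noise_sd, size=n)
    )
    width = len(str(n - 1))
    return [
        Individual(
            id=f"i{i:0{width}d}",
            r=float(r[i]),
            q=float(q[i]),
            b={name: float(levels[name][i]) for name in levels},
            lifespan=float(lifespan[i]),
        )
        for i in range(n)
    ]


def simulate_genes(params: CohortParams) -> list:
    """Assign archetypes, baselines, amplitudes, dispersions, and plant the
    age-orthogonal genes (flat archetype with a loading on q)."""
    rng = substream(params.seed, "genes")
    n = params.n_genes
    counts = np.floor(np.asarray(params.archetype_fractions) * n).astype(int)
    counts[0] += n - counts.sum()  # remainder goes to flat
    if params.n_orthogonal > counts[0]:
        raise ValueError("n_orthogonal exceeds the number of flat genes")
    archetypes = np.repeat(ARCHETYPES, counts)
    lo, hi = params.baseline_range
    baseline = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    amplitude = rng.uniform(*params.amplitude_range, size=n)
    alo, ahi = params.dispersion_range
    dispersion = np.exp(rng.uniform(math.log(alo), math.log(ahi), size=n))
    gamma_sign = rng.choice([-1.0, 1.0], size=n)
    width = len(str(n - 1))
    genes = []
    for g in range(n):
        orth = archetypes[g] == "flat" and g < params.n_orthogonal
        genes.append(
            GeneSpec(
                id=f"g{g:0{width}d}",
                archetype=str(archetypes[g]),
                baseline=float(baseline[g]),
                amplitude=float(amplitude[g]) if archetypes[g] != "flat" else 0.0,
                orthogonal_flag=bool(orth),
                gamma=float(gamma_sign[g] * params.effect_size_orth) if orth else 0.0,
                dispersion=float(dispersion[g]),
            )
        )
    return genes


def expression_mean(gene: GeneSpec, phys_age, q=0.0) -> np.ndarray:
    """Expected expression of one gene at a physiological age and latent q."""
    if np.any(np.asarray(phys_age) < 0):
        raise ValueError("physiological age must be >= 0")
    f = archetype_profile(gene.archetype, phys_age)
    load = gene.gamma * q if gene.orthogonal_flag else 0.0
    return gene.baseline * np.exp(f * gene.amplitude + load)


def _mean_matrix(genes: list, phys_ages: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """(n_genes,) pooled mean expression: mean over individuals of the
    per-individual expected expression, natural scale."""
    profiles = {a: archetype_profile(a, phys_ages) for a in ARCHETYPES}
    amp = np.array([g.amplitude for g in genes])
    base = np.array([g.baseline for g in genes])
    gam = np.array([g.gamma if g.orthogonal_flag else 0.0 for g in genes])
    f = np.stack([profiles[g.archetype] for g in genes])  # (G, n_pool)
    log_mu = amp[:, None] * f + gam[:, None] * qs[None, :]
    return base * np.exp(log_mu).mean(axis=1)


def decile_members(individuals: list, marker: str, which: str) -> list:
    """Individuals in the top or bottom tenth percentile of one biomarker.

    Nearest-rank deciles on the realized cohort: exactly ceil(n/10)
    individuals are eligible on each side.
    """
    b = np.array([ind.b[marker] for ind in individuals])
    k = math.ceil(0.1 * len(individuals))
    order = np.argsort(b, kind="stable")
    if which == "top_decile":
        idx = order[-k:]
    elif which == "bottom_decile":
        idx = order[:k]
    else:
        raise ValueError(f"unknown selection {which!r}")
    return [individuals[i] for i in idx]


def sample_bulk_counts(
    individuals: list,
    genes: list,
    chrono_age: float,
    selection: str = "all",
    marker: str | None = None,
    pool_size: int | None = None,
    batch_factor: np.ndarray | None = None,
    size_scale: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list]:
    """One pooled bulk library: NB counts over genes, plus the pooled ids.

    The pool is drawn from the whole cohort (``selection='all'``) or from the
    top/bottom biomarker decile; per-gene means are averaged across the pool
    before a single negative-binomial draw per gene.
    """
    rng = np.random.default_rng(seed)
    if selection == "all":
        stratum = list(individuals)
    else:
        if marker is None:
            raise ValueError("decile selection requires a marker name")
        stratum = decile_members(individuals, marker, selection)
    if not stratum:
        raise ValueError("empty stratum for bulk sample")
    pool_size = len(stratum) if pool_size is None else pool_size
    if pool_size > len(stratum):
        raise ValueError(
            f"pool_size {pool_size} exceeds stratum of {len(stratum)} individuals"
        )
    pick = rng.choice(len(stratum), size=pool_size, replace=False)
    pool = [stratum[i] for i in pick]
    phys = np.array([ind.r * chrono_age for ind in pool])
    qs = np.array([ind.q for ind in pool])
    mu = _mean_matrix(genes, phys, qs) * size_scale
    if batch_factor is not None:
        mu = mu * batch_factor
    alpha = np.array([g.dispersion for g in genes])
    # NB as gamma-Poisson mixture; alpha -> 0 recovers Poisson
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam)
    return counts.astype(np.int64), [ind.id for ind in pool]


def generate_dataset(params: CohortParams):
    """Full synthetic dataset: counts, sample metadata, survival, truth.

    Emits a time-course sample per (timepoint, replicate) with marker code 0,
    and a day-``sort_day`` decile-sorted sample per (marker, level,
    replicate) with marker code +1 (predicted long-lived) or -1 (predicted
    short-lived). Replicates cycle over sequencing batches. The survival
    table holds post-sort lifespans of every sorted individual, with a small
    random censoring rate.
    """
    individuals = simulate_individuals(params)
    genes = simulate_genes(params)
    rng = substream(params.seed, "samples")

    gene_ids = [g.id for g in genes]
    batch_log = rng.normal(0.0, params.batch_sd, size=(params.n_batches, len(genes)))
    batch_log[0] = 0.0  # reference batch
    batch_factors = np.exp(batch_log)

    columns, meta_rows, composition = {}, [], {}

    def add_sample(sid, age, group, marker, code, selection, batch_idx):
        size_scale = float(np.exp(rng.normal(0.0, params.library_size_sd)))
        counts, pool_ids = sample_bulk_counts(
            individuals,
            genes,
            chrono_age=age,
            selection=selection,
            marker=marker,
            pool_size=params.pool_size,
            batch_factor=batch_factors[batch_idx],
            size_scale=size_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        columns[sid] = counts
        meta_rows.append(
            {
                "sample_id": sid,
                "age_days": float(age),
                "group": group,
                "marker": marker if marker is not None else "none",
                "marker_code": int(code),
                "batch": f"b{batch_idx}",
            }
        )
        composition[sid] = pool_ids

    for t in params.timepoints:
        for rep in range(params.reps):
            add_sample(
                f"tc_d{int(t):02d}_r{rep + 1}",
                t, "timecourse", None, 0, "all", rep % params.n_batches,
            )
    for m in params.markers:
        for level in ("high", "low"):
            selection = "top_decile" if level == "high" else "bottom_decile"
            code = m.sign if level == "high" else -m.sign
            for rep in range(params.reps):
                add_sample(
                    f"{m.name}_{level}_r{rep + 1}",
                    params.sort_day,
                    f"marker-{level}",
                    m.name,
                    code,
                    selection,
                    rep % params.n_batches,
                )

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows)

    surv_rows, seen = [], {}
    censor_rng = substream(params.seed, "censoring")
    by_id = {ind.id: ind for ind in individuals}
    for sid, pool_ids in composition.items():
        row = meta.loc[meta["sample_id"] == sid].iloc[0]
        if row["marker_code"] == 0:
            continue
        group = f"{row['marker']}-{row['group'].split('-')[1]}"
        for iid in pool_ids:
            if (iid, group) in seen:
                continue
            seen[(iid, group)] = True
            ind = by_id[iid]
            if censor_rng.uniform() < params.censor_rate:
                day = censor_rng.uniform(params.sort_day, max(ind.lifespan, params.sort_day + 0.5))
                event = "censor"
            else:
                day, event = ind.lifespan, "death"
            surv_rows.append(
                {"individual_id": iid, "group": group, "day": float(day), "event": event}
            )
    survival = pd.DataFrame(surv_rows)

    truth = CohortTruth(
        individuals=individuals, genes=genes,
        sample_composition=composition, params=params,
    )
    return counts, meta, survival, truth


def single_marker_params(params: CohortParams) -> CohortParams:
    """Convenience: collapse the marker panel to one marker named 'marker'
    with direction ``params.marker_sign`` and noise ``params.sigma_b``."""
    return replace(
        params,
        markers=(MarkerSpec("marker", params.marker_sign, params.sigma_b),),
    )
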