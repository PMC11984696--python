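# wormage

Transcriptomic aging trajectories and lifespan signatures for pooled
*C. elegans* cohorts.

Isogenic worm populations reared in a common environment still show large
lifespan variability, and fluorescent biomarkers of aging (e.g.
*lin-4*p::GFP, *mir-243*p::GFP, *mir-240/786*p::GFP, gut autofluorescence)
can prospectively separate long- from short-lived individuals at
mid-adulthood. `wormage` is a pipeline for asking what that separation looks
like at the transcriptome level: how much of the "predicted long-lived"
expression signature is just being *physiologically younger* — sitting
earlier on the average aging trajectory — and which genes separate the
groups *orthogonally* to age. It is aimed at researchers analyzing bulk
RNA-seq of aging time courses plus biomarker-sorted subpopulations, and it
ships a synthetic cohort generator with full ground truth so every stage can
be validated end to end.

## Model

Counts for gene *g* in sample *j* follow a negative-binomial GLM with log
link and library-size offset log *s<sub>j</sub>* (median-of-ratios factors):

```
log μ_gj = log s_j + β₀ + β_Age1·x_j + β_Age2·x_j² + β_Age3·x_j³ + β_Marker·m_j + β_Batch
```

where *x* is age (centered/scaled, chronological or physiological) and *m*
is the marker code (+1 predicted long-lived, −1 predicted short-lived, 0
time course) — or one term per biomarker in the per-marker variant.
Coefficients are estimated by IRLS (vectorized across genes), dispersions by
method-of-moments shrunk toward a mean-dispersion trend α(μ) = a₀/μ + a₁,
significance by Wald test with Benjamini–Hochberg adjustment per
coefficient.

Physiological age is defined geometrically: a Hastie–Stuetzle principal
curve is fit through the time-course samples in PC space (VST-transformed,
batch-corrected counts), every sample is projected to its nearest point on
the curve, and arc length — calibrated so the youngest/oldest time-course
days map to their chronological ages — is read off as the sample's
physiological age. Re-fitting the GLM with physiological in place of
chronological age splits biomarker-associated genes into an age-aligned
component (absorbed by the age terms) and an age-orthogonal component (still
carried by the marker term). Temporal shapes are characterized separately by
complete-linkage clustering of smoothed, z-scored per-gene trajectories
under a dynamic-time-warping distance (band radius one day) with DTW
barycenter-averaged centroids; genes without any significant age term form
"cluster 0".

## Worked example

```python
import numpy as np
import wormage as w
from wormage import dge, physage, signatures

params = w.CohortParams(seed=1)                       # the default study design
counts, meta, survival, truth = w.generate_dataset(params)

detected = dge.detection_filter(counts)               # >=5 counts in >=75% samples
meta = dge.align_meta(meta, detected.columns)
s = dge.size_factors(detected)
design = dge.build_design(meta, marker_coding="pooled")
disp = dge.estimate_dispersions(detected, s, design)
expr = dge.vst(detected, s, disp)
protect = design.X[[c for c in design.columns if not c.startswith("batch_")]]
expr = dge.remove_batch(expr, meta, protect=protect)

model = physage.pca(expr, n_components=3)
tc = meta.loc[meta["group"] == "timecourse", "sample_id"]
curve = physage.fit_principal_curve(model.scores.loc[tc].to_numpy(), df=4)
est = physage.calibrate_and_estimate(curve, meta, model.scores)

codes = meta.set_index("sample_id")["marker_code"].loc[est.index]
truth_age = truth.true_mean_phys_age(meta).loc[est.index]
print(f"detected genes: {detected.shape[0]}/{counts.shape[0]}")
print(f"corr(estimated, true physiological age): "
      f"{np.corrcoef(est['phys_age_days'], truth_age)[0, 1]:.3f}")
print(f"mean physiological age at day 5: "
      f"predicted long-lived {est.loc[codes == 1, 'phys_age_days'].mean():.2f} d, "
      f"predicted short-lived {est.loc[codes == -1, 'phys_age_days'].mean():.2f} d")

phys_dge = dge.run_dge(detected, meta, age_source="physiological",
                       marker_coding="pooled",
                       phys_ages=est["phys_age_days"], s=s)
cls = signatures.classify_genes(phys_dge, alpha=1e-4)
print("classification:", cls.counts)
```

Output:

```
detected genes: 2998/3000
corr(estimated, true physiological age): 0.996
mean physiological age at day 5: predicted long-lived 3.92 d, predicted short-lived 7.27 d
classification: {'age_specific': 972, 'marker_specific': 155, 'intersection': 28, 'neither': 1843}
```

All 57 samples were collected between days 2 and 12, yet the day-5
subpopulations sorted as prospectively long- vs short-lived sit at very
different points on the aging trajectory (3.9 vs 7.3 days), and after
controlling for physiological age a marker-specific gene set remains — in
the synthetic cohort these are overwhelmingly the planted age-orthogonal
genes (here 155 called marker-specific vs 150 planted).

The same analysis runs from the shell on YAML-configured artifact
directories:

```
wormage all --outdir run1 --seed 1
```

which writes counts, metadata, survival records, DGE tables, cluster
assignments, physiological ages, the gene classification with Venn counts,
GSEA enrichment and Kaplan–Meier/log-rank statistics into `run1/`.

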