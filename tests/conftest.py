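import numpy as np
import pandas as pd
import pytest

import wormage as w
from wormage import dge, physage


@pytest.fixture(scope="session")
def small_params():
    """A small but structurally complete cohort for unit tests."""
    return w.CohortParams(seed=42, n_genes=400, n_individuals=500,
                          n_orthogonal=20, pool_size=30)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return w.generate_dataset(small_params)


@pytest.fixture(scope="session")
def default_params():
    """The full study-scale synthetic configuration."""
    return w.CohortParams(seed=20240501)


@pytest.fixture(scope="session")
def default_dataset(default_params):
    return w.generate_dataset(default_params)


def normalize_chain(counts, meta):
    """detection filter -> size factors -> dispersions -> VST -> batch removal."""
    det = dge.detection_filter(counts)
    meta2 = dge.align_meta(meta, det.columns)
    s = dge.size_factors(det)
    design = dge.build_design(meta2, marker_coding="pooled")
    disp = dge.estimate_dispersions(det, s, design)
    X = dge.vst(det, s, disp)
    protect = design.X[[c for c in design.columns if not c.startswith("batch_")]]
    Xc = dge.remove_batch(X, meta2, protect=protect)
    return det, meta2, s, disp, Xc


def physage_chain(counts, meta, n_components=3, df=4):
    """Normalization through physiological-age estimates for every sample."""
    det, meta2, s, disp, Xc = normalize_chain(counts, meta)
    model = physage.pca(Xc, n_components=n_components)
    tc = meta2.loc[meta2["group"] == "timecourse", "sample_id"]
    curve = physage.fit_principal_curve(model.scores.loc[tc].to_numpy(), df=df)
    est = physage.calibrate_and_estimate(curve, meta2, model.scores)
    return det, meta2, s, est


@pytest.fixture(scope="session")
def default_physage(default_dataset):
    counts, meta, _, truth = default_dataset
    det, meta2, s, est = physage_chain(counts, meta)
    return det, meta2, s, est, truth


def nb_counts(rng, mu, alpha, size=None):
    """Negative-binomial draws via the gamma-Poisson mixture."""
    lam = rng.gamma(1.0 / alpha, alpha * np.asarray(mu, dtype=float), size=size)
    return rng.poisson(lam)


def frame(Y, prefix_g="g", prefix_s="s"):
    Y = np.atleast_2d(Y)
    return pd.DataFrame(
        Y,
        index=[f"{prefix_g}{i:04d}" for i in range(Y.shape[0])],
        columns=[f"{prefix_s}{j:03d}" for j in range(Y.shape[1])],
    )
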