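"""Differential expression core: filter, normalization, NB GLM, Wald/BH."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from wormage import dge
from wormage.dge import nb_loglik

from conftest import frame, nb_counts


# ------------------------------------------------------------------ oracles

def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def glm_oracle(y, X, s, alpha):
    """Brute-force NB likelihood maximization, independent of the IRLS path."""
    def nll(beta):
        mu = s * np.exp(np.clip(X @ beta, -30, 30))
        return -nb_loglik(y, mu, alpha)

    best = None
    for x0 in (np.zeros(X.shape[1]),
               np.r_[math.log(max(y.mean(), 0.5)), np.zeros(X.shape[1] - 1)]):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


# ----------------------------------------------------------------- filtering

class TestDetectionFilter:
    def test_boundary_three_quarters_retained(self):
        counts = frame([[5, 5, 5, 0]])
        assert len(dge.detection_filter(counts)) == 1

    def test_all_below_threshold_removed(self):
        counts = frame([[4, 4, 4, 4]])
        assert len(dge.detection_filter(counts)) == 0

    def test_planted_fixture_matches_brute_force(self):
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 12, size=(100, 8))
        counts = frame(Y)
        kept = dge.detection_filter(counts)
        expected = [
            i for i in range(100)
            if (Y[i] >= 5).sum() >= math.ceil(0.75 * 8)
        ]
        assert list(kept.index) == [f"g{i:04d}" for i in expected]
        assert (np.array([(row >= 5).sum() >= 6 for row in Y])).sum() == len(kept)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = frame([[10, 10], [100, 100]])
        s = dge.size_factors(counts)
        assert np.allclose(s, 1.0)

    def test_doubled_library_hand_computation(self):
        counts = frame([[10, 20], [100, 200]])
        s = dge.size_factors(counts)
        assert s.iloc[0] == pytest.approx(1 / math.sqrt(2))
        assert s.iloc[1] == pytest.approx(math.sqrt(2))

    def test_ratio_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = frame(rng.integers(1, 500, size=(50, 6)))
        s1 = dge.size_factors(counts)
        s3 = dge.size_factors(counts * 3)
        assert np.allclose(s1, s3)


class TestVst:
    def test_zero_maps_to_zero(self):
        counts = frame([[0, 0]])
        s = pd.Series([1.0, 1.0], index=counts.columns)
        assert np.allclose(dge.vst(counts, s, 0.1), 0.0)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(2)
        y = np.sort(rng.integers(0, 10000, 100))
        counts = frame(y[None, :])
        s = pd.Series(np.ones(100), index=counts.columns)
        x = dge.vst(counts, s, 0.05).to_numpy()[0]
        assert (np.diff(x) >= 0).all()

    def test_variance_flattening_across_mean_grid(self):
        rng = np.random.default_rng(3)
        a1 = 0.05
        sds = []
        for mu in (10, 100, 1000, 10000):
            y = nb_counts(rng, np.full(20000, float(mu)), a1)
            counts = frame(y[None, :])
            s = pd.Series(np.ones(20000), index=counts.columns)
            sds.append(dge.vst(counts, s, a1).to_numpy().std())
        sds = np.array(sds)
        assert (sds.max() - sds.min()) / sds.mean() < 0.25


class TestRemoveBatch:
    def _meta(self, batches):
        return pd.DataFrame({
            "sample_id": [f"s{j:03d}" for j in range(len(batches))],
            "age_days": np.tile([2.0, 12.0], len(batches) // 2),
            "group": "timecourse", "marker": "none", "marker_code": 0,
            "batch": batches,
        })

    def test_single_batch_returns_input(self):
        X = frame(np.random.default_rng(4).normal(size=(10, 6)))
        out = dge.remove_batch(X, self._meta(["b0"] * 6))
        pd.testing.assert_frame_equal(out, X)

    def test_additive_shift_fully_removed(self):
        rng = np.random.default_rng(5)
        base = np.tile(rng.normal(size=(20, 1)), (1, 8))  # no structure but the shift
        shifted = base.copy()
        shifted[:, 4:] += 0.7  # batch shift on second half
        X = frame(shifted)
        out = dge.remove_batch(X, self._meta(["b0"] * 4 + ["b1"] * 4))
        assert np.allclose(out.to_numpy(), base, atol=1e-8)

    def test_protected_age_trend_untouched_when_orthogonal(self):
        rng = np.random.default_rng(6)
        n = 12
        age = np.tile([2.0, 12.0], n // 2)
        batches = ["b0"] * (n // 2) + ["b1"] * (n // 2)  # balanced vs age
        slope = 0.5
        X = frame(slope * age[None, :] + rng.normal(0, 0.01, size=(5, n)))
        meta = self._meta(batches)
        meta["age_days"] = age
        protect = pd.DataFrame({"age": age}, index=meta["sample_id"])
        out = dge.remove_batch(X, meta, protect=protect)
        for g in range(5):
            before = np.polyfit(age, X.to_numpy()[g], 1)[0]
            after = np.polyfit(age, out.to_numpy()[g], 1)[0]
            assert after == pytest.approx(before, abs=1e-6)

    def test_confounded_batch_raises(self):
        X = frame(np.random.default_rng(7).normal(size=(5, 4)))
        meta = self._meta(["b0", "b0", "b1", "b1"])
        protect = pd.DataFrame(
            {"x": [0.0, 0.0, 1.0, 1.0]}, index=meta["sample_id"])
        with pytest.raises(ValueError, match="confounded"):
            dge.remove_batch(X, meta, protect=protect)


class TestBuildDesign:
    def _meta(self):
        rows = []
        for j, a in enumerate([2, 4, 6, 8, 10, 12] * 2):
            rows.append({"sample_id": f"t{j}", "age_days": float(a),
                         "group": "timecourse", "marker": "none",
                         "marker_code": 0, "batch": f"b{j % 2}"})
        for m in ("lin4", "mir243", "mir240_786", "autofl"):
            for lvl, code in (("high", 1), ("low", -1)):
                rows.append({"sample_id": f"{m}_{lvl}", "age_days": 5.0,
                             "group": f"marker-{lvl}", "marker": m,
                             "marker_code": code, "batch": "b0"})
        return pd.DataFrame(rows)

    def test_age_column_centered_scaled(self):
        d = dge.build_design(self._meta())
        assert abs(d.X["age1"].mean()) < 1e-12
        assert d.X["age1"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_shared_centering_for_powers(self):
        d = dge.build_design(self._meta())
        assert np.allclose(d.X["age2"], d.X["age1"] ** 2)
        assert np.allclose(d.X["age3"], d.X["age1"] ** 3)

    def test_timecourse_only_marker_column_pruned(self):
        meta = self._meta()
        meta = meta.loc[meta["group"] == "timecourse"]
        d = dge.build_design(meta, marker_coding="pooled")
        assert "marker" not in d.columns
        assert "marker" in d.pruned

    def test_per_marker_emits_four_columns(self):
        d = dge.build_design(self._meta(), marker_coding="per_marker")
        cols = [c for c in d.columns if c.startswith("marker_")]
        assert len(cols) == 4

    def test_per_marker_codes_by_level(self):
        d = dge.build_design(self._meta(), marker_coding="per_marker")
        col = d.X["marker_lin4"]
        assert col.loc["lin4_high"] == 1.0
        assert col.loc["lin4_low"] == -1.0
        assert (col.drop(["lin4_high", "lin4_low"]) == 0).all()

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown marker"):
            dge.build_design(self._meta(), marker_coding="per_marker",
                             markers=["nonesuch"])

    def test_physiological_source_requires_estimates(self):
        with pytest.raises(ValueError):
            dge.build_design(self._meta(), age_source="physiological")


class TestDispersions:
    def test_poisson_counts_shrink_to_floor(self):
        rng = np.random.default_rng(8)
        mu = rng.uniform(50, 2000, 300)
        counts = frame(rng.poisson(mu[:, None], size=(300, 24)))
        s = pd.Series(np.ones(24), index=counts.columns)
        d = dge.estimate_dispersions(counts, s)
        assert d.alpha.median() <= 0.01

    def test_nb_dispersion_recovered_in_band(self):
        rng = np.random.default_rng(9)
        mu = rng.uniform(50, 2000, 300)
        counts = frame(nb_counts(rng, np.broadcast_to(mu[:, None], (300, 24)), 0.2))
        s = pd.Series(np.ones(24), index=counts.columns)
        d = dge.estimate_dispersions(counts, s)
        assert 0.1 <= d.alpha.median() <= 0.4

    def test_constant_gene_clamped_at_floor(self):
        Y = np.vstack([np.full(10, 100), np.random.default_rng(10).poisson(100, 10)])
        counts = frame(Y)
        s = pd.Series(np.ones(10), index=counts.columns)
        d = dge.estimate_dispersions(counts, s)
        assert d.alpha.iloc[0] == pytest.approx(dge.ALPHA_MIN)


class TestNbGlm:
    def test_unit_normalized_counts_zero_intercept(self):
        s = np.array([1.0, 2.0, 4.0, 8.0])
        y = s.copy()  # all ones after offset
        X = np.ones((4, 1))
        beta, _, conv = dge.fit_nb_glm(y, X, s, alpha=1e-8)
        assert conv and beta[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_group_log_fold_change_closed_form(self):
        y = np.array([100.0] * 6 + [200.0] * 6)
        X = np.column_stack([np.ones(12), np.r_[np.zeros(6), np.ones(6)]])
        s = np.ones(12)
        beta, _, _ = dge.fit_nb_glm(y, X, s, alpha=1e-8)
        assert beta[1] == pytest.approx(math.log(2), abs=1e-3)

    def test_brute_force_likelihood_oracle_agreement(self):
        rng = np.random.default_rng(11)
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        s = np.exp(rng.normal(0, 0.1, n))
        for _ in range(20):
            alpha = rng.uniform(0.05, 0.5)
            beta_true = np.array([rng.uniform(2, 4), rng.normal(0, 0.5)])
            mu = s * np.exp(X @ beta_true)
            y = nb_counts(rng, mu, alpha).astype(float)
            beta_hat, _, _ = dge.fit_nb_glm(y, X, s, alpha)
            beta_ref = glm_oracle(y, X, s, alpha)
            assert np.max(np.abs(beta_hat - beta_ref)) < 1e-4

    def test_marker_effect_recovery_within_three_se(self):
        rng = np.random.default_rng(12)
        n, reps, effect = 36, 200, 0.5
        age = np.tile(np.linspace(-1, 1, n // 2), 2)
        marker = np.r_[np.full(n // 2, 1.0), np.full(n // 2, -1.0)]
        X = np.column_stack([np.ones(n), age, marker])
        s = np.ones(n)
        alpha = np.full(reps, 0.1)
        mu = np.exp(4.0 + 0.8 * age + effect * marker)
        Y = nb_counts(rng, np.broadcast_to(mu, (reps, n)), 0.1)
        beta, se, conv, _ = dge.fit_nb_glm_many(Y.astype(float), X, s, alpha)
        hit = np.abs(beta[:, 2] - effect) <= 3 * se[:, 2]
        assert conv.all()
        assert hit.mean() >= 0.95


class TestWaldBh:
    def test_zero_beta_gives_p_one(self):
        p, q = dge.wald_bh(np.array([0.0]), np.array([1.0]))
        assert p[0] == pytest.approx(1.0)
        assert q[0] == pytest.approx(1.0)

    def test_hand_bh_example(self):
        p_in = np.array([0.01, 0.02, 0.03, 0.04])
        beta = np.full(4, 1.0)
        # invert to betas that give exactly these p-values
        from scipy.stats import norm
        se = beta / norm.isf(p_in / 2)
        p, q = dge.wald_bh(beta, se)
        assert np.allclose(p, p_in, atol=1e-12)
        assert np.allclose(q, 0.04, atol=1e-12)

    def test_bh_matches_textbook_step_up_on_random_vectors(self):
        rng = np.random.default_rng(13)
        from scipy.stats import norm
        for _ in range(10):
            p_in = rng.uniform(0, 1, 50)
            se = 1.0 / norm.isf(p_in / 2)
            p, q = dge.wald_bh(np.ones(50), se)
            assert np.allclose(q, bh_oracle(p), atol=1e-10)

    def test_zero_se_excluded_from_adjustment(self):
        p, q = dge.wald_bh(np.array([1.0, 1.0]), np.array([0.0, 0.5]))
        assert np.isnan(p[0]) and np.isnan(q[0])
        assert np.isfinite(q[1])


class TestGeneOrderInvariance:
    def test_permuting_rows_permutes_outputs(self, small_dataset):
        counts, meta, _, _ = small_dataset
        det = dge.detection_filter(counts).iloc[:80]
        s = dge.size_factors(det)
        t1 = dge.run_dge(det, meta, s=s)
        rng = np.random.default_rng(14)
        perm = rng.permutation(len(det))
        t2 = dge.run_dge(det.iloc[perm], meta, s=s)
        pd.testing.assert_frame_equal(t1.loc[t2.index], t2)
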