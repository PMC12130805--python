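import numpy as np
import pytest

from mrpanel.estimators import (
    egger,
    ivw_uncorrelated,
    mr_presso,
    mvmr_ivw,
    weighted_median,
    weighted_mode,
)
from mrpanel.harmonize import HarmonizedSet


def hset(bx, by, sy=None, sx=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.full_like(bx, 0.05) if sy is None else np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    ids = tuple(f"rs{i}" for i in range(bx.size))
    return HarmonizedSet(ids, bx, sx, by, sy)


class TestIvw:
    def test_exact_ratio_recovered(self):
        h = hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        assert ivw_uncorrelated(h).beta == pytest.approx(0.5)

    def test_outlier_dominates_by_weight_arithmetic(self):
        """Oracle: the IVW estimate is the weight-averaged ratio; a tiny-SE
        outlier pulls it toward its own ratio, and removing it restores the
        bulk value."""
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.05, 0.05, 0.05, 0.30])
        sy = np.array([0.05, 0.05, 0.05, 0.001])
        w = 1.0 / sy**2
        oracle_full = np.sum(w * bx * by) / np.sum(w * bx**2)
        est_full = ivw_uncorrelated(hset(bx, by, sy))
        assert est_full.beta == pytest.approx(oracle_full)
        assert est_full.beta > 2.0  # pulled toward the outlier ratio 3.0
        est_bulk = ivw_uncorrelated(hset(bx[:3], by[:3], sy[:3]))
        assert est_bulk.beta == pytest.approx(0.5)

    def test_minimum_two_variants(self):
        with pytest.raises(ValueError):
            ivw_uncorrelated(hset([0.1], [0.05]))

    def test_type_i_error_near_nominal(self):
        """Under θ = 0 with valid instruments, IVW rejects at ~5%."""
        rng = np.random.default_rng(7)
        j, n_rep = 50, 1000
        bx_true = rng.normal(0.08, 0.01, j)
        sx, sy = np.full(j, 0.003), np.full(j, 0.02)
        rejections = 0
        for _ in range(n_rep):
            bx = rng.normal(bx_true, sx)
            by = rng.normal(0.0, sy)
            rejections += ivw_uncorrelated(hset(bx, by, sy, sx)).pval < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.5 * bx
        est = egger(hset(bx, by))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_joint_negation_invariance(self):
        rng = np.random.default_rng(1)
        bx = rng.normal(0.2, 0.05, 10)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.01, 10)
        est = egger(hset(bx, by))
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        est2 = egger(hset(bx2, by2))
        assert est2.beta == pytest.approx(est.beta, abs=1e-10)
        assert abs(est2.extras["egger_intercept"]) == pytest.approx(
            abs(est.extras["egger_intercept"]), abs=1e-10)

    def test_balanced_pleiotropy_intercept_type_i(self):
        """With balanced (mean-zero) pleiotropy the intercept test should
        reject at the nominal 5% rate."""
        rng = np.random.default_rng(11)
        j, n_rep = 30, 1000
        rejections = 0
        for _ in range(n_rep):
            bx_true = rng.normal(0.15, 0.03, j)
            alpha = rng.normal(0.0, 0.02, j)
            sx, sy = np.full(j, 0.005), np.full(j, 0.02)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(0.3 * bx_true + alpha, sy)
            est = egger(hset(bx, by, sy, sx))
            rejections += est.extras["egger_intercept_p"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_minimum_three_variants(self):
        with pytest.raises(ValueError):
            egger(hset([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        h = hset([1, 1, 1], [1, 2, 3], sy=[1, 1, 1])
        assert weighted_median(h, n_boot=200, seed=0).beta == pytest.approx(2.0)

    def test_interpolated_median(self, equal_weight_hset):
        est = weighted_median(equal_weight_hset, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.5)

    def test_robust_to_forty_percent_contamination(self):
        """Oracle: contamination simulation — 40% of variants shifted by +1;
        the median stays near θ while IVW is badly biased."""
        rng = np.random.default_rng(5)
        theta, j, n_rep = 0.5, 20, 200
        med_est, ivw_est = [], []
        for _ in range(n_rep):
            bx_true = rng.normal(0.2, 0.02, j)
            alpha = np.zeros(j)
            alpha[: int(0.4 * j)] = 1.0 * bx_true[: int(0.4 * j)]
            sx, sy = np.full(j, 0.002), np.full(j, 0.006)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(theta * bx_true + alpha, sy)
            h = hset(bx, by, sy, sx)
            med_est.append(weighted_median(h, n_boot=50, seed=1).beta)
            ivw_est.append(ivw_uncorrelated(h).beta)
        assert abs(np.mean(med_est) - theta) < 0.1 * theta
        assert abs(np.mean(ivw_est) - theta) > 0.25 * theta

    def test_seeded_determinism(self, equal_weight_hset):
        a = weighted_median(equal_weight_hset, n_boot=100, seed=9)
        b = weighted_median(equal_weight_hset, n_boot=100, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_degenerate_mode_is_common_ratio(self):
        h = hset([0.1, 0.2, 0.3], [0.07, 0.14, 0.21])
        assert weighted_mode(h, n_boot=100, seed=0).beta == pytest.approx(0.7, abs=1e-9)

    def test_bimodal_majority_cluster_wins(self):
        """Density-grid oracle: six high-weight ratios near 0.5 versus three
        low-weight ratios near 2.0."""
        bx = np.array([0.3] * 6 + [0.1] * 3)
        by = np.array([0.15, 0.149, 0.151, 0.152, 0.148, 0.15, 0.2, 0.201, 0.199])
        h = hset(bx, by, sy=np.full(9, 0.02))
        est = weighted_mode(h, phi=1.0, n_boot=100, seed=0)
        assert abs(est.beta - 0.5) < 0.1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        bx = rng.normal(0.2, 0.05, 9)
        by = 0.4 * bx + rng.normal(0, 0.01, 9)
        h = hset(bx, by)
        est = weighted_mode(h, n_boot=50, seed=3)
        perm = rng.permutation(9)
        h2 = HarmonizedSet(tuple(f"rs{i}" for i in range(9)), h.bx[perm], h.sx[perm],
                           h.by[perm], h.sy[perm])
        est2 = weighted_mode(h2, n_boot=50, seed=3)
        assert est2.beta == pytest.approx(est.beta, abs=1e-9)


class TestMrPresso:
    def _clean(self, seed=0, j=30, theta=0.3):
        rng = np.random.default_rng(seed)
        bx_true = rng.normal(0.15, 0.03, j)
        sx, sy = np.full(j, 0.005), np.full(j, 0.02)
        bx = rng.normal(bx_true, sx)
        by = rng.normal(theta * bx_true, sy)
        return hset(bx, by, sy, sx), theta

    def test_no_outliers_headline_absent_global_p_reported(self):
        h, _ = self._clean(seed=4)
        est = mr_presso(h, n_sim=300, seed=1)
        assert np.isnan(est.beta)
        assert 0 < est.extras["presso_global_p"] <= 1
        assert est.extras["presso_outlier_ids"] == ()

    def test_planted_outlier_flagged_and_corrected(self):
        h, theta = self._clean(seed=8)
        by = h.by.copy()
        by[5] += 10 * h.sy[5]
        h2 = HarmonizedSet(h.variant_ids, h.bx, h.sx, by, h.sy)
        # Bonferroni-corrected empirical p needs n_sim > J/alpha to resolve
        est = mr_presso(h2, n_sim=1000, seed=2)
        assert "rs5" in est.extras["presso_outlier_ids"]
        # corrected estimate consistent with truth at the 95% sampling bound
        assert abs(est.beta - theta) < 2 * est.se
        assert est.extras["presso_global_p"] < 0.05

    def test_null_global_p_calibration(self):
        """Without pleiotropy the global test should rarely reject."""
        keep = 0
        n_rep = 100
        for i in range(n_rep):
            h, _ = self._clean(seed=100 + i)
            est = mr_presso(h, n_sim=200, seed=i)
            keep += est.extras["presso_global_p"] > 0.05
        assert keep >= 0.90 * n_rep

    def test_seeded_determinism(self):
        h, _ = self._clean(seed=4)
        a = mr_presso(h, n_sim=200, seed=7)
        b = mr_presso(h, n_sim=200, seed=7)
        assert a.extras["presso_global_p"] == b.extras["presso_global_p"]

    def test_minimum_four_variants(self):
        with pytest.raises(ValueError):
            mr_presso(hset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15]), n_sim=200, seed=0)


class TestMvmrIvw:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.2, 0.05, (10, 2))
        by = 0.3 * bx[:, 0] - 0.2 * bx[:, 1]
        ests = mvmr_ivw(bx, np.full((10, 2), 0.01), by, np.full(10, 0.02))
        assert ests[0].beta == pytest.approx(0.3, abs=1e-10)
        assert ests[1].beta == pytest.approx(-0.2, abs=1e-10)

    def test_nested_model_equals_univariable(self):
        rng = np.random.default_rng(1)
        bx1 = rng.normal(0.2, 0.05, 12)
        by = 0.4 * bx1 + rng.normal(0, 0.01, 12)
        sy = np.full(12, 0.02)
        bx = np.column_stack([bx1, np.zeros(12)])
        est = mvmr_ivw(bx, np.full((12, 2), 0.01), by, sy)[0]
        uni = ivw_uncorrelated(hset(bx1, by, sy))
        assert est.beta == pytest.approx(uni.beta, abs=1e-12)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(2)
        bx1 = rng.normal(0.2, 0.05, 12)
        bx = np.column_stack([bx1, 2.0 * bx1])
        with pytest.raises(np.linalg.LinAlgError):
            mvmr_ivw(bx, np.full((12, 2), 0.01), bx1, np.full(12, 0.02))

    def test_mediation_attenuates_direct_effect(self):
        """Generative oracle: exposure 2 mediates part of exposure 1's effect,
        so the multivariable direct effect of exposure 1 is smaller than its
        univariable total effect."""
        rng = np.random.default_rng(3)
        j = 40
        g1 = rng.normal(0.2, 0.05, j)          # effects on exposure 1
        g2 = 0.5 * g1 + rng.normal(0, 0.05, j)  # exposure 2 partly downstream
        direct1, via2 = 0.2, 0.4
        by = direct1 * g1 + via2 * g2 + rng.normal(0, 0.01, j)
        sy = np.full(j, 0.02)
        ests = mvmr_ivw(np.column_stack([g1, g2]), np.full((j, 2), 0.01), by, sy)
        uni = ivw_uncorrelated(hset(g1, by, sy))
        assert ests[0].beta < uni.beta
        assert ests[0].beta == pytest.approx(direct1, abs=3 * ests[0].se)


class TestPanelAgreement:
    def test_all_methods_agree_on_homogeneous_data(self):
        """When every ratio estimate equals θ exactly, IVW, Egger, median,
        mode and the PRESSO raw IVW coincide."""
        rng = np.random.default_rng(6)
        j, theta = 50, 0.25
        bx = np.abs(rng.normal(0.2, 0.03, j))
        by = theta * bx
        h = hset(bx, by, sy=np.full(j, 0.02))
        values = [
            ivw_uncorrelated(h).beta,
            egger(h).beta,
            weighted_median(h, n_boot=50, seed=0).beta,
            weighted_mode(h, n_boot=50, seed=0).beta,
            mr_presso(h, n_sim=200, seed=0).extras["raw_ivw_beta"],
        ]
        assert np.all(np.abs(np.array(values) - theta) < 2e-2)
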