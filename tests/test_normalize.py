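"""The six normalization methods: defining properties and small oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import rankdata

from regnorm.core import MAMatrix, ProbeCategory, compute_ma
from regnorm.evaluate import roc_auc
from regnorm.normalize import (
    lowess_normalize,
    peng_normalize,
    quantile_normalize,
    tbw_scale,
    tquantile_normalize,
    tukey_biweight,
    vsn_normalize,
)
from regnorm.simulate import SimulationConfig, simulate_experiment

from conftest import make_annotation, make_experiment


def _ma(M, A=None, ids=None):
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if A is None:
        A = np.full_like(M, 10.0)
    ids = ids or [f"a{j}" for j in range(M.shape[1])]
    return MAMatrix(M=M, A=np.asarray(A, dtype=float), array_ids=ids)


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------


class TestLowess:
    def test_zero_m_is_fixed_point(self, rng):
        n = 200
        ma = _ma(np.zeros(n), A=rng.normal(10, 1, n)[:, None])
        out = lowess_normalize(ma)
        np.testing.assert_allclose(out.M_norm, 0.0, atol=1e-12)

    def test_constant_m_removed(self, rng):
        n = 200
        ma = _ma(np.full(n, 0.7), A=rng.normal(10, 1, n)[:, None])
        out = lowess_normalize(ma)
        np.testing.assert_allclose(out.M_norm, 0.0, atol=1e-6)

    def test_quadratic_trend_removed_per_decile(self, rng):
        # injected M = 0.3*(A-10)^2 trend plus noise, no enrichment: after
        # detrending, every A-decile of M has mean within +/-0.02 of zero
        n = 5000
        a = rng.normal(10, 1, n)
        m = 0.3 * (a - 10) ** 2 + rng.normal(0, 0.1, n)
        # a finer span than the 0.3 default: strong curvature needs a more
        # local fit to keep the edge deciles unbiased
        out = lowess_normalize(_ma(m[:, None], A=a[:, None]), span=0.2)
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (a >= lo) & (a <= hi)
            assert abs(out.M_norm[sel, 0].mean()) < 0.02

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            lowess_normalize(_ma(np.zeros(5), A=np.arange(5.0)[:, None]))


# ---------------------------------------------------------------------------
# quantile / T-quantile
# ---------------------------------------------------------------------------


class TestQuantile:
    def test_three_value_toy_rankwise_means(self):
        # channels [2,4,6] and [3,5,7] -> both [2.5,4.5,6.5]
        exp = make_experiment([[4.0, 2.0, 6.0]], [[5.0, 3.0, 7.0]], make_annotation(3))
        out = quantile_normalize(exp)
        lg = out.A_norm - out.M_norm / 2.0
        lr = out.A_norm + out.M_norm / 2.0
        np.testing.assert_allclose(2.0**lg[:, 0], [4.5, 2.5, 6.5], atol=1e-12)
        np.testing.assert_allclose(2.0**lr[:, 0], [4.5, 2.5, 6.5], atol=1e-12)

    def test_identical_channels_unchanged(self):
        x = np.array([10.0, 20.0, 40.0, 80.0])
        exp = make_experiment([x], [x.copy()], make_annotation(4))
        out = quantile_normalize(exp)
        np.testing.assert_allclose(out.M_norm, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.A_norm[:, 0], np.log2(x), atol=1e-12)

    def test_all_channels_share_sorted_vector(self, rng):
        exp = make_experiment(
            [rng.lognormal(7, 1, 50) for _ in range(3)],
            [rng.lognormal(7.5, 1.2, 50) for _ in range(3)],
            make_annotation(50),
        )
        out = quantile_normalize(exp)
        lg = out.A_norm - out.M_norm / 2.0
        lr = out.A_norm + out.M_norm / 2.0
        channels = np.column_stack([lg, lr])
        ref = np.sort(channels[:, 0])
        for j in range(channels.shape[1]):
            np.testing.assert_allclose(np.sort(channels[:, j]), ref, atol=1e-12)

    def test_idempotent(self, rng):
        exp = make_experiment(
            [rng.lognormal(7, 1, 40) for _ in range(2)],
            [rng.lognormal(7, 1, 40) for _ in range(2)],
            make_annotation(40),
        )
        once = quantile_normalize(exp)
        twice = quantile_normalize(once.as_ma())
        np.testing.assert_allclose(twice.M_norm, once.M_norm, atol=1e-12)
        np.testing.assert_allclose(twice.A_norm, once.A_norm, atol=1e-12)


class TestTQuantile:
    def test_identical_arrays_unchanged(self, rng):
        g, r = rng.lognormal(7, 1, 30), rng.lognormal(7.5, 1, 30)
        exp = make_experiment([g, g.copy()], [r, r.copy()], make_annotation(30))
        out = tquantile_normalize(exp)
        np.testing.assert_allclose(out.M_norm[:, 0], np.log2(r) - np.log2(g), atol=1e-12)
        np.testing.assert_allclose(out.M_norm[:, 0], out.M_norm[:, 1], atol=1e-12)

    def test_single_array_rejected(self, rng):
        exp = make_experiment(
            [rng.lognormal(7, 1, 30)], [rng.lognormal(7, 1, 30)], make_annotation(30)
        )
        with pytest.raises(ValueError):
            tquantile_normalize(exp)

    def test_scaled_red_channels_equalized_auc_preserved(self, rng):
        # red_j = k_j * common red: after normalization all red channels are
        # equal and the control-vs-promoter AUC equals any raw array's
        n = 400
        ann = make_annotation(
            n,
            categories=[ProbeCategory.NEGATIVE_CONTROL] * 200 + [ProbeCategory.PROMOTER] * 200,
        )
        g = rng.lognormal(7, 1, n)
        r = rng.lognormal(7, 1, n) * np.concatenate([np.ones(200), np.full(200, 4.0)])
        exp = make_experiment([g, g.copy()], [r, 3.0 * r], ann)
        out = tquantile_normalize(exp)
        lr = out.A_norm + out.M_norm / 2.0
        np.testing.assert_allclose(lr[:, 0], lr[:, 1], atol=1e-12)
        neg, pos = ann.category_mask(ProbeCategory.NEGATIVE_CONTROL), ann.category_mask(
            ProbeCategory.PROMOTER
        )
        raw = compute_ma(exp)
        auc_raw = roc_auc(raw.M[neg, 0], raw.M[pos, 0]).auc
        auc_norm = roc_auc(out.M_norm[neg, 0], out.M_norm[pos, 0]).auc
        assert auc_norm == pytest.approx(auc_raw, abs=1e-12)

    def test_within_channel_ranks_preserved_sorted_vectors_shared(self, rng):
        exp = make_experiment(
            [rng.lognormal(7, 1, 60) for _ in range(3)],
            [rng.lognormal(8, 1.5, 60) for _ in range(3)],
            make_annotation(60),
        )
        out = tquantile_normalize(exp)
        lg = out.A_norm - out.M_norm / 2.0
        lr = out.A_norm + out.M_norm / 2.0
        for j in range(3):
            np.testing.assert_array_equal(
                rankdata(lg[:, j]), rankdata(exp.arrays[j].green)
            )
            np.testing.assert_array_equal(
                rankdata(lr[:, j]), rankdata(exp.arrays[j].red)
            )
            np.testing.assert_allclose(np.sort(lg[:, j]), np.sort(lg[:, 0]), atol=1e-12)
            np.testing.assert_allclose(np.sort(lr[:, j]), np.sort(lr[:, 0]), atol=1e-12)
        # red and green sorted vectors may differ from each other
        assert not np.allclose(np.sort(lg[:, 0]), np.sort(lr[:, 0]))

    def test_idempotent(self, rng):
        exp = make_experiment(
            [rng.lognormal(7, 1, 40) for _ in range(2)],
            [rng.lognormal(7, 1, 40) for _ in range(2)],
            make_annotation(40),
        )
        once = tquantile_normalize(exp)
        twice = tquantile_normalize(once.as_ma())
        np.testing.assert_allclose(twice.M_norm, once.M_norm, atol=1e-12)

    def test_quantile_can_change_m_ranks_tquantile_cannot(self):
        # constructed so pooling channels remaps M ranks: one array's red is
        # strongly compressed relative to its green
        g1 = np.array([100.0, 200.0, 400.0, 800.0])
        r1 = np.array([110.0, 190.0, 420.0, 780.0])
        g2 = np.array([100.0, 200.0, 400.0, 800.0])
        r2 = np.array([300.0, 310.0, 320.0, 330.0])
        exp = make_experiment([g1, g2], [r1, r2], make_annotation(4))
        raw = compute_ma(exp)
        q = quantile_normalize(exp)
        tq = tquantile_normalize(exp)
        assert not np.array_equal(rankdata(q.M_norm[:, 1]), rankdata(raw.M[:, 1]))
        for j in range(2):
            lg = tq.A_norm[:, j] - tq.M_norm[:, j] / 2.0
            lr = tq.A_norm[:, j] + tq.M_norm[:, j] / 2.0
            np.testing.assert_array_equal(rankdata(lg), rankdata(exp.arrays[j].green))
            np.testing.assert_array_equal(rankdata(lr), rankdata(exp.arrays[j].red))


# ---------------------------------------------------------------------------
# VSN-style
# ---------------------------------------------------------------------------


class TestVsn:
    def test_pure_scale_between_channels_absorbed(self, rng):
        x = rng.lognormal(6, 1, 50)
        exp = make_experiment([x], [3.0 * x], make_annotation(50))
        out = vsn_normalize(exp)
        assert np.abs(out.M_norm).max() < 1e-6

    def test_glog_identities(self):
        from regnorm.normalize import _glog2

        assert _glog2(np.array([0.0]))[0] == 0.0
        x = np.linspace(-5, 5, 101)
        assert np.all(np.diff(_glog2(x)) > 0)

    def test_transform_monotone_per_channel(self, rng):
        x = rng.lognormal(6, 1, 80)
        exp = make_experiment([x], [x * rng.lognormal(0, 0.1, 80)], make_annotation(80))
        out = vsn_normalize(exp)
        hg = out.A_norm[:, 0] - out.M_norm[:, 0] / 2.0
        order = np.argsort(x)
        assert np.all(np.diff(hg[order]) > -1e-12)

    def test_variance_stabilized_across_intensity_strata(self, rng):
        # additive + multiplicative noise replicates: the glog-transformed
        # replicate differences have near-constant sd across intensity
        # strata, unlike plain log2 which blows up at low intensity
        n = 4000
        t = rng.lognormal(5, 1.0, n)  # true abundances spanning the range
        sd_add, sd_mult = 30.0, 0.1
        ch1 = t * rng.lognormal(0, sd_mult, n) + rng.normal(0, sd_add, n)
        ch2 = t * rng.lognormal(0, sd_mult, n) + rng.normal(0, sd_add, n)
        eps = 1e-3
        exp = make_experiment(
            [np.maximum(ch1, eps)], [np.maximum(ch2, eps)], make_annotation(n)
        )
        out = vsn_normalize(exp)
        diff_glog = out.M_norm[:, 0]
        diff_log2 = np.log2(np.maximum(ch2, eps)) - np.log2(np.maximum(ch1, eps))
        strata = np.digitize(t, np.quantile(t, [0.2, 0.4, 0.6, 0.8]))
        sd_glog = np.array([diff_glog[strata == s].std(ddof=1) for s in range(5)])
        sd_log2 = np.array([diff_log2[strata == s].std(ddof=1) for s in range(5)])
        assert np.ptp(sd_glog) < 0.25 * sd_glog.mean()
        assert np.ptp(sd_log2) > 1.0 * sd_log2.mean()


# ---------------------------------------------------------------------------
# Tukey biweight / TBW scaling
# ---------------------------------------------------------------------------


class TestTukeyBiweight:
    def test_constant_vector_degenerate_mad(self):
        assert tukey_biweight(np.array([5.0, 5.0, 5.0])) == 5.0

    def test_symmetric_vector(self):
        assert tukey_biweight(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0, abs=1e-9)

    def test_outlier_case_matches_hand_iteration(self):
        # median 3, MAD 1, c=5: weights (0.7056, 0.9216, 1, 0.9216, 0),
        # first weighted mean 9.2352/3.5488 = 2.602344...
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        first = tukey_biweight(x, c=5.0, max_iter=1, tol=0.0)
        assert first == pytest.approx(9.2352 / 3.5488, abs=1e-10)

        # independent fixed-point oracle of the same weighting formula
        est, mad = 3.0, 1.0
        for _ in range(200):
            u = (x - est) / (5.0 * mad)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            new = float((w * x).sum() / w.sum())
            if abs(new - est) < 1e-12:
                break
            est = new
        assert tukey_biweight(x, c=5.0) == pytest.approx(est, abs=1e-5)

    def test_estimate_resists_outlier(self):
        assert abs(tukey_biweight(np.array([1.0, 2.0, 3.0, 4.0, 100.0])) - 2.6) < 0.1


class TestTbwScale:
    def test_centers_shifted_distribution(self, rng):
        m = rng.normal(0.7, 0.2, 500)
        out = tbw_scale(_ma(m))
        assert abs(np.median(out.M_norm)) < 0.05
        assert out.diagnostics["scale_factors"][0] == pytest.approx(0.7, abs=0.05)

    def test_per_array_auc_identical_to_raw(self, rng):
        n = 300
        neg = slice(0, 150)
        pos = slice(150, 300)
        M = np.column_stack(
            [rng.normal(0.5, 1, n), rng.normal(-0.3, 1, n)]
        )
        M[pos] += 1.0
        ma = _ma(M, A=np.full_like(M, 10.0))
        out = tbw_scale(ma)
        for j in range(2):
            assert roc_auc(out.M_norm[neg, j], out.M_norm[pos, j]).auc == pytest.approx(
                roc_auc(M[neg, j], M[pos, j]).auc, abs=1e-12
            )

    def test_identical_arrays_get_identical_constants(self, rng):
        m = rng.normal(0.2, 0.5, 100)
        out = tbw_scale(_ma(np.column_stack([m, m])))
        c1, c2 = out.diagnostics["scale_factors"]
        assert c1 == c2


# ---------------------------------------------------------------------------
# Peng
# ---------------------------------------------------------------------------


class TestPeng:
    def test_no_trend_limit_matches_plain_lowess(self, rng):
        n = 2000
        a = rng.normal(10, 1, n)
        m = rng.normal(0, 0.3, n)
        ma = _ma(m[:, None], A=a[:, None])
        out = peng_normalize(ma)
        ref = lowess_normalize(ma)
        assert abs(out.diagnostics["rotation_angles"][0]) < 0.05
        assert np.corrcoef(out.M_norm[:, 0], ref.M_norm[:, 0])[0, 1] > 0.99

    def test_rotation_zeroes_major_axis_slope(self, rng):
        from regnorm.normalize import _principal_slope

        n = 3000
        a = rng.normal(10, 1, n)
        m = 0.5 * a + rng.normal(0, 0.1, n)
        out = peng_normalize(_ma(m[:, None], A=a[:, None]))
        assert abs(_principal_slope(out.A_norm[:, 0], out.M_norm[:, 0])) < 0.01

    def test_rotation_is_isometry_of_centered_cloud(self, rng):
        n = 50
        a = rng.normal(10, 1, n)
        m = 0.3 * a + rng.normal(0, 0.2, n)
        ma = _ma(m[:, None], A=a[:, None])
        out = peng_normalize(ma, span=0.99)
        slope = np.tan(out.diagnostics["rotation_angles"][0])
        theta = -np.arctan(slope)
        ca, sa = np.cos(theta), np.sin(theta)
        a_rot = a.mean() + ca * (a - a.mean()) - sa * (m - m.mean())
        m_rot = m.mean() + sa * (a - a.mean()) + ca * (m - m.mean())
        d_orig = np.hypot(a[:, None] - a[None, :], m[:, None] - m[None, :])
        d_rot = np.hypot(a_rot[:, None] - a_rot[None, :], m_rot[:, None] - m_rot[None, :])
        np.testing.assert_allclose(d_rot, d_orig, atol=1e-10)
        assert out.M_norm.shape == (n, 1)

    def test_zero_variance_a_rejected(self):
        with pytest.raises(ValueError):
            peng_normalize(_ma(np.random.default_rng(0).normal(0, 1, 20)))


# ---------------------------------------------------------------------------
# cross-method invariants
# ---------------------------------------------------------------------------


def test_all_methods_preserve_shape_and_finiteness():
    cfg = SimulationConfig(
        n_arrays=3,
        n_tiling_probes=300,
        n_control_probes=150,
        n_promoter_probes=300,
        enriched_fraction=0.3,
        noise_sd=0.2,
        array_offset_sd=0.2,
        dye_trend_coeffs=(0.0, 0.05, 0.02),
        seed=11,
    )
    exp, _ = simulate_experiment(cfg)
    from regnorm.normalize import normalize

    for method in ["lowess", "quantile", "vsn", "tquantile", "tbw", "peng"]:
        out = normalize(exp, method)
        assert out.M_norm.shape == (750, 3)
        assert out.A_norm.shape == (750, 3)
        assert np.all(np.isfinite(out.M_norm))
        assert np.all(np.isfinite(out.A_norm))
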