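"""Agreement statistics: overlap ratio, Pearson, L1 regression, Bland-Altman."""

import numpy as np
import pytest

import cardiomap as cm
from cardiomap.compare import overlap_ratio, region_overlap
from cardiomap.errors import (ConfigurationError, UndefinedStatisticError)


class TestOverlapRatio:
    def test_identical_masks_give_unit_ratio_and_good_grade(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(0, 1, (8, 32)) > 0.6
        res = overlap_ratio(mask, mask)
        assert res.ratio == 1.0 and res.grade == "good"

    def test_disjoint_masks_give_zero_ratio(self):
        a = np.zeros((8, 32), bool)
        b = np.zeros((8, 32), bool)
        a[0, :5] = True
        b[4, :5] = True
        res = overlap_ratio(a, b)
        assert res.ratio == 0.0 and res.grade == "poor"

    def test_worked_pixel_count_example(self):
        # |A| = 30%, |B| = 40%, |A ∩ B| = 25% of a 100-cell surface
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a.ravel()[:30] = True
        b.ravel()[5:45] = True          # overlap cells 5..29 -> 25
        res = overlap_ratio(a, b)
        assert res.a_pct == 30.0 and res.b_pct == 40.0
        assert res.c_pct == 25.0 and res.d_pct == 25.0
        assert res.ratio == pytest.approx((25 + 25) / (30 + 40))

    def test_equals_dice_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.uniform(0, 1, (8, 32)) > rng.uniform(0.2, 0.8)
            b = rng.uniform(0, 1, (8, 32)) > rng.uniform(0.2, 0.8)
            if not (a.any() or b.any()):
                continue
            dice = 2 * (a & b).sum() / (a.sum() + b.sum())
            assert overlap_ratio(a, b).ratio == pytest.approx(dice, abs=1e-12)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (8, 32)) > 0.5
        b = rng.uniform(0, 1, (8, 32)) > 0.7
        assert overlap_ratio(a, b).ratio == overlap_ratio(b, a).ratio

    def test_empty_regions_rejected(self):
        z = np.zeros((4, 4), bool)
        with pytest.raises(UndefinedStatisticError):
            overlap_ratio(z, z)

    def test_region_definitions_partition(self, exact_model):
        # transmural + non-transmural region cells = combined region cells
        ph = cm.make_phantom(seed=13)
        tmap = cm.TransmuralityPolarMap(
            values=ph.transmurality_field,
            valid=np.ones_like(ph.transmurality_field, bool))
        bmap = cm.build_polar_map(cm.dense_sample_points(ph, exact_model),
                                  "bipv", fibrous_ring_frac=0.0)
        res = {r: region_overlap(tmap, bmap, r)
               for r in ("transmural", "non_transmural", "combined")}
        assert res["transmural"].b_pct + res["non_transmural"].b_pct == \
            pytest.approx(res["combined"].b_pct)
        assert res["transmural"].a_pct + res["non_transmural"].a_pct == \
            pytest.approx(res["combined"].a_pct)

    def test_unknown_region_rejected(self):
        tmap = cm.TransmuralityPolarMap(values=np.zeros((2, 4)),
                                        valid=np.ones((2, 4), bool))
        bmap = cm.PolarMap(values=np.zeros((2, 4)),
                           valid=np.ones((2, 4), bool), kind="bipolar_mV")
        with pytest.raises(ConfigurationError):
            region_overlap(tmap, bmap, "everything")


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = cm.pearson_with_grade(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.grade == "large"

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10000)
        y = rng.standard_normal(10000)
        res = cm.pearson_with_grade(x, y)
        assert abs(res.r) < 0.03
        assert res.grade == "negligible"

    def test_grade_bands_follow_magnitude(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal(40)
            y = 0.5 * x + rng.standard_normal(40)
            res = cm.pearson_with_grade(x, y)
            mag = abs(res.r)
            expected = ("large" if mag > 0.5 else "moderate" if mag > 0.3
                        else "small" if mag > 0.1 else "negligible")
            assert res.grade == expected

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cm.pearson_with_grade([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRobustLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 5, 7)
        fit = cm.robust_linear_fit(x, 3 * x - 2)
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-2.0, abs=1e-9)

    def test_resists_single_gross_outlier(self):
        x = np.arange(10.0)
        y = x.copy()
        y[3] += 100.0
        fit = cm.robust_linear_fit(x, y)
        assert fit.slope == pytest.approx(1.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_two_points_interpolated_exactly(self):
        fit = cm.robust_linear_fit([0.0, 2.0], [1.0, 5.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_matches_statsmodels_lad(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 30)
        y = 1.7 * x - 3.0 + rng.standard_normal(30)
        fit = cm.robust_linear_fit(x, y)
        qr = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
        assert fit.slope == pytest.approx(qr.params[1], abs=2e-3)
        assert fit.intercept == pytest.approx(qr.params[0], abs=2e-2)

    def test_constant_x_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cm.robust_linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 4.0, 9.0])
        res = cm.bland_altman(x, x)
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0
        assert res.lower_limit == 0.0 and res.upper_limit == 0.0

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0])
        res = cm.bland_altman(y + 5.0, y)
        assert res.mean_diff == pytest.approx(5.0)
        assert res.sd_diff == 0.0

    def test_matches_direct_formula_on_random_pairs(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 40, 60)
        y = rng.uniform(0, 40, 60)
        res = cm.bland_altman(x, y)
        d = x - y
        assert res.mean_diff == pytest.approx(d.mean())
        assert res.sd_diff == pytest.approx(d.std(ddof=1))
        assert res.upper_limit == pytest.approx(d.mean() + 2 * d.std(ddof=1))
        assert res.half_width == pytest.approx(2 * d.std(ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])
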