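"""Voltage polar maps: construction, classification, calibration, ROC."""

import numpy as np
import pandas as pd
import pytest

import cardiomap as cm
from cardiomap import geometry
from cardiomap.errors import (ConfigurationError, EmptyMapError,
                              UndefinedStatisticError)
from cardiomap.noga import roc_bipv_cutoff, threshold_sweep


def point_frame(rows):
    df = pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "upv_mV",
                                     "bipv_mV"])
    df["stable"] = True
    for col in ("slice_idx", "sector_idx", "slice_frac", "theta_rad"):
        df[col] = 0
    return df


class TestBuildPolarMap:
    def test_single_point_reach_defines_validity(self):
        # one point at a known surface position: exactly the cells within
        # 15 mm of it are valid (plus nothing else)
        xyz = geometry.surface_xyz(0.3, 1.0, 20.0, 64.0)
        pts = point_frame([[xyz[0], xyz[1], xyz[2], 12.0, 1.2]])
        pmap = cm.build_polar_map(pts, "bipv", connect_mm=15.0,
                                  fibrous_ring_frac=0.0)
        s, k = np.divmod(np.arange(256), 32)
        cells = geometry.surface_xyz(geometry.cell_polar_radius(s, 8),
                                     geometry.cell_angle(k, 32), 20.0, 64.0)
        d = np.linalg.norm(cells - xyz, axis=1).reshape(8, 32)
        np.testing.assert_array_equal(pmap.valid, d < 15.0)
        assert np.allclose(pmap.values[pmap.valid], 1.2)

    def test_dense_noisefree_sampling_reproduces_model(self, exact_model):
        ph = cm.make_phantom(seed=5)
        pts = cm.dense_sample_points(ph, exact_model)
        pmap = cm.build_polar_map(pts, "bipv", fibrous_ring_frac=0.0)
        expected = exact_model.bipv(ph.transmurality_field)
        assert np.abs(pmap.values - expected).max() <= 0.01
        assert pmap.valid.all()

    def test_default_point_count_covers_every_cell(self, default_phantom):
        pts = cm.sample_noga_points(default_phantom, n_points=202, seed=3)
        pmap = cm.build_polar_map(pts, "upv", fibrous_ring_frac=0.0)
        assert pmap.valid.all()

    def test_fibrous_ring_annulus_excluded(self, default_phantom):
        pts = cm.sample_noga_points(default_phantom, seed=3)
        pmap = cm.build_polar_map(pts, "upv", fibrous_ring_frac=0.10)
        assert not pmap.valid[-1].any()          # basal ring inside the annulus
        assert pmap.valid[:-1].any()

    def test_unstable_points_ignored(self, default_phantom):
        pts = cm.sample_noga_points(default_phantom, seed=3)
        pts.loc[:, "stable"] = False
        with pytest.raises(EmptyMapError):
            cm.build_polar_map(pts, "bipv")

    def test_unknown_field_rejected(self, default_phantom):
        pts = cm.sample_noga_points(default_phantom, seed=3)
        with pytest.raises(ConfigurationError):
            cm.build_polar_map(pts, "impedance")


class TestClassifyVoltage:
    @staticmethod
    def uniform_map(value, kind="unipolar_mV"):
        return cm.PolarMap(values=np.full((8, 32), float(value)),
                           valid=np.ones((8, 32), bool), kind=kind)

    def test_unipolar_examples(self):
        cls = cm.classify_voltage(self.uniform_map(4.9), cm.UNIPOLAR_THRESHOLDS)
        assert cls.area_fractions["infarct"] == 100.0
        cls = cm.classify_voltage(self.uniform_map(20.0), cm.UNIPOLAR_THRESHOLDS)
        assert cls.area_fractions == {"normal": 100.0, "border": 0.0,
                                      "infarct": 0.0}

    def test_bipolar_examples(self):
        cls = cm.classify_voltage(self.uniform_map(2.0, "bipolar_mV"),
                                  cm.BIPOLAR_THRESHOLDS)
        assert cls.area_fractions["normal"] == 100.0

    @pytest.mark.parametrize("value,thresholds,expected", [
        (5.0, cm.UNIPOLAR_THRESHOLDS, "border"),
        (15.0, cm.UNIPOLAR_THRESHOLDS, "border"),
        (0.8, cm.BIPOLAR_THRESHOLDS, "non_transmural"),
        (1.9, cm.BIPOLAR_THRESHOLDS, "non_transmural"),
    ])
    def test_boundary_values_fall_in_middle_band(self, value, thresholds,
                                                 expected):
        kind = thresholds.modality
        cls = cm.classify_voltage(self.uniform_map(value, kind), thresholds)
        assert cls.area_fractions[expected] == 100.0

    def test_fractions_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        pmap = cm.PolarMap(values=rng.uniform(0, 25, (8, 32)),
                           valid=rng.uniform(0, 1, (8, 32)) > 0.3,
                           kind="unipolar_mV")
        cls = cm.classify_voltage(pmap, cm.UNIPOLAR_THRESHOLDS)
        assert sum(cls.area_fractions.values()) == pytest.approx(100.0)

    def test_widening_infarct_band_never_shrinks_infarct_area(self):
        rng = np.random.default_rng(3)
        pmap = cm.PolarMap(values=rng.uniform(0, 4, (8, 32)),
                           valid=np.ones((8, 32), bool), kind="bipolar_mV")
        narrow = cm.classify_voltage(pmap, cm.VoltageThresholds(
            "bipolar_mV", 0.6, 1.9, cm.BIPOLAR_THRESHOLDS.class_names))
        wide = cm.classify_voltage(pmap, cm.VoltageThresholds(
            "bipolar_mV", 1.0, 1.9, cm.BIPOLAR_THRESHOLDS.class_names))
        assert wide.area_fractions["transmural"] >= narrow.area_fractions["transmural"]

    def test_modality_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.classify_voltage(self.uniform_map(1.0, "bipolar_mV"),
                                cm.UNIPOLAR_THRESHOLDS)


class TestThresholdSweep:
    def test_area_monotone_in_threshold(self, noisefree_cohort):
        _, tmaps, bmaps = noisefree_cohort
        sweep = threshold_sweep(bmaps[:5], tmaps[:5])
        assert (np.diff(sweep.noga_areas, axis=1) >= 0).all()

    def test_anchor_recovery_at_core_level(self, noisefree_cohort):
        _, tmaps, bmaps = noisefree_cohort
        step = 1.0 / 99.0
        for mode in ("areas", "cells"):
            sweep = threshold_sweep(bmaps, tmaps, mode=mode)
            assert sweep.best_cutoff_mV[75] == pytest.approx(0.80, abs=step + 1e-9)
            assert not sweep.saturated[75]

    def test_out_of_range_anchor_saturates_at_boundary(self, noisefree_cohort):
        # the 25% anchor lies at 1.9 mV, outside the 0.5-1.5 sweep window
        _, tmaps, bmaps = noisefree_cohort
        sweep = threshold_sweep(bmaps, tmaps, mode="cells")
        assert sweep.best_cutoff_mV[25] == pytest.approx(1.5)
        assert sweep.saturated[25]

    def test_constant_maps_rejected(self):
        values = np.full((8, 32), 1.0)
        bmap = cm.PolarMap(values=values, valid=np.ones_like(values, bool),
                           kind="bipolar_mV")
        tmap = cm.TransmuralityPolarMap(values=np.full((8, 32), 0.5),
                                        valid=np.ones_like(values, bool))
        with pytest.raises(UndefinedStatisticError):
            threshold_sweep([bmap, bmap], [tmap, tmap])


class TestROC:
    def test_worked_four_point_example(self):
        pts = point_frame([
            [0, 0, 0, 1.0, 0.3],    # non-viable (UPV < 5)
            [0, 0, 0, 2.0, 0.9],    # non-viable
            [0, 0, 0, 9.0, 1.2],    # viable
            [0, 0, 0, 20.0, 2.5],   # viable
        ])
        roc = roc_bipv_cutoff(pts, n_bootstrap=200, seed=0)
        assert roc.auc == pytest.approx(1.0)
        row = roc.table.iloc[(roc.table.cutoff_mV - 1.0).abs().idxmin()]
        assert row.sensitivity == pytest.approx(1.0)
        assert row.specificity == pytest.approx(1.0)

    def test_separated_classes_give_unit_auc(self):
        rng = np.random.default_rng(0)
        n = 200
        upv = np.concatenate([rng.uniform(0, 4, n), rng.uniform(6, 20, n)])
        bipv = np.concatenate([rng.uniform(0.05, 0.7, n), rng.uniform(2, 5, n)])
        pts = point_frame(np.column_stack(
            [np.zeros((2 * n, 3)), upv, bipv]).tolist())
        roc = roc_bipv_cutoff(pts, n_bootstrap=100, seed=1)
        assert roc.auc == pytest.approx(1.0)
        assert roc.auc_ci95[0] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        pts = point_frame([[0, 0, 0, 20.0, 2.0], [0, 0, 0, 18.0, 2.5]])
        with pytest.raises(UndefinedStatisticError):
            roc_bipv_cutoff(pts)
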