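"""Late-enhancement pipeline: 2SD segmentation, volume, transmurality maps."""

import numpy as np
import pytest

import cardiomap as cm
from cardiomap.errors import (ConfigurationError, InvalidReferenceError,
                              UndefinedStatisticError)
from cardiomap.mri import SCHEMES, classify_transmurality, transmurality_map
from cardiomap.phantom import SliceStack


def annulus_stack(n=41, r_endo=9.5, r_epi=19.5, scar_radius=None, value=100.0):
    """Single-plane circular stack with an optional scar annulus from the endo."""
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n] - c
    rho = np.hypot(xx, yy)
    endo = rho < r_endo
    epi = rho < r_epi
    myo = epi & ~endo
    vox = np.where(myo, value, 0.0)
    stack = SliceStack(voxels=vox[None], voxel_mm=(8.0, 1.0, 1.0),
                       endo_mask=endo[None], epi_mask=epi[None],
                       remote_mask=myo[None], n_slices=1)
    scar = (myo & (rho < scar_radius))[None] if scar_radius else np.zeros_like(myo)[None]
    return stack, scar


class TestSegment2SD:
    def test_threshold_is_remote_mean_plus_two_sample_sd(self):
        # remote {90, 100, 110}: mean 100, sd 10 -> threshold 120
        vox = np.zeros((1, 3, 3))
        vox[0, 0] = [90.0, 100.0, 110.0]
        vox[0, 1] = [121.0, 119.0, 120.0]
        myo = np.ones((1, 3, 3), bool)
        stack = SliceStack(voxels=vox, voxel_mm=(8, 1, 1),
                           endo_mask=np.zeros_like(myo), epi_mask=myo,
                           remote_mask=np.zeros_like(myo), n_slices=1)
        stack.remote_mask[0, 0] = True
        scar = cm.segment_2sd(stack)
        assert scar[0, 1, 0] and not scar[0, 1, 1] and not scar[0, 1, 2]

    def test_uniform_stack_yields_empty_mask(self):
        stack, _ = annulus_stack()
        assert not cm.segment_2sd(stack).any()

    def test_tiny_remote_region_rejected(self):
        stack, _ = annulus_stack()
        stack.remote_mask[:] = False
        with pytest.raises(InvalidReferenceError):
            cm.segment_2sd(stack)

    def test_never_tags_outside_myocardium(self, default_phantom):
        stack = cm.render_mri_stack(default_phantom, seed=8)
        scar = cm.segment_2sd(stack)
        assert not (scar & ~stack.myocardium_mask).any()

    def test_recovers_ground_truth_scar(self, default_phantom):
        stack = cm.render_mri_stack(default_phantom, seed=8)
        scar = cm.segment_2sd(stack)
        truth = stack.true_scar_mask
        dice = 2 * (scar & truth).sum() / (scar.sum() + truth.sum())
        assert dice >= 0.95


class TestInfarctVolume:
    def test_volume_arithmetic(self):
        stack, _ = annulus_stack()
        scar = np.zeros_like(stack.voxels, bool)
        myo = stack.myocardium_mask
        idx = np.argwhere(myo)[:100]
        scar[tuple(idx.T)] = True
        vol = cm.infarct_volume(scar, stack)
        assert vol.ml == pytest.approx(100 * 8.0 / 1000.0)

    def test_empty_scar_is_zero(self):
        stack, _ = annulus_stack()
        vol = cm.infarct_volume(np.zeros_like(stack.voxels, bool), stack)
        assert vol.ml == 0.0 and vol.percent_of_myocardium == 0.0

    def test_noisefree_percent_matches_analytic_integral(self, default_phantom,
                                                         noisefree_stack):
        vol = cm.infarct_volume(cm.segment_2sd(noisefree_stack), noisefree_stack)
        analytic = 100.0 * default_phantom.analytic_scar_volume_fraction()
        assert vol.percent_of_myocardium == pytest.approx(analytic, abs=1.0)


class TestTransmuralityMap:
    def test_full_thickness_sector_is_exactly_one(self):
        stack, _ = annulus_stack()
        scar = stack.myocardium_mask.copy()
        for method in ("rank", "rays"):
            tmap = transmurality_map(scar, stack, n_slices=1, n_sectors=4,
                                     method=method, rays_per_sector=1,
                                     sector_origin_deg=-45.0)
            assert (tmap.values == 1.0).all()

    def test_half_thickness_sector_is_exactly_half(self):
        # boundaries on half-integers, rays along the axes: exact counts
        stack, scar = annulus_stack(r_endo=9.5, r_epi=19.5, scar_radius=14.5)
        tmap = transmurality_map(scar, stack, n_slices=1, n_sectors=4,
                                 method="rays", rays_per_sector=1,
                                 sector_origin_deg=-45.0)
        assert (tmap.values == 0.5).all()

    def test_matches_brute_force_ray_oracle(self):
        """Hand-built 3-sector scar vs an independent per-ray oracle."""
        stack, _ = annulus_stack(n=61, r_endo=12.5, r_epi=27.5)
        c = 61 // 2
        yy, xx = np.mgrid[0:61, 0:61] - c
        rho = np.hypot(xx, yy)
        theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
        sec = np.minimum((theta / (2 * np.pi) * 3).astype(int), 2)
        depth_frac = np.select([sec == 0, sec == 1, sec == 2], [0.3, 0.8, 0.0])
        myo = stack.myocardium_mask[0]
        scar = (myo & (rho - 12.5 < depth_frac * 15.0) & (depth_frac > 0))[None]

        tmap = transmurality_map(scar, stack, n_slices=1, n_sectors=3,
                                 method="rays", rays_per_sector=7,
                                 radial_step_frac=0.25)

        # independent oracle: walk outward voxel-by-voxel on each of 7 rays
        expected = np.zeros(3)
        for k in range(3):
            vals = []
            for j in range(7):
                ang = (k + (j + 0.5) / 7) * 2 * np.pi / 3
                wall = scarred = 0
                for r in np.arange(0.125, 31, 0.25):
                    i0 = int(np.floor(c + r * np.sin(ang) + 0.5))
                    j0 = int(np.floor(c + r * np.cos(ang) + 0.5))
                    if not (0 <= i0 < 61 and 0 <= j0 < 61) or not myo[i0, j0]:
                        continue
                    wall += 1
                    scarred += bool(scar[0, i0, j0])
                vals.append(scarred / wall)
            expected[k] = np.mean(vals)
        np.testing.assert_allclose(tmap.values[0], expected, atol=1e-12)

    def test_recovers_phantom_field_noisefree(self, default_phantom,
                                              noisefree_stack):
        tmap = transmurality_map(cm.segment_2sd(noisefree_stack), noisefree_stack)
        err = np.abs(tmap.values - default_phantom.transmurality_field)
        assert err.max() <= 0.05

    def test_empty_sectors_marked_invalid(self):
        stack, scar = annulus_stack()
        stack.epi_mask[0, :, :20] = False   # amputate half the ring
        stack.endo_mask[0, :, :20] = False
        tmap = transmurality_map(scar, stack, n_slices=1, n_sectors=8)
        assert not tmap.valid.all() and tmap.valid.any()


class TestClassifyTransmurality:
    def test_band_membership_follows_printed_inequalities(self):
        values = np.array([[0.80, 0.55, 0.10, 0.25, 0.50, 0.75]])
        tmap = cm.TransmuralityPolarMap(values=values,
                                        valid=np.ones_like(values, bool))
        c1 = classify_transmurality(tmap, "25-50-75")
        names = [c1.scheme.class_names[i] for i in c1.labels[0]]
        assert names == ["transmural", "border", "normal",
                         "non_transmural", "non_transmural", "border"]
        c2 = classify_transmurality(tmap, "30-60")
        names = [c2.scheme.class_names[i] for i in c2.labels[0]]
        assert names == ["transmural", "non_transmural", "normal",
                         "normal", "non_transmural", "transmural"]

    def test_all_normal_map(self):
        values = np.full((4, 8), 0.10)
        tmap = cm.TransmuralityPolarMap(values=values,
                                        valid=np.ones_like(values, bool))
        cls = classify_transmurality(tmap, "25-50-75")
        assert cls.area_fractions["normal"] == 100.0
        assert sum(v for k, v in cls.area_fractions.items() if k != "normal") == 0.0

    def test_fractions_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (8, 32))
        valid = rng.uniform(0, 1, (8, 32)) > 0.2
        tmap = cm.TransmuralityPolarMap(values=values, valid=valid)
        for scheme in SCHEMES:
            cls = classify_transmurality(tmap, scheme)
            assert sum(cls.area_fractions.values()) == pytest.approx(100.0)

    def test_monotone_in_values(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 0.9, (8, 32))
        valid = np.ones((8, 32), bool)
        lo = classify_transmurality(
            cm.TransmuralityPolarMap(values=values, valid=valid), "25-50-75")
        hi = classify_transmurality(
            cm.TransmuralityPolarMap(values=np.clip(values + 0.1, 0, 1),
                                     valid=valid), "25-50-75")
        assert hi.area_fractions["transmural"] >= lo.area_fractions["transmural"]

    def test_unknown_scheme_rejected(self):
        tmap = cm.TransmuralityPolarMap(values=np.zeros((2, 4)),
                                        valid=np.ones((2, 4), bool))
        with pytest.raises(ConfigurationError):
            classify_transmurality(tmap, "10-90")

    def test_schemes_tile_the_percentage_axis(self):
        v = np.linspace(0, 100, 2001)
        for scheme in SCHEMES.values():
            idx = scheme.classify(v)
            assert idx.min() == 0 and idx.max() == len(scheme.class_names) - 1
            assert (np.diff(idx) >= 0).all()

    def test_no_valid_cells_rejected(self):
        tmap = cm.TransmuralityPolarMap(values=np.zeros((2, 4)),
                                        valid=np.zeros((2, 4), bool))
        with pytest.raises(UndefinedStatisticError):
            classify_transmurality(tmap)
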