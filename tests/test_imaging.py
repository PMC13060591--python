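"""Projection, thresholding, having/not-having myelination, densities and
coassociation."""

import numpy as np
import pytest
from skimage.draw import disk

from tntsim import (
    ThresholdSpec,
    axon_density,
    binarize,
    capillary_density,
    coassociation,
    gen_nerve_image,
    max_project,
    myelination_fraction,
    quantify_bundle,
)
from tntsim.errors import ConfigurationError, InputError


def _discs(centres, radius, shape=(120, 120)):
    m = np.zeros(shape, dtype=bool)
    for c in centres:
        rr, cc = disk(c, radius, shape=shape)
        m[rr, cc] = True
    return m


SQUARE_ROI = np.array([[5.0, 5.0], [115.0, 5.0], [115.0, 115.0], [5.0, 115.0]])


class TestMaxProject:
    def test_single_plane_unchanged(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(max_project(img), img)
        assert np.array_equal(max_project(img[None]), img)

    def test_disjoint_bright_spots_union(self):
        a = np.zeros((10, 10)); a[2, 2] = 5.0
        b = np.zeros((10, 10)); b[7, 7] = 3.0
        out = max_project(np.stack([a, b]))
        assert out[2, 2] == 5.0 and out[7, 7] == 3.0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.random((4, 15, 15))
        out = max_project(stack)
        for i in range(15):
            for j in range(15):
                assert out[i, j] == max(stack[z, i, j] for z in range(4))

    def test_empty_stack_rejected(self):
        with pytest.raises(InputError):
            max_project(np.zeros((0, 5, 5)))


class TestBinarize:
    def test_threshold_above_max_gives_empty_mask(self):
        img = np.random.default_rng(0).random((10, 10))
        assert not binarize(img, ThresholdSpec("manual", value=2.0)).any()

    def test_threshold_zero_on_nonnegative_gives_full_mask(self):
        img = np.abs(np.random.default_rng(0).random((10, 10)))
        assert binarize(img, ThresholdSpec("manual", value=0.0)).all()

    def test_otsu_recovers_bimodal_ground_truth(self):
        rng = np.random.default_rng(1)
        truth = _discs([(30, 30), (80, 80), (50, 90)], 8)
        img = np.where(truth, 200.0, 0.0) + rng.poisson(2.0, truth.shape)
        mask = binarize(img)  # automatic, no reference -> Otsu
        mismatch = np.count_nonzero(mask != truth) / truth.size
        assert mismatch < 0.01

    def test_reference_mean_plus_k_sd(self):
        ref = np.full((10, 10), 1.0)  # sd 0 -> threshold = 1
        img = np.array([[0.5, 1.0], [1.5, 2.0]])
        mask = binarize(img, ThresholdSpec("automatic", reference=ref))
        assert mask.tolist() == [[False, True], [True, True]]

    def test_manual_without_value_rejected(self):
        with pytest.raises(ConfigurationError):
            ThresholdSpec("manual")


class TestMyelinationFraction:
    def test_identical_masks_fully_myelinated(self):
        nf = _discs([(30, 30), (80, 80)], 5)
        res = myelination_fraction(nf, nf.copy())
        assert res.pct_myelinated == 100.0
        assert res.pct_unmyelinated == 0.0

    def test_disjoint_masks_fully_unmyelinated(self):
        nf = _discs([(30, 30)], 5)
        mbp = _discs([(80, 80)], 5)
        res = myelination_fraction(nf, mbp)
        assert res.pct_myelinated == 0.0

    def test_generator_ground_truth_recovered(self):
        bundle, truth = gen_nerve_image(n_axons=50, n_myelinated=20, n_vessels=0,
                                        seed=5)
        nf = binarize(bundle.channels["NF"])
        mbp = binarize(bundle.channels["MBP"])
        res = myelination_fraction(nf, mbp)
        assert res.n_axons == 50
        assert res.n_myelinated == 20
        assert res.pct_myelinated == pytest.approx(40.0)
        assert res.pct_unmyelinated == pytest.approx(60.0)

    def test_zero_axons_flagged_not_raised(self):
        res = myelination_fraction(np.zeros((20, 20), bool), np.zeros((20, 20), bool))
        assert res.flagged_empty
        assert res.pct_myelinated is None

    def test_percent_pair_partitions_axon_count(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            n_ax = int(rng.integers(3, 20))
            n_my = int(rng.integers(0, n_ax + 1))
            bundle, _ = gen_nerve_image(n_axons=n_ax, n_myelinated=n_my,
                                        n_vessels=0, shape=(256, 256),
                                        roi_area_mm2=0.02, seed=seed)
            res = myelination_fraction(binarize(bundle.channels["NF"]),
                                       binarize(bundle.channels["MBP"]))
            assert res.pct_myelinated + res.pct_unmyelinated == pytest.approx(100.0)


class TestDensities:
    def test_axon_density_arithmetic(self):
        # 10 axons in a square ROI scaled to exactly 0.1 mm^2
        centres = [(20 + 10 * i, 60) for i in range(10)]
        nf = _discs(centres, 3, shape=(200, 200))
        side_px = np.sqrt(0.1e6)  # at 1 um/px
        roi = np.array([[0, 0], [side_px, 0], [side_px, side_px], [0, side_px]])
        assert axon_density(nf, roi, pixel_size=1.0) == pytest.approx(100.0)

    def test_empty_mask_zero_density(self):
        assert axon_density(np.zeros((50, 50), bool), SQUARE_ROI, 1.0) == 0.0

    def test_degenerate_roi_rejected(self):
        with pytest.raises(InputError):
            axon_density(np.zeros((50, 50), bool),
                         np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), 1.0)

    def test_density_scales_inverse_square_of_pixel_size(self):
        nf = _discs([(30, 30), (60, 60), (90, 90)], 4)
        d1 = axon_density(nf, SQUARE_ROI, pixel_size=1.0)
        d2 = axon_density(nf, SQUARE_ROI, pixel_size=0.5)
        assert d2 == pytest.approx(4 * d1)

    def test_capillary_requires_dapi_confirmation(self):
        cd31 = _discs([(30, 30), (80, 80)], 5)
        dapi = _discs([(30, 30)], 2)  # only the first vessel has a nucleus
        d_all = capillary_density(cd31, _discs([(30, 30), (80, 80)], 2),
                                  SQUARE_ROI, 1.0)
        d_one = capillary_density(cd31, dapi, SQUARE_ROI, 1.0)
        d_none = capillary_density(cd31, np.zeros_like(dapi), SQUARE_ROI, 1.0)
        assert d_none == 0.0
        assert d_one == pytest.approx(d_all / 2)

    def test_capillary_density_generator_exact(self):
        bundle, truth = gen_nerve_image(n_axons=0, n_myelinated=0, n_vessels=12,
                                        seed=3)
        cd31 = binarize(bundle.channels["CD31"])
        dapi = binarize(bundle.channels["DAPI"])
        d = capillary_density(cd31, dapi, bundle.rois["fascicle"], bundle.pixel_size)
        assert d == pytest.approx(12 / 0.1)

    def test_translation_invariance(self):
        bundle, _ = gen_nerve_image(n_axons=10, n_myelinated=4, n_vessels=3,
                                    shape=(256, 256), roi_area_mm2=0.02, seed=9)
        nf = binarize(bundle.channels["NF"])
        roi = bundle.rois["fascicle"]
        base = axon_density(nf, roi, 1.0)
        shifted = axon_density(np.roll(nf, (7, -5), axis=(0, 1)),
                               roi + np.array([-5.0, 7.0]), 1.0)
        assert shifted == pytest.approx(base)


class TestCoassociation:
    def test_identical_markers_full_coassociation(self):
        a = _discs([(30, 30), (80, 80)], 5)
        for den in ("A", "B", "union"):
            assert coassociation(a, a.copy(), denominator=den).pct == 100.0

    def test_disjoint_markers_zero(self):
        a = _discs([(30, 30)], 5)
        b = _discs([(80, 80)], 5)
        assert coassociation(a, b).pct == 0.0

    def test_known_double_positive_fraction(self):
        # 10 A-cells, 3 of them also B-positive -> 30% with denominator A
        a_centres = [(15 + 10 * i, 40) for i in range(10)]
        a = _discs(a_centres, 3)
        b = _discs(a_centres[:3], 3)
        res = coassociation(a, b, denominator="A")
        assert res.pct == pytest.approx(30.0)
        assert res.n_double_positive == 3

    def test_empty_denominator_flagged(self):
        res = coassociation(np.zeros((20, 20), bool), np.zeros((20, 20), bool))
        assert res.flagged_empty and res.pct is None

    def test_generator_gfp_cd31_recovery(self):
        bundle, truth = gen_nerve_image(n_axons=0, n_myelinated=0, n_vessels=8,
                                        gfp_vessel_fraction=0.5, n_gfp_only=4,
                                        seed=21)
        res = coassociation(binarize(bundle.channels["GFP"]),
                            binarize(bundle.channels["CD31"]),
                            binarize(bundle.channels["DAPI"]),
                            denominator="A")
        assert res.n_denominator == truth.n_gfp == 8
        assert res.pct == pytest.approx(100.0 * truth.n_gfp_vessels / truth.n_gfp)


class TestQuantifyBundle:
    def test_full_panel_on_generated_image(self):
        bundle, truth = gen_nerve_image(n_axons=30, n_myelinated=12, n_vessels=6,
                                        gfp_vessel_fraction=0.5, n_gfp_only=3,
                                        seed=13)
        q = quantify_bundle(bundle)
        assert q.axon_count == 30
        assert q.pct_myelinated == pytest.approx(40.0)
        assert q.axons_per_mm2 == pytest.approx(30 / 0.1)
        assert q.capillaries_per_mm2 == pytest.approx(6 / 0.1)
        assert q.coassociation_pct == pytest.approx(50.0)
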