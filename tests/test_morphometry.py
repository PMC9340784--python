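"""Tubule labeling, measurement, and the Gravelius circularity filter."""

import math

import numpy as np
import pytest
from skimage import draw

from gonadquant import (
    filter_circular,
    generate_phantom,
    gravelius,
    label_tubules,
    measure,
    measure_mask,
    representativeness,
)
from gonadquant.morphometry import TubuleRecord

from conftest import native_spec


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def raster_ellipse(a, b, angle=0.0, pad=5):
    size = int(2 * max(a, b)) + 2 * pad
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.ellipse(size / 2, size / 2, a, b, rotation=angle)
    mask[rr, cc] = True
    return mask


def record(k):
    """Stub record with a given Gravelius K."""
    return TubuleRecord(
        label=0, area_px=100, area_um2=100.0, perimeter_px=10.0, perimeter_um=10.0,
        circularity=1.0 / k**2, major_axis_px=1.0, minor_axis_px=1.0,
        gravelius_k=k, centroid=(0.0, 0.0), touches_border=False,
    )


class TestGravelius:
    def test_circle_identity_exact(self):
        r = 3.7
        assert gravelius(2 * math.pi * r, math.pi * r**2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b,expected",
        [(2.0, 1.0, 1.090), (8.0, 1.0, 1.842)],
    )
    def test_analytic_ellipses(self, a, b, expected):
        p = ramanujan_perimeter(a, b)
        assert gravelius(p, math.pi * a * b) == pytest.approx(expected, abs=0.001)

    @pytest.mark.parametrize("p,a", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, p, a):
        with pytest.raises(ValueError):
            gravelius(p, a)

    def test_k_is_inverse_root_circularity(self):
        recs = measure_mask(raster_ellipse(60, 30), 1.0)
        r = recs[0]
        assert r.gravelius_k == pytest.approx(1.0 / math.sqrt(r.circularity), rel=1e-9)


class TestMeasure:
    def test_disk_circularity_and_k(self):
        recs = measure_mask(raster_ellipse(50, 50), 1.0)
        assert len(recs) == 1
        assert 0.95 <= recs[0].circularity <= 1.02
        assert 0.98 <= recs[0].gravelius_k <= 1.05

    def test_disk_k_converges_with_radius(self):
        recs = measure_mask(raster_ellipse(100, 100), 1.0)
        assert recs[0].gravelius_k == pytest.approx(1.0, abs=0.02)

    def test_ellipse_axis_ratio(self):
        recs = measure_mask(raster_ellipse(80, 40), 1.0)
        ratio = recs[0].major_axis_px / recs[0].minor_axis_px
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_area_um2_duality(self):
        recs = measure_mask(raster_ellipse(20, 20), 2.5, min_area_px=10)
        assert recs[0].area_um2 == pytest.approx(recs[0].area_px * 2.5**2)

    def test_single_pixel_region(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 4] = True
        recs = measure_mask(mask, 1.0, min_area_px=1)
        assert recs[0].area_px == 1
        assert recs[0].touches_border  # on row 0
        mask2 = np.zeros((10, 10), dtype=bool)
        mask2[5, 5] = True
        assert not measure_mask(mask2, 1.0, min_area_px=1)[0].touches_border

    def test_brute_force_small_regions(self):
        """Area and centroid agree exactly with direct pixel enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = np.zeros((24, 24), dtype=bool)
            n = int(rng.integers(1, 101))
            mask.ravel()[rng.choice(mask.size, size=n, replace=False)] = True
            labels, regions = label_tubules(mask, min_area_px=1)
            for region in regions:
                pix = np.argwhere(labels == region.label)
                rec = measure(region, 1.0, image_shape=mask.shape)
                assert rec.area_px == len(pix)
                assert rec.centroid == pytest.approx(tuple(pix.mean(axis=0)), abs=1e-12)


class TestLabelTubules:
    def test_counting_and_size_filter(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:15, 5:15] = True  # 100 px
        mask[30:40, 30:40] = True  # 100 px
        labels, regions = label_tubules(mask, min_area_px=50)
        assert len(regions) == 2
        small = np.zeros((20, 20), dtype=bool)
        small[3:5, 3:8] = True  # 10 px
        _, regions = label_tubules(small, min_area_px=50)
        assert len(regions) == 0

    def test_phantom_count_matches_truth(self):
        _, truth = generate_phantom(native_spec(seed=41))
        _, regions = label_tubules(truth.gt_mask, min_area_px=30)
        assert len(regions) == truth.true_n_tubules

    def test_area_conservation(self):
        """Labeled areas plus discarded speck pixels account for every GT pixel."""
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.25
        labels, regions = label_tubules(mask, min_area_px=5)
        labeled_px = sum(r.area for r in regions)
        discarded_px = int(mask.sum()) - int((labels > 0).sum())
        assert labeled_px + discarded_px == int(mask.sum())
        assert labeled_px == int((labels > 0).sum())


class TestFilterCircular:
    def test_strict_boundary(self):
        records = [record(k) for k in (1.0, 1.69, 1.70, 1.84)]
        kept = filter_circular(records)
        assert [r.gravelius_k for r in kept] == [1.0, 1.69]

    def test_empty_input(self):
        assert filter_circular([]) == []

    def test_idempotent_and_order_preserving(self):
        records = [record(k) for k in (1.5, 1.0, 1.65)]
        once = filter_circular(records)
        assert filter_circular(once) == once
        assert [r.gravelius_k for r in once] == [1.5, 1.0, 1.65]

    def test_disks_kept_elongated_removed(self):
        disks = measure_mask(raster_ellipse(50, 50), 1.0)
        thin = measure_mask(raster_ellipse(160, 20), 1.0)
        assert len(filter_circular(disks)) == 1
        assert len(filter_circular(thin)) == 0


class TestRepresentativeness:
    def test_all_kept_degenerate(self):
        res = representativeness([(10, 10), (8, 8), (12, 12)])
        assert res.degenerate_flag
        assert res.p_value == 1.0

    def test_small_t_not_significant(self):
        # proportions 0.9, 0.92, 0.88 against pooled 0.90: t = 0 exactly
        res = representativeness([(90, 100), (92, 100), (88, 100)])
        assert abs(res.t_statistic) < 1e-9
        assert res.p_value > 0.05

    def test_zero_total_animal_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            res = representativeness([(0, 0), (9, 10), (8, 10)])
        assert "excluded" in caplog.text
        assert res.degrees_of_freedom == 1

    def test_too_few_animals(self):
        with pytest.raises(ValueError):
            representativeness([(5, 10)])
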