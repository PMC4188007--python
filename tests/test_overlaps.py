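"""Shoebox construction, bounding-box search and overlap confirmation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mxindex import default_experiment, random_crystal
from mxindex.overlaps import (
    ProfileModel,
    ReflectionShoebox,
    compute_shoebox,
    confirm_overlaps,
    find_bbox_overlaps,
    overlap_stats,
    shoeboxes_for_predictions,
)
from mxindex.simulate import predict_spots


@pytest.fixture(scope="module")
def profile():
    return ProfileModel(sigma_b=0.02, sigma_m=0.05, n_sigma=3.0)


def _predictions(crystal, experiment, d_min=4.0, lattice_id=0):
    spots = predict_spots(crystal, experiment, d_min)
    spots["lattice_id"] = lattice_id
    hkl = spots[["h", "k", "l"]].to_numpy(float)
    spots["d"] = 1.0 / np.linalg.norm(hkl @ crystal.A.T, axis=1)
    return spots


class TestComputeShoebox:
    def test_degenerate_profile_single_pixel(self, wedge_experiment):
        tiny = ProfileModel(sigma_b=0.0, sigma_m=0.0, n_sigma=3.0)
        box = compute_shoebox(0, (1, 2, 3), (100.3, 200.6, 4.2), tiny, wedge_experiment)
        x0, x1, y0, y1, z0, z1 = box.bbox
        assert (x1 - x0, y1 - y0, z1 - z0) == (1, 1, 1)
        assert (x0, y0, z0) == (100, 201, 4)
        assert box.mask.all()

    def test_n_sigma_monotonicity(self, wedge_experiment):
        c = (1000.0, 1300.0, 5.0)
        small = compute_shoebox(0, (0, 0, 1), c, ProfileModel(0.02, 0.05, 2.0), wedge_experiment)
        big = compute_shoebox(0, (0, 0, 1), c, ProfileModel(0.02, 0.05, 4.0), wedge_experiment)
        for dim in range(3):
            lo_s, hi_s = small.bbox[2 * dim], small.bbox[2 * dim + 1]
            lo_b, hi_b = big.bbox[2 * dim], big.bbox[2 * dim + 1]
            assert hi_b - lo_b >= hi_s - lo_s
            assert lo_b <= lo_s and hi_b >= hi_s
        # old peak voxels are a subset of the new ones (global coordinates)
        def peaks(sb):
            zz, yy, xx = np.where(sb.mask)
            return {
                (int(x + sb.bbox[0]), int(y + sb.bbox[2]), int(z + sb.bbox[4]))
                for x, y, z in zip(xx, yy, zz)
            }

        assert peaks(small) <= peaks(big)

    def test_mask_matches_dense_ellipsoid_oracle(self, wedge_experiment, profile):
        """Pixel-by-pixel mask equals an independent ellipsoid evaluation."""
        from mxindex.geometry import mm_to_s1, pixel_to_mm

        centroid = (800.25, 1500.75, 3.6)
        box = compute_shoebox(0, (2, 1, 0), centroid, profile, wedge_experiment)
        x0, x1, y0, y1, z0, z1 = box.bbox
        det, beam, scan = wedge_experiment.detector, wedge_experiment.beam, wedge_experiment.scan
        s1c = mm_to_s1(*pixel_to_mm(centroid[0], centroid[1], det), det, beam)
        s1c_hat = s1c / np.linalg.norm(s1c)
        e1 = np.cross(s1c, beam.s0)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(s1c_hat, e1)
        for iz, iy, ix in itertools.product(range(z1 - z0), range(y1 - y0), range(x1 - x0)):
            px, py, pz = x0 + ix, y0 + iy, z0 + iz
            if (px, py, pz) == (round(centroid[0]), round(centroid[1]), int(centroid[2])):
                continue  # centroid voxel is peak by definition
            sp = mm_to_s1(*pixel_to_mm(float(px), float(py), det), det, beam)
            sp_hat = sp / np.linalg.norm(sp)
            a1 = np.degrees(np.dot(sp_hat - s1c_hat, e1)) / profile.sigma_b
            a2 = np.degrees(np.dot(sp_hat - s1c_hat, e2)) / profile.sigma_b
            a3 = (pz + 0.5 - centroid[2]) * scan.delta_phi / profile.sigma_m
            expected = a1 * a1 + a2 * a2 + a3 * a3 <= profile.n_sigma**2
            assert box.mask[iz, iy, ix] == expected

    def test_centroid_outside_rejected(self, wedge_experiment, profile):
        from mxindex.geometry import GeometryError

        with pytest.raises(GeometryError):
            compute_shoebox(0, (0, 0, 1), (-5.0, 10.0, 1.0), profile, wedge_experiment)


def _random_boxes(n, seed):
    rng = np.random.default_rng(seed)
    boxes = []
    for i in range(n):
        x0, y0, z0 = rng.integers(0, 80, 3)
        dx, dy, dz = rng.integers(1, 12, 3)
        bbox = (int(x0), int(x0 + dx), int(y0), int(y0 + dy), int(z0), int(z0 + dz))
        boxes.append(
            ReflectionShoebox(
                lattice_id=0,
                h=(i, 0, 0),
                centroid=(0, 0, 0),
                bbox=bbox,
                mask=np.ones((dz, dy, dx), dtype=bool),
                d_spacing=2.0,
            )
        )
    return boxes


class TestFindBboxOverlaps:
    def test_disjoint_boxes(self):
        a = _random_boxes(1, 0)[0]
        b = ReflectionShoebox(0, (9, 9, 9), (0, 0, 0), (200, 210, 200, 210, 200, 210),
                              np.ones((10, 10, 10), bool), 2.0)
        assert find_bbox_overlaps([a, b]) == []

    def test_face_sharing_boxes_do_not_overlap(self):
        m = np.ones((2, 2, 2), bool)
        a = ReflectionShoebox(0, (0, 0, 0), (0, 0, 0), (0, 2, 0, 2, 0, 2), m, 2.0)
        b = ReflectionShoebox(0, (1, 0, 0), (0, 0, 0), (2, 4, 0, 2, 0, 2), m, 2.0)
        assert find_bbox_overlaps([a, b]) == []

    def test_matches_brute_force_on_500_boxes(self):
        boxes = _random_boxes(500, 42)
        fast = set(find_bbox_overlaps(boxes))

        def brute(b1, b2):
            return (
                max(b1[0], b2[0]) < min(b1[1], b2[1])
                and max(b1[2], b2[2]) < min(b1[3], b2[3])
                and max(b1[4], b2[4]) < min(b1[5], b2[5])
            )

        slow = {
            (i, j)
            for i in range(500)
            for j in range(i + 1, 500)
            if brute(boxes[i].bbox, boxes[j].bbox)
        }
        assert fast == slow
        assert len(slow) > 0  # the instance actually exercises the search


class TestConfirmOverlaps:
    def test_intersecting_boxes_disjoint_peaks_dropped(self):
        ma = np.zeros((1, 1, 4), bool)
        ma[0, 0, 0] = True
        mb = np.zeros((1, 1, 4), bool)
        mb[0, 0, 3] = True
        a = ReflectionShoebox(0, (0, 0, 0), (0, 0, 0), (0, 4, 0, 1, 0, 1), ma, 2.0)
        b = ReflectionShoebox(1, (0, 0, 0), (0, 0, 0), (2, 6, 0, 1, 0, 1), mb, 2.0)
        pairs = find_bbox_overlaps([a, b])
        assert pairs == [(0, 1)]
        assert confirm_overlaps(pairs, [a, b]) == []

    def test_duplicated_reflection_fully_shared(self, wedge_experiment, profile):
        box = compute_shoebox(0, (1, 1, 1), (700.0, 900.0, 5.0), profile, wedge_experiment)
        import copy

        twin = copy.deepcopy(box)
        twin.lattice_id = 1
        confirmed = confirm_overlaps([(0, 1)], [box, twin])
        assert len(confirmed) == 1
        assert confirmed[0][2] == box.n_peak

    def test_two_lattice_fixture_matches_dense_oracle(self, cubic_cell):
        """Two-stage pipeline equals a brute-force all-pairs voxel scan."""
        exp = default_experiment(n_frames=10)
        rng = np.random.default_rng(91)
        crystals = [random_crystal(cubic_cell, rng) for _ in range(2)]
        profile = ProfileModel(sigma_b=0.05, sigma_m=0.2, n_sigma=3.0)
        preds = pd.concat(
            [_predictions(c, exp, 5.0, lattice_id=i) for i, c in enumerate(crystals)],
            ignore_index=True,
        )
        boxes = shoeboxes_for_predictions(preds, profile, exp)
        confirmed = {(i, j) for i, j, _ in confirm_overlaps(find_bbox_overlaps(boxes), boxes)}

        def voxels(sb):
            zz, yy, xx = np.where(sb.mask)
            return {
                (int(x + sb.bbox[0]), int(y + sb.bbox[2]), int(z + sb.bbox[4]))
                for x, y, z in zip(xx, yy, zz)
            }

        vox = [voxels(b) for b in boxes]
        oracle = {
            (i, j)
            for i in range(len(boxes))
            for j in range(i + 1, len(boxes))
            if vox[i] & vox[j]
        }
        assert confirmed == oracle

    def test_symmetry_and_irreflexivity(self):
        boxes = _random_boxes(100, 7)
        pairs = find_bbox_overlaps(boxes)
        assert all(i < j for i, j in pairs)
        assert all(i != j for i, j in pairs)


class TestOverlapStats:
    def _boxes_with_d(self, ds):
        m = np.ones((1, 1, 1), bool)
        return [
            ReflectionShoebox(0, (i, 0, 0), (0, 0, 0), (i, i + 1, 0, 1, 0, 1), m, d)
            for i, d in enumerate(ds)
        ]

    def test_no_overlaps_all_zero(self):
        boxes = self._boxes_with_d([1.5, 2.5, 3.5])
        stats, fractions = overlap_stats(boxes, [], np.array([1.0, 2.0, 3.0, 4.0]))
        assert (stats["fraction"] == 0).all()
        assert len(fractions) == 0

    def test_fully_duplicated_lattice_fraction_one(self, wedge_experiment, profile):
        box = compute_shoebox(0, (1, 1, 1), (700.0, 900.0, 5.0), profile, wedge_experiment)
        box.d_spacing = 2.5
        import copy

        twin = copy.deepcopy(box)
        boxes = [box, twin]
        confirmed = confirm_overlaps(find_bbox_overlaps(boxes), boxes)
        stats, fractions = overlap_stats(boxes, confirmed, np.array([2.0, 3.0]))
        assert stats["fraction"].tolist() == [1.0]
        assert np.allclose(fractions, 1.0)

    def test_empty_bins_absent(self):
        boxes = self._boxes_with_d([1.5, 1.6])
        stats, _ = overlap_stats(boxes, [], np.array([1.0, 2.0, 3.0]))
        assert len(stats) == 1  # the 2-3 A bin is absent, not zero
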