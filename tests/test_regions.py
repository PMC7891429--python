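"""Annulus masks, offset bands, AHA sectoring, T1 assignment lookup."""

import numpy as np
import pytest

from myoperf import (
    GeometryError,
    InputError,
    MyocardialGeometry,
    build_annulus_mask,
    build_t1_assignment,
    offset_contours,
    sector_t1_means,
    sectorize,
)


def circle(center, r, n=128):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def point_in_polygon(x, y, poly):
    """Brute-force ray-casting oracle."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


@pytest.fixture
def concentric():
    return MyocardialGeometry(circle((32, 32), 10), circle((32, 32), 20))


class TestAnnulusMask:
    def test_concentric_circles_area(self, concentric):
        mask = build_annulus_mask(concentric, (64, 64))
        expected = np.pi * (20**2 - 10**2)
        assert abs(mask.sum() - expected) / expected < 0.02

    def test_equal_contours_rejected(self):
        geom = MyocardialGeometry(circle((32, 32), 15), circle((32, 32), 15))
        with pytest.raises(GeometryError):
            build_annulus_mask(geom, (64, 64))

    def test_crossing_contours_rejected(self):
        geom = MyocardialGeometry(circle((32, 32), 12), circle((40, 32), 13))
        with pytest.raises(GeometryError):
            build_annulus_mask(geom, (64, 64))

    def test_random_star_shape_against_point_in_polygon_oracle(self):
        rng = np.random.default_rng(6)
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        r_in = 6 + 2 * rng.random(24)
        r_out = 12 + 4 * rng.random(24)
        c = (20.0, 20.0)
        endo = np.column_stack([c[0] + r_in * np.cos(th), c[1] + r_in * np.sin(th)])
        epi = np.column_stack([c[0] + r_out * np.cos(th), c[1] + r_out * np.sin(th)])
        geom = MyocardialGeometry(endo, epi)
        mask = build_annulus_mask(geom, (40, 40))
        for row in range(40):
            for col in range(40):
                expected = point_in_polygon(col, row, epi) and not point_in_polygon(
                    col, row, endo
                )
                assert mask[row, col] == expected, (row, col)


class TestOffsetContours:
    def test_quarter_offset_band_radii(self, concentric):
        band = offset_contours(concentric, (64, 64), 0.25)
        rows, cols = np.nonzero(band)
        r = np.hypot(cols - 32, rows - 32)
        assert r.min() >= 12.5 - 0.5 and r.max() <= 17.5 + 0.5

    def test_zero_fraction_is_identity(self, concentric):
        assert np.array_equal(
            offset_contours(concentric, (64, 64), 0.0),
            build_annulus_mask(concentric, (64, 64)),
        )

    def test_band_is_subset_of_annulus(self, concentric):
        band = offset_contours(concentric, (64, 64), 0.25)
        annulus = build_annulus_mask(concentric, (64, 64))
        assert not (band & ~annulus).any()

    def test_elliptical_annulus_against_dense_ray_oracle(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        c = (32.0, 30.0)
        endo = np.column_stack([c[0] + 9 * np.cos(th), c[1] + 7 * np.sin(th)])
        epi = np.column_stack([c[0] + 19 * np.cos(th), c[1] + 15 * np.sin(th)])
        geom = MyocardialGeometry(endo, epi, centroid=c)
        band = offset_contours(geom, (64, 64), 0.25)
        # dense-ray oracle: analytic ellipse radii at 3600 angles
        rows, cols = np.nonzero(build_annulus_mask(geom, (64, 64)))
        px_th = np.arctan2(c[1] - rows, cols - c[0])
        px_r = np.hypot(cols - c[0], rows - c[1])

        def ellipse_r(a, b, theta):
            return a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))

        # image-direction angle: y flip means sin term sign-flips, radius even
        r_e = ellipse_r(9, 7, px_th)
        r_E = ellipse_r(19, 15, px_th)
        w = r_E - r_e
        expected = (px_r >= r_e + 0.25 * w) & (px_r <= r_E - 0.25 * w)
        got = band[rows, cols]
        # allow 1 px discretization: mismatches only within 1 px of the band edge
        mismatch = got != expected
        dist_to_edge = np.minimum(
            np.abs(px_r - (r_e + 0.25 * w)), np.abs(px_r - (r_E - 0.25 * w))
        )
        assert np.all(dist_to_edge[mismatch] <= 1.0)

    def test_invalid_fraction_rejected(self, concentric):
        with pytest.raises(InputError):
            offset_contours(concentric, (64, 64), 0.6)


class TestSectorize:
    def test_six_sectors_equal_area(self, concentric):
        labels = sectorize(concentric, 6, (64, 64))
        mask = build_annulus_mask(concentric, (64, 64))
        counts = np.array([(mask & (labels == s)).sum() for s in range(1, 7)])
        assert np.all(np.abs(counts / mask.sum() - 1 / 6) < 0.05 / 6 + 0.01)

    def test_twelve_collapses_onto_six(self, concentric):
        l6 = sectorize(concentric, 6, (64, 64))
        l12 = sectorize(concentric, 12, (64, 64))
        assert np.array_equal((l12 - 1) // 2 + 1, l6)

    def test_nesting_all_counts(self, concentric):
        l6 = sectorize(concentric, 6, (64, 64))
        for n in (12, 18, 24):
            ln = sectorize(concentric, n, (64, 64))
            assert np.array_equal((ln - 1) // (n // 6) + 1, l6)

    def test_angle_binning_oracle(self, concentric):
        labels = sectorize(concentric, 6, (64, 64))
        cx, cy = concentric.centroid
        ref = concentric.reference_angle
        rng = np.random.default_rng(13)
        for _ in range(200):
            row, col = rng.integers(0, 64, 2)
            theta = np.arctan2(cy - row, col - cx)
            rel = np.mod(theta - ref, 2 * np.pi)
            expected = int(rel // (np.pi / 3)) + 1
            assert labels[row, col] == expected

    def test_partition_property(self, concentric):
        mask = build_annulus_mask(concentric, (64, 64))
        for n in (6, 12, 18, 24):
            labels = sectorize(concentric, n, (64, 64))
            inside = labels[mask]
            assert inside.min() >= 1 and inside.max() <= n
            assert (np.bincount(inside, minlength=n + 1)[1:] > 0).all()

    def test_invalid_count_rejected(self, concentric):
        with pytest.raises(InputError):
            sectorize(concentric, 7, (64, 64))


class TestSectorT1Means:
    def test_uniform_map(self, concentric):
        labels = sectorize(concentric, 6, (64, 64))
        mask = build_annulus_mask(concentric, (64, 64))
        means = sector_t1_means(np.full((64, 64), 1.3), labels, mask)
        assert np.allclose(means, 1.3)

    def test_elevated_deficit_sector(self, concentric):
        # deficit/non-deficit native T1 pattern: 1425 vs 1235 msec
        labels = sectorize(concentric, 6, (64, 64))
        mask = build_annulus_mask(concentric, (64, 64))
        t1 = np.where(labels == 4, 1.425, 1.235)
        means = sector_t1_means(t1, labels, mask)
        assert means[3] == pytest.approx(1.425, abs=1e-12)
        for s in (0, 1, 2, 4, 5):
            assert means[s] == pytest.approx(1.235, abs=1e-12)

    def test_random_map_against_masked_sum_oracle(self, concentric):
        rng = np.random.default_rng(21)
        labels = sectorize(concentric, 12, (64, 64))
        mask = build_annulus_mask(concentric, (64, 64))
        t1 = rng.uniform(0.9, 1.8, (64, 64))
        means = sector_t1_means(t1, labels, mask)
        for s in range(1, 13):
            sel = mask & (labels == s)
            assert means[s - 1] == pytest.approx(t1[sel].sum() / sel.sum(), rel=1e-12)

    def test_nested_weighted_means_collapse_exactly(self, concentric):
        rng = np.random.default_rng(22)
        mask = build_annulus_mask(concentric, (64, 64))
        t1 = rng.uniform(1.0, 1.6, (64, 64))
        l6 = sectorize(concentric, 6, (64, 64))
        l24 = sectorize(concentric, 24, (64, 64))
        m6 = sector_t1_means(t1, l6, mask)
        m24 = sector_t1_means(t1, l24, mask)
        counts24 = np.array([(mask & (l24 == s)).sum() for s in range(1, 25)])
        for s in range(6):
            grp = slice(4 * s, 4 * s + 4)
            weighted = np.sum(m24[grp] * counts24[grp]) / counts24[grp].sum()
            assert weighted == pytest.approx(m6[s], rel=1e-12)


class TestT1Assignment:
    def test_global_scalar_fill(self, concentric):
        a = build_t1_assignment(
            "global_scalar",
            shape=(64, 64),
            geometry=concentric,
            blood_t1=1.891,
            myo_t1=1.259,
            phase="diastole",
        )
        mask = build_annulus_mask(concentric, (64, 64))
        assert np.all(a.myo_t1_per_pixel[mask] == 1.259)
        assert np.isnan(a.myo_t1_per_pixel[~mask]).all()

    def test_sectoral_lookup_equals_sector_mean(self, concentric):
        rng = np.random.default_rng(30)
        t1_map = rng.uniform(1.0, 1.5, (64, 64))
        a = build_t1_assignment(
            "sectoral",
            shape=(64, 64),
            geometry=concentric,
            t1_map=t1_map,
            blood_t1=1.891,
            n_sectors=6,
            phase="diastole",
        )
        labels = sectorize(concentric, 6, (64, 64))
        band = offset_contours(concentric, (64, 64), 0.25)
        means = sector_t1_means(t1_map, labels, band)
        mask = build_annulus_mask(concentric, (64, 64))
        for s in range(1, 7):
            sel = mask & (labels == s)
            assert np.all(a.myo_t1_per_pixel[sel] == means[s - 1])

    def test_population_average_constants(self, concentric):
        a = build_t1_assignment(
            "population_average", shape=(64, 64), geometry=concentric, phase="diastole"
        )
        mask = build_annulus_mask(concentric, (64, 64))
        assert a.blood_t1 == 1.891
        assert np.all(a.myo_t1_per_pixel[mask] == 1.259)

    def test_none_mode_uncorrected(self):
        a = build_t1_assignment("none")
        assert not a.corrected

    def test_sectoral_without_geometry_rejected(self):
        with pytest.raises(InputError):
            build_t1_assignment("sectoral", blood_t1=1.8, n_sectors=6, phase="diastole")
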