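import heapq

import numpy as np
import pytest

from noduleant.baseline_edges import (
    RegionGrowParams,
    count_basins,
    histogram256,
    otsu_edges,
    otsu_threshold,
    region_growing_edges,
    watershed_edges,
)


def otsu_brute_force(hist):
    """Independent oracle: exhaustively minimize the within-class variance."""
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(256, dtype=float)
    best_t, best_wcv = None, np.inf
    for t in range(256):
        h0, h1 = hist[: t + 1], hist[t + 1 :]
        b0, b1 = bins[: t + 1], bins[t + 1 :]
        wcv = 0.0
        for h, b in ((h0, b0), (h1, b1)):
            n = h.sum()
            if n > 0:
                mu = (h * b).sum() / n
                wcv += (h * (b - mu) ** 2).sum() / hist.sum()
        if wcv < best_wcv - 1e-12:
            best_wcv, best_t = wcv, t
    return best_t


class TestOtsuThreshold:
    def test_two_point_histogram_tie_breaks_low(self):
        h = np.zeros(256, dtype=int)
        h[10] = 40
        h[200] = 60
        assert otsu_threshold(h) == 10  # any t in [10,199] optimal; lowest wins

    def test_single_bin_warns_and_returns_it(self):
        h = np.zeros(256, dtype=int)
        h[77] = 5
        with pytest.warns(UserWarning):
            assert otsu_threshold(h) == 77

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError, match="empty histogram"):
            otsu_threshold(np.zeros(256, dtype=int))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 50, size=256)
        assert otsu_threshold(h) == otsu_brute_force(h)


class TestOtsuEdges:
    def test_vertical_step_yields_single_boundary_column(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        em = otsu_edges(img)
        rows, cols = np.nonzero(em)
        assert set(cols) == {4}  # one column, on the bright side
        assert len(rows) == 6

    def test_constant_image_has_no_edges(self):
        with pytest.warns(UserWarning):
            em = otsu_edges(np.full((5, 5), 0.3))
        assert not em.any()

    def test_disk_yields_its_boundary_ring(self):
        img = np.full((21, 21), 0.1)
        rr, cc = np.mgrid[0:21, 0:21]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 36
        img[disk] = 0.9
        em = otsu_edges(img)
        # oracle: disk pixels with a 4-neighbour outside the disk
        ring = np.zeros_like(disk)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ring |= disk & ~np.roll(np.roll(disk, dr, 0), dc, 1)
        assert np.array_equal(em, ring)


def watershed_1d(profile):
    """Independent 1-D flooding oracle: returns dam positions."""
    n = len(profile)
    labels = [0] * n
    nextlab = 1
    i = 0
    while i < n:
        j = i
        while j + 1 < n and profile[j + 1] == profile[i]:
            j += 1
        if (i == 0 or profile[i - 1] > profile[i]) and (
            j == n - 1 or profile[j + 1] > profile[i]
        ):
            for t in range(i, j + 1):
                labels[t] = nextlab
            nextlab += 1
        i = j + 1
    heap = [(profile[i], i) for i in range(n) if labels[i]]
    heapq.heapify(heap)
    dams = set()
    while heap:
        _, i = heapq.heappop(heap)
        for nb in (i - 1, i + 1):
            if 0 <= nb < n and labels[nb] == 0 and nb not in dams:
                around = {
                    labels[t]
                    for t in (nb - 1, nb + 1)
                    if 0 <= t < n and labels[t] > 0 and t not in dams
                }
                if len(around) > 1:
                    dams.add(nb)
                else:
                    labels[nb] = labels[i]
                    heapq.heappush(heap, (profile[nb], nb))
    return sorted(dams)


class TestWatershed:
    def test_constant_image_single_basin_no_dams(self):
        assert not watershed_edges(np.full((8, 8), 0.5)).any()

    def test_ridge_dams_match_1d_flooding_oracle(self):
        # A smooth bright ridge: uniform rows reduce the 2-D problem to 1-D.
        cols = np.arange(64)
        prof = np.exp(-((cols - 32.0) ** 2) / 50.0) * 0.8 + 0.1
        img = np.tile(prof, (16, 1))
        em = watershed_edges(img, n_smooth=0)
        pad = np.pad(prof, 1, mode="edge")
        grad = np.abs((pad[2:] - pad[:-2]) / 2.0)
        assert sorted(set(np.nonzero(em)[1].tolist())) == watershed_1d(list(grad))
        assert set(np.nonzero(em)[0]) == set(range(16))  # dams span all rows

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_smoothing_never_increases_basins(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((48, 48))
        counts = [count_basins(img, s) for s in range(4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_dams_separate_basins(self):
        cols = np.arange(64)
        prof = np.exp(-((cols - 32.0) ** 2) / 50.0) * 0.8 + 0.1
        img = np.tile(prof, (16, 1))
        em = watershed_edges(img, n_smooth=0)
        # removing dam pixels leaves no 4-connected path between basins
        from scipy import ndimage as ndi

        _, n = ndi.label(~em)
        assert n >= 2


class TestRegionGrowing:
    def test_full_tolerance_region_is_whole_raster(self):
        img = np.random.default_rng(1).random((7, 9))
        em = region_growing_edges(img, RegionGrowParams(seed=(3, 4), intensity_tolerance=1.0))
        border = np.zeros((7, 9), dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        assert np.array_equal(em, border)

    def test_zero_tolerance_unique_seed_gives_seed_only(self):
        img = np.full((5, 5), 0.2)
        img[2, 2] = 0.9
        em = region_growing_edges(img, RegionGrowParams(seed=(2, 2), intensity_tolerance=0.0))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        assert np.array_equal(em, expected)

    def test_uniform_disk_recovered_exactly(self):
        img = np.full((21, 21), 0.1)
        rr, cc = np.mgrid[0:21, 0:21]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 25
        img[disk] = 0.9
        em = region_growing_edges(img, RegionGrowParams(seed=(10, 10), intensity_tolerance=0.2))
        ring = np.zeros_like(disk)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ring |= disk & ~np.roll(np.roll(disk, dr, 0), dc, 1)
        assert np.array_equal(em, ring)

    def test_out_of_bounds_seed_raises(self):
        with pytest.raises(ValueError, match="seed"):
            region_growing_edges(np.zeros((4, 4)), RegionGrowParams(seed=(9, 0)))

    def test_deterministic(self):
        img = np.random.default_rng(5).random((20, 20))
        p = RegionGrowParams(seed=(10, 10), intensity_tolerance=0.3)
        assert np.array_equal(region_growing_edges(img, p), region_growing_edges(img, p))


def test_histogram256_counts_every_pixel():
    img = np.random.default_rng(0).random((13, 17))
    assert histogram256(img).sum() == 13 * 17
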