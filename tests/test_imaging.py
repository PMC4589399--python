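"""Tests of ROI definition, region growing, TAC extraction, SUV and image I/O."""

import numpy as np
import pytest

import petkin as pk


@pytest.fixture()
def small_schedule():
    return pk.FrameSchedule.from_durations([10.0, 20.0, 30.0])


def make_volume(data, schedule, voxel=1.0):
    return pk.ImageVolume4D(data, (voxel, voxel, voxel), schedule)


class TestScheduleInvariants:
    def test_mouse_protocol_totals(self, schedule):
        assert schedule.n_frames == 29
        assert schedule.total_duration == pytest.approx(3093.0)

    @pytest.mark.parametrize(
        "starts,durations",
        [
            ([0.0, 5.0], [10.0, 5.0]),  # overlapping
            ([0.0, 20.0], [10.0, 5.0]),  # gap
            ([0.0], [-1.0]),
            ([0.0, 0.0], [1.0, 1.0]),
        ],
    )
    def test_invalid_schedules_rejected(self, starts, durations):
        with pytest.raises(ValueError):
            pk.FrameSchedule(np.asarray(starts), np.asarray(durations))


class TestEllipsoidRoi:
    def test_sub_voxel_axes_select_center_voxel(self, small_schedule):
        vol = make_volume(np.zeros((3, 9, 9, 9)), small_schedule)
        roi = pk.ellipsoid_roi((4, 4, 4), (0.4, 0.4, 0.4), vol)
        assert roi.n_voxels == 1 and tuple(roi.indices[0]) == (4, 4, 4)

    def test_huge_axes_select_everything(self, small_schedule):
        vol = make_volume(np.zeros((3, 4, 5, 6)), small_schedule)
        roi = pk.ellipsoid_roi((2, 2, 3), (100, 100, 100), vol)
        assert roi.n_voxels == 4 * 5 * 6

    def test_sphere_voxel_count_matches_lattice_enumeration(self, small_schedule):
        # brute-force count of lattice points with |r|^2 <= 2.5^2 around the center
        vol = make_volume(np.zeros((3, 15, 15, 15)), small_schedule)
        roi = pk.ellipsoid_roi((7, 7, 7), (2.5, 2.5, 2.5), vol)
        count = sum(
            x * x + y * y + z * z <= 2.5**2
            for x in range(-3, 4)
            for y in range(-3, 4)
            for z in range(-3, 4)
        )
        assert count == 81
        assert roi.n_voxels == count

    def test_no_intersection_rejected(self, small_schedule):
        vol = make_volume(np.zeros((3, 4, 4, 4)), small_schedule)
        with pytest.raises(ValueError):
            pk.ellipsoid_roi((50, 50, 50), (0.5, 0.5, 0.5), vol)


def brute_force_grow(img, seed, lo, hi):
    """Independent 6-connected flood fill used as the oracle."""
    from collections import deque

    grown = {seed}
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            n = (z + dz, y + dy, x + dx)
            if (
                all(0 <= n[i] < img.shape[i] for i in range(3))
                and n not in grown
                and lo <= img[n] <= hi
            ):
                grown.add(n)
                queue.append(n)
    return grown


class TestRegionGrowing:
    def test_uniform_image_grows_everywhere(self, small_schedule):
        vol = make_volume(np.full((3, 5, 5, 5), 2.0), small_schedule)
        init = pk.ROIMask(np.array([[2, 2, 2]]), (5, 5, 5))
        grown = pk.region_grow_refine(vol, init)
        assert grown.n_voxels == 125

    def test_isolated_seed_stays_alone(self, small_schedule):
        data = np.full((3, 5, 5, 5), 100.0)
        data[:, 2, 2, 2] = 10.0
        vol = make_volume(data, small_schedule)
        init = pk.ROIMask(np.array([[2, 2, 2]]), (5, 5, 5))
        grown = pk.region_grow_refine(vol, init)
        assert grown.n_voxels == 1 and tuple(grown.indices[0]) == (2, 2, 2)

    def test_seed_outside_band_warns_and_returns_seed(self, small_schedule):
        # initial ROI mean dominated by background so the hot seed exceeds +40%
        data = np.ones((3, 5, 5, 5))
        data[:, 2, 2, 2] = 50.0
        vol = make_volume(data, small_schedule)
        init = pk.ellipsoid_roi((2, 2, 2), (2.0, 2.0, 2.0), vol)
        with pytest.warns(UserWarning, match="seed voxel"):
            grown = pk.region_grow_refine(vol, init)
        assert grown.n_voxels == 1 and tuple(grown.indices[0]) == (2, 2, 2)

    def test_hot_sphere_recovered_exactly(self, small_schedule):
        # hot sphere (value 10) on background 1; initial ROI straddles the edge
        zz, yy, xx = np.meshgrid(*[np.arange(13)] * 3, indexing="ij")
        sphere = (zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= 3.0**2
        img = np.where(sphere, 10.0, 1.0)
        vol = make_volume(np.broadcast_to(img, (3, 13, 13, 13)).copy(), small_schedule)
        # off-center manual ROI: ~78% inside the sphere, so its mean keeps
        # the hot value inside the +/-40% band while excluding background
        init = pk.ellipsoid_roi((5, 5, 6), (2.5, 2.5, 2.5), vol)
        grown = pk.region_grow_refine(vol, init)

        m = img[tuple(init.indices.T)].mean()
        seed = tuple(init.indices[np.argmax(img[tuple(init.indices.T)])])
        oracle = brute_force_grow(img, seed, 0.6 * m, 1.4 * m)
        assert set(map(tuple, grown.indices)) == oracle
        assert set(map(tuple, grown.indices)) == set(map(tuple, np.argwhere(sphere)))

    def test_grown_mask_invariants(self, small_schedule, rng):
        data = np.broadcast_to(rng.uniform(0.5, 1.5, (6, 6, 6)), (3, 6, 6, 6)).copy()
        vol = make_volume(data, small_schedule)
        init = pk.ellipsoid_roi((3, 3, 3), (1.5, 1.5, 1.5), vol)
        grown = pk.region_grow_refine(vol, init)
        img = vol.time_average()
        vals = img[tuple(init.indices.T)]
        m = vals.mean()
        seed = tuple(init.indices[np.argmax(vals)])
        # contains the seed, all members in band, 6-connected
        assert seed in set(map(tuple, grown.indices))
        gvals = img[tuple(grown.indices.T)]
        assert np.all((gvals >= 0.6 * m) & (gvals <= 1.4 * m))
        oracle = brute_force_grow(img, seed, 0.6 * m, 1.4 * m)
        assert set(map(tuple, grown.indices)) == oracle


class TestExtractTac:
    def test_single_voxel_series(self, small_schedule, rng):
        data = rng.uniform(0, 4, (3, 4, 4, 4))
        vol = make_volume(data, small_schedule)
        tac = pk.extract_tac(vol, pk.ROIMask(np.array([[1, 2, 3]]), (4, 4, 4)))
        assert np.array_equal(tac.values, data[:, 1, 2, 3])

    def test_linearity_in_intensities(self, small_schedule, rng):
        data = rng.uniform(0, 4, (3, 4, 4, 4))
        roi = pk.ROIMask(np.array([[0, 0, 0], [1, 1, 1], [2, 3, 1]]), (4, 4, 4))
        a = pk.extract_tac(make_volume(data, small_schedule), roi)
        b = pk.extract_tac(make_volume(3.0 * data, small_schedule), roi)
        assert np.allclose(b.values, 3.0 * a.values, rtol=1e-12)


class TestSuv:
    @pytest.mark.parametrize(
        "conc,dose,weight,expected",
        [
            (1.0, 10.0, 10.0, 1.0),
            (0.0, 5.0, 20.0, 0.0),
            (0.5, 5.55, 21.1, 0.5 / (5.55 / 21.1)),  # the study's mean dose and weight
        ],
    )
    def test_examples(self, conc, dose, weight, expected):
        assert pk.compute_suv(conc, dose, weight) == pytest.approx(expected, rel=1e-12)

    def test_mean_dose_weight_value(self):
        assert pk.compute_suv(0.5, 5.55, 21.1) == pytest.approx(1.9009, abs=1e-4)

    @pytest.mark.parametrize("dose,weight", [(0.0, 20.0), (-1.0, 20.0), (5.0, 0.0)])
    def test_invalid_dose_weight(self, dose, weight):
        with pytest.raises(ValueError):
            pk.compute_suv(1.0, dose, weight)

    def test_uniform_roi_max_equals_mean(self, small_schedule):
        vol = make_volume(np.full((3, 4, 4, 4), 2.0), small_schedule)
        roi = pk.ROIMask(np.array([[0, 0, 0], [1, 1, 1]]), (4, 4, 4))
        rec = pk.suvmax_static(vol, roi, 10.0, 10.0)
        assert rec.suv_max == rec.suv_mean == pytest.approx(2.0)

    def test_hot_voxel_sets_max_regardless_of_roi_size(self, small_schedule):
        data = np.ones((3, 5, 5, 5))
        data[-1, 2, 2, 2] = 2.0
        vol = make_volume(data, small_schedule)
        small = pk.ROIMask(np.array([[2, 2, 2], [2, 2, 3]]), (5, 5, 5))
        big = pk.ellipsoid_roi((2, 2, 2), (2.0, 2.0, 2.0), vol)
        assert pk.suvmax_static(vol, small, 10, 10).suv_max == pytest.approx(2.0)
        assert pk.suvmax_static(vol, big, 10, 10).suv_max == pytest.approx(2.0)

    def test_adding_colder_voxels_preserves_max(self, small_schedule, rng):
        data = rng.uniform(0.5, 1.0, (3, 5, 5, 5))
        data[-1, 1, 1, 1] = 5.0
        vol = make_volume(data, small_schedule)
        roi = pk.ROIMask(np.array([[1, 1, 1]]), (5, 5, 5))
        bigger = pk.ellipsoid_roi((1, 1, 1), (1.5, 1.5, 1.5), vol)
        assert (
            pk.suvmax_static(vol, bigger, 8, 20).suv_max
            == pk.suvmax_static(vol, roi, 8, 20).suv_max
        )


class TestIo:
    def test_volume_nifti_roundtrip(self, small_schedule, tmp_path, rng):
        data = rng.uniform(0, 3, (3, 4, 5, 6))
        vol = make_volume(data, small_schedule, voxel=0.5)
        pk.save_volume(vol, tmp_path / "vol.nii")
        back = pk.load_volume(tmp_path / "vol.nii")
        assert np.allclose(back.data, vol.data)
        assert back.voxel_size_mm == vol.voxel_size_mm
        assert back.schedule == vol.schedule

    def test_mask_tsv_roundtrip(self, tmp_path):
        mask = pk.ROIMask(np.array([[0, 1, 2], [3, 2, 1]]), (4, 4, 4))
        pk.save_mask_tsv(mask, tmp_path / "m.tsv")
        assert pk.load_mask_tsv(tmp_path / "m.tsv") == mask

    def test_tac_tsv_roundtrip(self, schedule, plasma_tac, tmp_path):
        pk.write_tac(plasma_tac, tmp_path / "t.tsv", comment="plasma input")
        back = pk.read_tac(tmp_path / "t.tsv")
        assert back.schedule == schedule
        assert np.allclose(back.values, plasma_tac.values)
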