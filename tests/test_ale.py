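import numpy as np
import pytest

import focimeta as fm
from focimeta.ale import kernel_fwhm, p_check, report_to_frame, sample_null
from focimeta.exceptions import ConfigError, EmptyInputError, ValidationError
from focimeta.grid import VoxelGrid


def flat_grid(shape=(11, 11, 11), voxel_size=2.0):
    """Small fully-unmasked grid centred on the origin."""
    shape = tuple(shape)
    origin = -(np.array(shape) - 1) / 2 * voxel_size
    return VoxelGrid(voxel_size=voxel_size, origin=origin, shape=shape,
                     mask=np.ones(shape, dtype=bool))


class TestKernel:
    def test_sum_normalised_and_peak_central(self):
        kern = fm.build_kernel(voxel_size=2.0)
        assert kern.sum() == pytest.approx(1.0, abs=1e-9)
        c = kern.shape[0] // 2
        assert kern[c, c, c] == kern.max()

    def test_finer_voxels_spread_probability_mass(self):
        coarse = fm.build_kernel(fwhm_override=10.0, voxel_size=2.0)
        fine = fm.build_kernel(fwhm_override=10.0, voxel_size=1.0)
        assert fine.max() < coarse.max()

    def test_subject_count_shrinks_fwhm(self):
        assert kernel_fwhm(50) < kernel_fwhm(5) < kernel_fwhm(1)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ConfigError):
            fm.build_kernel(fwhm_override=-1.0)


class TestMaMap:
    def test_single_focus_peak_equals_kernel_peak(self):
        grid = flat_grid()
        kern = fm.build_kernel(fwhm_override=8.0, voxel_size=2.0)
        ma = fm.compute_ma_map(np.array([[0.0, 0.0, 0.0]]), kern, grid)
        assert ma.max() == pytest.approx(kern.max())
        assert np.unravel_index(ma.argmax(), ma.shape) == (5, 5, 5)

    def test_matches_brute_force_stamping_oracle(self, rng):
        grid = flat_grid(shape=(13, 13, 13))
        kern = fm.build_kernel(fwhm_override=6.0, voxel_size=2.0)
        foci = rng.uniform(-10, 10, size=(4, 3))
        ma = fm.compute_ma_map(foci, kern, grid)
        # oracle: place the full kernel around each focus by direct indexing
        r = kern.shape[0] // 2
        expect = np.zeros(grid.shape)
        for f in foci:
            idx = np.ceil((f - grid.origin) / grid.voxel_size - 0.5).astype(int)
            for off in np.ndindex(kern.shape):
                tgt = idx + np.array(off) - r
                if ((tgt >= 0) & (tgt < np.array(grid.shape))).all():
                    t = tuple(tgt)
                    expect[t] = max(expect[t], kern[off])
        np.testing.assert_allclose(ma, expect, atol=1e-12)

    def test_within_study_combination_is_max_not_sum(self):
        grid = flat_grid()
        kern = fm.build_kernel(fwhm_override=8.0, voxel_size=2.0)
        one = fm.compute_ma_map(np.array([[0.0, 0.0, 0.0]]), kern, grid)
        dup = fm.compute_ma_map(np.array([[0.0, 0.0, 0.0]] * 5), kern, grid)
        np.testing.assert_array_equal(one, dup)

    def test_empty_focus_list_rejected(self):
        with pytest.raises(EmptyInputError):
            fm.compute_ma_map(np.empty((0, 3)), fm.build_kernel(), flat_grid())


class TestAleUnion:
    def test_single_study_identity(self, rng):
        ma = rng.uniform(0, 0.1, size=(4, 4, 4))
        np.testing.assert_allclose(fm.compute_ale_map([ma]), ma)

    def test_two_half_probabilities_give_three_quarters(self):
        a = np.full((2, 2, 2), 0.5)
        np.testing.assert_allclose(fm.compute_ale_map([a, a]), 0.75)

    def test_union_dominates_every_contributor(self, rng):
        mas = [rng.uniform(0, 0.2, size=(5, 5, 5)) for _ in range(4)]
        ale = fm.compute_ale_map(mas)
        for ma in mas:
            assert (ale >= ma - 1e-12).all()
        assert (ale < 1.0).all()

    def test_monotone_in_any_ma_increase(self, rng):
        mas = [rng.uniform(0, 0.2, size=(4, 4, 4)) for _ in range(3)]
        base = fm.compute_ale_map(mas)
        for _ in range(10):
            i = rng.integers(3)
            bumped = [m.copy() for m in mas]
            v = tuple(rng.integers(4, size=3))
            bumped[i][v] = min(bumped[i][v] + 0.3, 0.9)
            assert fm.compute_ale_map(bumped)[v] >= base[v]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fm.compute_ale_map([np.zeros((3, 3, 3)), np.zeros((4, 4, 4))])


class TestNull:
    def test_same_seed_identical_summaries(self):
        grid = flat_grid(shape=(9, 9, 9), voxel_size=4.0)
        kern = fm.build_kernel(fwhm_override=10.0, voxel_size=4.0)
        a = sample_null([3, 2], kern, grid, n_perm=20, seed=9)
        b = sample_null([3, 2], kern, grid, n_perm=20, seed=9)
        np.testing.assert_array_equal(a.voxel_values, b.voxel_values)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_pooled_mass_conserved(self):
        grid = flat_grid(shape=(7, 7, 7), voxel_size=4.0)
        kern = fm.build_kernel(fwhm_override=10.0, voxel_size=4.0)
        null = sample_null([2], kern, grid, n_perm=15, seed=0)
        assert null.voxel_values.size == 15 * int(grid.mask.sum())

    def test_single_focus_values_match_exhaustive_placement_oracle(self):
        # with one study of one focus, every permutation's value multiset must
        # equal the clipped kernel stamped at one of the mask voxels
        grid = flat_grid(shape=(5, 5, 5), voxel_size=4.0)
        kern = fm.build_kernel(fwhm_override=8.0, voxel_size=4.0)
        r = kern.shape[0] // 2
        placements = {}
        for idx in np.ndindex(grid.shape):
            vol = np.zeros(grid.shape)
            for off in np.ndindex(kern.shape):
                tgt = np.array(idx) + np.array(off) - r
                if ((tgt >= 0) & (tgt < np.array(grid.shape))).all():
                    vol[tuple(tgt)] = max(vol[tuple(tgt)], kern[off])
            placements[idx] = np.sort(vol[grid.mask]).astype(np.float32)
        null = sample_null([1], kern, grid, n_perm=30, seed=2)
        for p in range(30):
            got = np.sort(null.voxel_values[p])
            assert any(np.allclose(got, exp, atol=1e-7)
                       for exp in placements.values())


class TestThreshold:
    @pytest.fixture()
    def noise_setup(self):
        grid = flat_grid(shape=(9, 9, 9), voxel_size=4.0)
        kern = fm.build_kernel(fwhm_override=10.0, voxel_size=4.0)
        null = sample_null([4, 4, 4], kern, grid, n_perm=40, seed=5)
        return grid, kern, null

    def test_all_zero_map_gives_empty_report(self, noise_setup):
        grid, _, null = noise_setup
        out, rows = fm.threshold_ale(np.zeros(grid.shape), null, grid)
        assert rows == [] and not out.any()

    def test_suprathreshold_set_shrinks_with_stricter_p(self, noise_setup):
        grid, kern, null = noise_setup
        ma = fm.compute_ma_map(np.array([[0.0, 0.0, 0.0]]), kern, grid)
        ale = fm.compute_ale_map([ma] * 6)
        loose = (ale > null.voxel_threshold(0.05)).sum()
        strict = (ale > null.voxel_threshold(0.001)).sum()
        assert strict <= loose

    def test_report_geometry_invariants(self, noise_setup):
        grid, kern, null = noise_setup
        ma = fm.compute_ma_map(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
                               kern, grid)
        ale = fm.compute_ale_map([ma] * 8)
        _, rows = fm.threshold_ale(ale, null, grid, cluster_forming_p=0.01,
                                   cluster_fwe_p=0.4)
        assert rows, "a strongly convergent peak must survive a loose cutoff"
        for row in rows:
            assert row.size_mm3 == row.size_voxels * grid.voxel_volume
            idx = grid.mm_to_voxel(np.array(row.peak_mm))[0]
            assert grid.mask[tuple(idx)]
        frame = report_to_frame(rows)
        assert list(frame["size_voxels"]) == sorted(frame["size_voxels"],
                                                    reverse=True)

    def test_bad_cluster_forming_p_rejected(self, noise_setup):
        grid, _, null = noise_setup
        with pytest.raises(ConfigError):
            fm.threshold_ale(np.zeros(grid.shape), null, grid,
                             cluster_forming_p=0.7)
        with pytest.raises(ConfigError):
            p_check(0.0)
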