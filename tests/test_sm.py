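import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammacal.detector import sample_counts
from gammacal.geometry import AngularGrid, make_coarse_grid, make_fine_grid
from gammacal.sm import (
    DRFImage,
    ScalingFactors,
    SystemMatrix,
    apply_scaling,
    assemble_sm,
    compute_scaling,
    crop_drf,
    crop_image,
    extract_drf,
    interpolate_coarse_to_fine,
    invert_scaling,
    load_sm,
    pad_drf,
    pad_image,
    save_sm,
)


def random_sm(rng, grid=None, n_bins=7):
    grid = grid or make_coarse_grid()
    return SystemMatrix(rng.random((grid.n_pixels, n_bins)), grid)


class TestContainer:
    def test_negative_values_rejected(self):
        grid = make_coarse_grid()
        vals = np.ones((grid.n_pixels, 3))
        vals[0, 0] = -1
        with pytest.raises(ValueError):
            SystemMatrix(vals, grid)

    def test_row_count_must_match_grid(self):
        with pytest.raises(ValueError):
            SystemMatrix(np.ones((10, 3)), make_coarse_grid())

    @pytest.mark.parametrize("suffix", [".h5", ".npz"])
    def test_save_load_round_trip(self, tmp_path, rng, suffix):
        sm = random_sm(rng)
        sm.metadata.update({"source": "Tc99m", "kind": "test"})
        path = tmp_path / f"sm{suffix}"
        save_sm(sm, path)
        back = load_sm(path)
        np.testing.assert_array_equal(back.values, sm.values)
        np.testing.assert_array_equal(back.grid.theta_values, sm.grid.theta_values)
        assert back.metadata == sm.metadata


class TestDRFRoundTrip:
    def test_extract_orientation_is_phi_by_theta(self, rng):
        sm = random_sm(rng)
        drf = extract_drf(sm, 3)
        assert drf.image.shape == (36, 10)  # (phi, theta) on the coarse grid
        # pixel (theta index 2, phi index 5) lands at image[5, 2]
        i = sm.grid.pixel_index(2, 5)
        assert drf.image[5, 2] == sm.values[i, 3]

    def test_fine_grid_drf_has_32760_elements(self):
        grid = make_fine_grid()
        sm = SystemMatrix(np.ones((grid.n_pixels, 1)), grid)
        drf = extract_drf(sm, 0)
        assert drf.image.shape == (360, 91)
        assert drf.image.size == 32_760

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10)
    def test_decompose_assemble_bijection(self, seed):
        rng = np.random.default_rng(seed)
        sm = random_sm(rng, n_bins=5)
        drfs = [extract_drf(sm, j) for j in range(5)]
        rng.shuffle(drfs)  # assembly order must not matter
        back = assemble_sm(drfs, sm.grid)
        np.testing.assert_array_equal(back.values, sm.values)

    def test_assemble_rejects_duplicates_and_negatives(self, rng):
        sm = random_sm(rng, n_bins=3)
        drfs = [extract_drf(sm, j) for j in range(3)]
        with pytest.raises(ValueError):
            assemble_sm(drfs[:2] + [drfs[1]], sm.grid)
        with pytest.raises(ValueError):
            DRFImage(-np.ones((36, 10)), 0)


class TestInterpolation:
    def test_coarse_nodes_reproduced(self, small_true_sm):
        fine = interpolate_coarse_to_fine(small_true_sm)
        cg, fg = small_true_sm.grid, fine.grid
        it = np.searchsorted(fg.theta_values, cg.theta_values)
        ip = np.searchsorted(fg.phi_values, cg.phi_values)
        coarse_img = small_true_sm.values[:, 4].reshape(cg.shape)
        fine_img = fine.values[:, 4].reshape(fg.shape)
        np.testing.assert_allclose(fine_img[np.ix_(it, ip)], coarse_img, rtol=1e-9)

    def test_constant_sm_stays_constant(self):
        grid = make_coarse_grid()
        sm = SystemMatrix(np.full((grid.n_pixels, 2), 3.5), grid)
        fine = interpolate_coarse_to_fine(sm)
        np.testing.assert_allclose(fine.values, 3.5, rtol=1e-9)

    def test_beats_bilinear_on_smooth_field(self):
        """Bicubic interpolation of cos(theta) must beat a bilinear oracle."""
        from scipy.interpolate import RegularGridInterpolator

        cg, fg = make_coarse_grid(), make_fine_grid()
        th, ph = cg.mesh()
        field = np.cos(np.deg2rad(th))
        sm = SystemMatrix(field.ravel()[:, None], cg)
        fine = interpolate_coarse_to_fine(sm)
        fth, fph = fg.mesh()
        truth = np.cos(np.deg2rad(fth)).ravel()
        err_spline = np.abs(fine.values[:, 0] - truth).max()
        lin = RegularGridInterpolator(
            (cg.theta_values, cg.phi_values), field, method="linear"
        )
        pts = np.stack([fth.ravel(), np.minimum(fph.ravel(), 350.0)], axis=1)
        err_bilinear = np.abs(lin(pts) - truth).max()
        assert err_spline < err_bilinear

    def test_output_is_nonnegative_even_with_overshoot(self, small_true_sm):
        noisy = sample_counts(small_true_sm, seed=2)
        fine = interpolate_coarse_to_fine(noisy)
        assert np.all(fine.values >= 0)

    def test_refinement_converges_to_simulator(self, small_geometry):
        """A 5-degree calibration grid interpolates closer to the true fine
        response than the 10-degree grid does."""
        from gammacal.detector import SourceSpec, simulate_true_sm

        src = SourceSpec("Tc99m", mu=0.15, events_per_point=1.0)
        target = AngularGrid(np.arange(0.0, 91.0, 2.5), np.arange(0.0, 360.0, 2.5))
        truth = simulate_true_sm(small_geometry, src, target)
        errs = {}
        for step in (10.0, 5.0):
            coarse = AngularGrid(
                np.arange(0.0, 90.0 + 1e-9, step), np.arange(0.0, 359.9, step)
            )
            sm = simulate_true_sm(small_geometry, src, coarse)
            fine = interpolate_coarse_to_fine(sm, target)
            # compare normalised shapes: row totals differ by construction
            errs[step] = np.abs(
                fine.values / fine.values.sum() - truth.values / truth.values.sum()
            ).max()
        assert errs[5.0] < errs[10.0]


class TestPadding:
    def test_pad_fine_drf_to_368_by_96(self):
        drf = DRFImage(np.arange(360 * 91, dtype=float).reshape(360, 91), 0)
        padded = pad_drf(drf)
        assert padded.image.shape == (368, 96)
        assert padded.offset == (4, 2)
        assert padded.image.sum() == drf.image.sum()

    @pytest.mark.parametrize("shape", [(360, 91), (60, 16), (72, 19)])
    def test_crop_inverts_pad_bit_exactly(self, rng, shape):
        drf = DRFImage(rng.random(shape), 2)
        back = crop_drf(pad_drf(drf))
        np.testing.assert_array_equal(back.image, drf.image)
        assert back.bin_index == 2

    def test_padded_dims_are_multiples_of_16(self, rng):
        padded, _ = pad_image(rng.random((37, 21)))
        assert padded.shape == (48, 32)


class TestScaling:
    def test_identical_devices_give_unit_factors(self, rng):
        sm = random_sm(rng)
        f = compute_scaling(sm, sm)
        np.testing.assert_allclose(f.values, 1.0)

    def test_factor_arithmetic(self, rng):
        sm1 = random_sm(rng, n_bins=4)
        sm2 = SystemMatrix(sm1.values * 0.5, sm1.grid)
        np.testing.assert_allclose(compute_scaling(sm1, sm2).values, 2.0)

    def test_apply_invert_round_trip_is_exact(self, rng):
        sm = random_sm(rng, n_bins=4)
        f = ScalingFactors(rng.uniform(0.5, 2.0, size=4))
        back = invert_scaling(apply_scaling(sm, f), f)
        np.testing.assert_array_equal(back.values, (sm.values * f.values) / f.values)
        np.testing.assert_allclose(back.values, sm.values, rtol=1e-15)

    def test_scaled_device2_totals_match_device1(self, rng):
        sm1 = random_sm(rng, n_bins=4)
        sm2 = SystemMatrix(sm1.values * rng.uniform(0.3, 3.0, size=4), sm1.grid)
        f = compute_scaling(sm1, sm2)
        scaled = apply_scaling(sm2, f)
        np.testing.assert_allclose(scaled.bin_totals(), sm1.bin_totals(), rtol=1e-12)

    def test_zero_total_names_the_bin(self, rng):
        sm1 = random_sm(rng, n_bins=3)
        vals = sm1.values.copy()
        vals[:, 1] = 0.0
        sm2 = SystemMatrix(vals, sm1.grid)
        with pytest.raises(ValueError, match="1"):
            compute_scaling(sm1, sm2)
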