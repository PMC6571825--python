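"""Pretreatment operators: exactness, invariances and leakage safety."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from wheyscreen.preprocess import (Recipe, apply_recipe, baseline_correct,
                                   crop, despike, msc, normalize,
                                   sg_derivative, sg_smooth, snv)
from wheyscreen.spectra import SpectrumSet
from wheyscreen.synthetic import (clean_mixture, component_spectrum,
                                  default_axis, default_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestDespike:
    def test_single_huge_spike_removed(self, rng, axis, library):
        clean = component_spectrum(library.peaks("wpc"), axis)
        noisy = clean + rng.normal(0, 0.01, axis.size)
        spiked = noisy.copy()
        spiked[700] += 50 * 0.01
        out = despike(spiked)
        # the spike channel is replaced by a local median: two noisy
        # quantities, so allow a 5-sigma gap instead of the 50-sigma spike
        assert np.max(np.abs(out - noisy)) < 5 * 0.01
        # the spike is repaired; at most a handful of noise extremes may
        # legitimately cross the z-threshold, all repaired to local medians
        changed = np.flatnonzero(out != spiked)
        assert 700 in changed and changed.size <= 5

    def test_smooth_spectrum_unchanged(self, axis, library):
        clean = component_spectrum(library.peaks("wpc"), axis)
        assert np.array_equal(despike(clean), clean)

    def test_adjacent_spikes_removed(self, rng, axis):
        noisy = rng.normal(0, 0.01, axis.size) + 1.0
        spiked = noisy.copy()
        spiked[[500, 501]] += 5.0
        out = despike(spiked)
        assert np.max(np.abs(out - noisy)) < 3 * 0.01

    def test_window_validation(self, axis):
        with pytest.raises(ValueError, match="odd"):
            despike(np.ones(100), window=6)
        with pytest.raises(ValueError, match="shorter"):
            despike(np.ones(5), window=7)


class TestBaseline:
    def test_pure_line_removed_exactly(self, axis):
        y = 3.0 + 0.002 * axis
        assert np.max(np.abs(baseline_correct(y, axis, order=1))) < 1e-8

    def test_constant_offset_order0(self, axis):
        out = baseline_correct(np.full(axis.size, 7.0), axis, order=0)
        assert np.max(np.abs(out)) < 1e-10

    def test_peak_height_recovered_on_sloped_background(self, axis):
        peak = 1.5 * np.exp(-0.5 * ((axis - 900) / 8.0) ** 2)
        y = peak + (2.0 + 0.001 * axis)
        out = baseline_correct(y, axis, order=1)
        i = np.argmin(np.abs(axis - 900))
        assert out[i] == pytest.approx(1.5, rel=0.02)

    def test_invalid_order(self, axis):
        with pytest.raises(ValueError):
            baseline_correct(np.ones(axis.size), axis, order=5)


class TestSavitzkyGolay:
    def test_quadratic_preserved(self, axis):
        y = 1.0 + 0.01 * axis + 1e-5 * axis ** 2
        out = sg_smooth(y, window=25, polyorder=2)
        interior = slice(12, -12)
        assert np.max(np.abs(out[interior] - y[interior])) < 1e-9 * np.max(y)

    def test_noise_variance_reduced_by_kernel_norm(self, rng):
        """White-noise variance shrinks by the summed squared SG weights."""
        coeffs = savgol_coeffs(25, 2)
        expected = np.sum(coeffs ** 2)
        noise = rng.normal(0, 1.0, 200_000)
        out = sg_smooth(noise, window=25, polyorder=2)
        assert np.var(out[12:-12]) == pytest.approx(expected, rel=0.02)

    def test_matches_bruteforce_local_fit(self, rng):
        """window=5 smoothing equals an explicit per-point quadratic fit."""
        y = rng.normal(0, 1.0, 41)
        out = sg_smooth(y, window=5, polyorder=2)
        for i in range(2, 39):
            u = np.arange(-2, 3)
            coef = np.polynomial.polynomial.polyfit(u, y[i - 2:i + 3], 2)
            assert out[i] == pytest.approx(coef[0], abs=1e-10)

    def test_first_derivative_of_line_is_slope(self, axis):
        out = sg_derivative(2.0 + 0.25 * axis, axis, deriv_order=1)
        assert np.allclose(out, 0.25, atol=1e-9)

    def test_second_derivative_of_quadratic(self, axis):
        c = 3e-4
        out = sg_derivative(c * axis ** 2, axis, deriv_order=2,
                            window=25, polyorder=2)
        interior = slice(12, -12)
        assert np.allclose(out[interior], 2 * c, rtol=1e-6)

    def test_gaussian_derivative_zero_crossing_at_center(self, axis):
        y = np.exp(-0.5 * ((axis - 1000) / 15.0) ** 2)
        d = sg_derivative(y, axis, deriv_order=1, window=9, polyorder=3)
        i = np.argmin(np.abs(axis - 1000))
        assert np.sign(d[i - 3]) != np.sign(d[i + 3])
        assert abs(d[i]) < 1e-4

    def test_window_validation(self, axis):
        with pytest.raises(ValueError):
            sg_smooth(np.ones(100), window=24, polyorder=2)
        with pytest.raises(ValueError):
            sg_derivative(np.ones(100), np.arange(100.0), deriv_order=3)


class TestSnv:
    def test_output_standardized(self, rng):
        y = rng.normal(5, 2, (4, 300))
        out = snv(y)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1), 1, atol=1e-12)

    def test_affine_invariance(self, rng):
        y = rng.normal(0, 1, 300)
        assert np.allclose(snv(3.7 * y + 11.0), snv(y), atol=1e-10)

    def test_idempotent(self, rng):
        y = rng.normal(0, 1, 300)
        assert np.allclose(snv(snv(y)), snv(y), atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(100, 3.0))


class TestMsc:
    def test_reference_itself_unchanged(self, rng):
        ref = rng.normal(1, 0.3, 300)
        out = msc(ref[None, :], reference=ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_affine_distortion_inverted(self, rng):
        ref = rng.normal(1, 0.3, 300)
        out = msc((2.0 * ref + 3.0)[None, :], reference=ref)
        assert np.allclose(out[0], ref, atol=1e-9)

    def test_scatter_variance_reduced_on_replicates(self, rng, axis, library):
        import pandas as pd
        base = clean_mixture(
            pd.Series({"creatine": 5.0, "taurine": 0.0, "glutamine": 0.0}),
            library, axis)
        reps = np.stack([rng.uniform(0.7, 1.3) * base + rng.uniform(-0.2, 0.2)
                         + rng.normal(0, 0.005, axis.size) for _ in range(12)])
        corrected = msc(reps)
        assert (corrected.std(axis=0).mean()
                < 0.2 * reps.std(axis=0).mean())


class TestCrop:
    def test_identity_region(self, axis, rng):
        y = rng.normal(0, 1, axis.size)
        out, ax = crop(y, axis, [[400, 1800]])
        assert np.array_equal(out, y) and np.array_equal(ax, axis)

    @pytest.mark.parametrize("regions,n", [
        ([[800, 1000], [1300, 1500]], 402),
        ([[500, 1100]], 601),
    ])
    def test_inclusive_point_counts(self, axis, regions, n):
        _, ax = crop(np.ones(axis.size), axis, regions)
        assert ax.size == n

    def test_out_of_axis_region_rejected(self, axis):
        with pytest.raises(ValueError, match="outside"):
            crop(np.ones(axis.size), axis, [[300, 500]])

    def test_overlapping_regions_rejected(self, axis):
        with pytest.raises(ValueError, match="overlap"):
            crop(np.ones(axis.size), axis, [[500, 900], [800, 1000]])


class TestRecipe:
    def test_empty_recipe_is_identity(self, dataset):
        _, sset = dataset
        out = apply_recipe(sset, Recipe.make())
        assert np.array_equal(out.intensities, sset.intensities)

    def test_recipe_equals_manual_composition(self, dataset):
        _, sset = dataset
        recipe = Recipe.make(("sg_smooth", {"window": 25, "polyorder": 2}),
                             "snv")
        out = apply_recipe(sset, recipe)
        manual = snv(sg_smooth(sset.intensities, 25, 2))
        assert np.allclose(out.intensities, manual, atol=1e-12)

    def test_shorthand(self):
        r = Recipe.make("despike", ("baseline", {"order": 1}),
                        ("sg_smooth", {"window": 25, "polyorder": 2}), "snv")
        assert r.describe() == "SG + SNV"
        r2 = Recipe.make("sg_smooth",
                         ("sg_derivative", {"deriv_order": 1}))
        assert r2.describe() == "SG + 1st der."

    def test_config_round_trip(self):
        r = Recipe.make(("sg_smooth", {"window": 25, "polyorder": 2}), "msc")
        assert Recipe.from_config(r.to_config()) == r

    def test_msc_reference_comes_from_training_only(self, dataset):
        """Permuting or corrupting test rows must not change the transform
        applied to a given test spectrum when fit_on is supplied."""
        _, sset = dataset
        train = sset.subset(np.arange(0, 120))
        test = sset.subset(np.arange(120, 192))
        recipe = Recipe.make("snv", "msc")
        out1 = apply_recipe(test, recipe, fit_on=train)
        corrupted = test.copy()
        corrupted.intensities[1:] *= 3.0
        out2 = apply_recipe(corrupted, recipe, fit_on=train)
        assert np.allclose(out1.intensities[0], out2.intensities[0],
                           atol=1e-10)

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Recipe.make("fourier_magic")
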