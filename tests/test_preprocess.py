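import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramancellid.preprocess import (
    PLSDA_RECIPE,
    PreprocessError,
    PreprocessRecipe,
    Step,
    apply_recipe,
    despike,
    normalize_area,
    normalize_vector,
    savgol_smooth,
    second_derivative,
    subtract_baseline,
)
from ramancellid.spectral_data import Spectrum, WavenumberAxis

from conftest import lorentzian, make_dataset


class TestDespike:
    def test_smooth_band_untouched(self, toy_spectrum):
        out, spikes = despike(toy_spectrum)
        assert spikes.size == 0
        assert np.array_equal(out.intensities, toy_spectrum.intensities)

    def test_planted_spike_removed(self, fingerprint_axis):
        rng = np.random.default_rng(0)
        sigma = 0.01
        v = fingerprint_axis.values
        clean = lorentzian(v, 1003, 12, 1.0) + rng.normal(0, sigma, v.size)
        y = clean.copy()
        j = 500
        y[j] += 40 * sigma
        out, spikes = despike(Spectrum(fingerprint_axis, y))
        assert j in spikes
        assert abs(out.intensities[j] - clean[j]) <= 3 * sigma

    def test_unflagged_points_bitwise_unchanged(self, fingerprint_axis):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 0.01, len(fingerprint_axis))
        y[200] += 1.0
        s = Spectrum(fingerprint_axis, y)
        out, spikes = despike(s)
        keep = np.ones(y.size, dtype=bool)
        keep[spikes] = False
        assert np.array_equal(out.intensities[keep], y[keep])

    def test_edge_spike_no_crash(self, fingerprint_axis):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.01, len(fingerprint_axis))
        y[0] += 1.0
        out, spikes = despike(Spectrum(fingerprint_axis, y))
        assert np.all(np.isfinite(out.intensities))
        assert abs(out.intensities[0]) < 0.5

    def test_too_short_spectrum_rejected(self):
        s = Spectrum(WavenumberAxis(np.arange(4.0)), np.zeros(4))
        with pytest.raises(PreprocessError):
            despike(s)


class TestBaseline:
    def test_pure_polynomial_removed(self, fingerprint_axis):
        u = (fingerprint_axis.values - 1200) / 600.0
        y = 5 + 3 * u - 2 * u**2 + u**3 + 0.5 * u**4 - 0.2 * u**5
        s = Spectrum(fingerprint_axis, y)
        corrected, baseline = subtract_baseline(s, order=5)
        assert np.max(np.abs(corrected.intensities)) < 1e-6 * np.ptp(y)

    def test_band_heights_recovered(self, fingerprint_axis):
        v = fingerprint_axis.values
        u = (v - 1200) / 600.0
        base = 4 + 2 * u + u**2
        bands = (
            lorentzian(v, 800, 12, 1.0)
            + lorentzian(v, 1100, 12, 0.7)
            + lorentzian(v, 1550, 12, 1.3)
        )
        corrected, _ = subtract_baseline(Spectrum(fingerprint_axis, base + bands), 5)
        for center, amp in [(800, 1.0), (1100, 0.7), (1550, 1.3)]:
            window = np.abs(v - center) <= 8
            height = np.max(corrected.intensities[window])
            assert height == pytest.approx(amp, rel=0.05)

    def test_zero_spectrum(self, fingerprint_axis):
        s = Spectrum(fingerprint_axis, np.zeros(len(fingerprint_axis)))
        corrected, baseline = subtract_baseline(s)
        assert np.all(corrected.intensities == 0)
        assert np.allclose(baseline, 0)

    def test_reconstruction_identity(self, toy_spectrum):
        corrected, baseline = subtract_baseline(toy_spectrum)
        np.testing.assert_allclose(
            corrected.intensities + baseline,
            toy_spectrum.intensities,
            rtol=0, atol=1e-12 * np.max(np.abs(toy_spectrum.intensities)),
        )

    def test_axis_too_short_for_order(self):
        s = Spectrum(WavenumberAxis(np.arange(5.0)), np.ones(5))
        with pytest.raises(PreprocessError):
            subtract_baseline(s, order=5)


class TestSavgol:
    def test_cubic_reproduced_exactly(self, fingerprint_axis):
        v = fingerprint_axis.values / 1000.0
        y = v**3
        out = savgol_smooth(Spectrum(fingerprint_axis, y), 11, 3)
        interior = slice(5, -5)
        np.testing.assert_allclose(
            out.intensities[interior], y[interior], rtol=1e-8
        )

    def test_white_noise_variance_matches_coefficient_oracle(self):
        # independent local least-squares solve for the center-point weights
        width, order = 11, 3
        offsets = np.arange(width) - width // 2
        A = np.vander(offsets, order + 1, increasing=True)
        weights = (np.linalg.pinv(A.T @ A) @ A.T)[0]
        expected_var = float(np.sum(weights**2))

        rng = np.random.default_rng(0)
        n = 10_000
        y = rng.normal(0, 1.0, n)
        s = Spectrum(WavenumberAxis(np.arange(n, dtype=float)), y)
        out = savgol_smooth(s, width, order)
        observed = float(np.var(out.intensities[width:-width]))
        assert observed == pytest.approx(expected_var, rel=0.05)

    def test_constant_unchanged(self, fingerprint_axis):
        s = Spectrum(fingerprint_axis, np.full(len(fingerprint_axis), 3.5))
        out = savgol_smooth(s)
        np.testing.assert_allclose(out.intensities, 3.5, rtol=1e-12)

    def test_even_width_rejected(self, toy_spectrum):
        with pytest.raises(PreprocessError):
            savgol_smooth(toy_spectrum, width=10)


class TestSecondDerivative:
    def test_quadratic_constant_curvature(self):
        ax = WavenumberAxis(np.arange(600.0, 700.0, 0.5))
        a = 0.03
        y = a * ax.values**2
        out = second_derivative(Spectrum(ax, y), 11, 3)
        interior = slice(6, -6)
        np.testing.assert_allclose(out.intensities[interior], 2 * a, rtol=1e-8)

    def test_linear_gives_zero(self, fingerprint_axis):
        y = 0.01 * fingerprint_axis.values + 3
        out = second_derivative(Spectrum(fingerprint_axis, y))
        assert np.max(np.abs(out.intensities)) < 1e-10

    def test_gaussian_negative_extremum_at_center(self, fingerprint_axis):
        v = fingerprint_axis.values
        fwhm, A, c = 20.0, 1.0, 1200.0
        k = 4 * np.log(2) / fwhm**2
        y = A * np.exp(-k * (v - c) ** 2)
        out = second_derivative(Spectrum(fingerprint_axis, y), 11, 3)
        i = int(np.argmin(out.intensities))
        assert v[i] == pytest.approx(c, abs=1.0)
        # analytic gaussian second derivative at the center is -2kA; the
        # 11-point window attenuates the curvature by a few percent
        assert out.intensities[i] == pytest.approx(-2 * k * A, rel=0.10)
        assert out.intensities[i] < 0


class TestNormalization:
    def test_area_norm_constant_closed_form(self):
        ax = WavenumberAxis(np.arange(0.0, 101.0))
        s = Spectrum(ax, np.full(101, 2.0))
        out = normalize_area(s)
        np.testing.assert_allclose(out.intensities, 1.0 / 100.0, rtol=1e-12)

    def test_vector_norm_closed_form(self):
        ax = WavenumberAxis(np.array([0.0, 1.0]))
        out = normalize_vector(Spectrum(ax, np.array([3.0, 4.0])))
        np.testing.assert_allclose(out.intensities, [0.6, 0.8], rtol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    def test_idempotent_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        ax = WavenumberAxis(np.arange(50.0))
        y = rng.normal(1.0, 0.3, 50)
        s = Spectrum(ax, y)
        for f in (normalize_area, normalize_vector):
            once = f(s)
            np.testing.assert_allclose(
                f(once).intensities, once.intensities, atol=1e-12
            )
            np.testing.assert_allclose(
                f(Spectrum(ax, scale * y)).intensities, once.intensities, atol=1e-9
            )

    def test_zero_input_rejected(self, fingerprint_axis):
        z = Spectrum(fingerprint_axis, np.zeros(len(fingerprint_axis)))
        with pytest.raises(PreprocessError):
            normalize_area(z)
        with pytest.raises(PreprocessError):
            normalize_vector(z)


class TestRecipes:
    def test_empty_recipe_is_identity(self, small_sim):
        d, _ = small_sim
        out = apply_recipe(d, PreprocessRecipe())
        assert np.array_equal(out.matrix, d.matrix)

    def test_area_norm_recipe_unit_rows(self, small_sim):
        d, _ = small_sim
        out = apply_recipe(d.select(np.arange(3)), PreprocessRecipe((Step("area_norm"),)))
        areas = np.trapezoid(np.abs(out.matrix), d.axis.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_plsda_recipe_centers_columns(self, small_sim):
        d, _ = small_sim
        out = apply_recipe(d, PLSDA_RECIPE)
        assert np.max(np.abs(out.matrix.mean(axis=0))) < 1e-10

    def test_mean_center_single_spectrum_rejected(self, small_sim):
        d, _ = small_sim
        single = d.select(np.array([0]))
        with pytest.raises(PreprocessError):
            apply_recipe(single, PreprocessRecipe((Step("mean_center"),)))

    def test_invalid_savgol_step_rejected(self):
        with pytest.raises(PreprocessError):
            Step("savgol", {"width": 4, "polyorder": 3})

    def test_recipe_config_round_trip(self):
        cfg = ["vector_norm", {"derivative": {"order": 2, "width": 15, "polyorder": 3}}]
        r = PreprocessRecipe.from_config(cfg)
        assert r.to_config() == cfg


def test_noise_free_simulation_band_shapes_survive_conditioning(templates):
    """Without noise or spikes, despike+baseline preserve the strong marker
    bands' peak heights within 5%; weak bands riding the overlapping-tail
    pedestal are attenuated more (an inherent cost of polynomial baselines)."""
    from ramancellid.synthetic_data import (
        SimulationConfig, band_profile, simulate_dataset,
    )

    cfg = SimulationConfig(
        n_cells_per_class=1, n_points_per_cell=1,
        cell_amplitude_cv=0, point_amplitude_cv=0, baseline_cv=0,
        noise_scale=0, cosmic_ray_rate=0, seed=0,
    )
    d, truth = simulate_dataset(cfg, templates[:1])
    recipe = PreprocessRecipe((Step("despike"), Step("baseline", {"order": 5})))
    out = apply_recipe(d, recipe)
    v = d.axis.values
    bands_only = np.sum(
        [band_profile(v, b) for b in templates[0].bands], axis=0
    )
    for center in (1003.0, 1301.0, 1440.0, 1658.0):
        w = np.abs(v - center) <= 8
        assert np.max(out.matrix[0][w]) == pytest.approx(
            np.max(bands_only[w]), rel=0.05
        )
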