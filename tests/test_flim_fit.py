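import numpy as np
import pytest

from test_synthetic_decay import invert_truncated_mean

from cln3topo.flim import (DecayHistogram, FitError, bin_pixels,
                           filter_background, fit_biexponential,
                           lifetime_population_peaks)
from cln3topo.synthetic import DecayParams, generate_decay_histogram, \
    generate_flim_image


class TestBinning:
    def test_factor_five_blocks_sum(self):
        grid = generate_flim_image((10, 10), DecayParams(), 100, seed=0)
        binned = bin_pixels(grid, 5)
        assert binned.shape == (2, 2)
        np.testing.assert_array_equal(binned.totals, np.full((2, 2), 2500))

    def test_factor_one_is_identity(self):
        grid = generate_flim_image((4, 4), DecayParams(), 50, seed=0)
        np.testing.assert_array_equal(bin_pixels(grid, 1).counts, grid.counts)

    def test_partial_blocks_conserve_photons(self):
        grid = generate_flim_image((7, 9), DecayParams(), 60, seed=0)
        assert bin_pixels(grid, 5).counts.sum() == grid.counts.sum()

    @pytest.mark.parametrize("factor", [0, -2, 100])
    def test_invalid_factor_rejected(self, factor):
        grid = generate_flim_image((4, 4), DecayParams(), 50, seed=0)
        with pytest.raises(ValueError):
            bin_pixels(grid, factor)


class TestBackgroundFilter:
    def test_threshold_semantics_are_strictly_less_than(self):
        counts = np.array([[24, 25]])
        grid = generate_flim_image((1, 2), DecayParams(), counts, seed=0)
        mask = filter_background(grid, 25)
        assert not mask[0, 0] and mask[0, 1]

    def test_zero_threshold_retains_everything(self):
        grid = generate_flim_image((3, 3), DecayParams(), 5, seed=0)
        assert filter_background(grid, 0).all()

    def test_filter_is_idempotent(self):
        grid = generate_flim_image((4, 4), DecayParams(), 30, seed=0)
        m1 = filter_background(grid, 25)
        np.testing.assert_array_equal(m1, filter_background(grid, 25))


class TestBiexponentialFit:
    def test_monoexponential_input_flags_degenerate_and_matches_mle(self):
        params = DecayParams(components=((1.0, 2.0),))
        h = generate_decay_histogram(params, 10 ** 6, seed=3)
        fit = fit_biexponential(h)
        assert fit.degenerate
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        mle = invert_truncated_mean(float((centers * h.counts).sum() / h.n_photons),
                                    h.window)
        assert fit.mean_lifetime == pytest.approx(mle, abs=0.02)
        assert fit.mean_lifetime == pytest.approx(2.0, abs=0.02)

    def test_pooled_donor_pair_recovery_with_fixed_fraction(self):
        """The printed donor-only pair is recovered from a pooled deep decay."""
        params = DecayParams(components=((0.5, 2.28), (0.5, 2.14)))
        h = generate_decay_histogram(params, 10 ** 7, seed=5)
        fit = fit_biexponential(h, fix={"f1": 0.5, "bg": 0.0})
        assert fit.tau1 == pytest.approx(2.28, abs=0.03)
        assert fit.tau2 == pytest.approx(2.14, abs=0.03)

    def test_too_few_photons_rejected(self):
        h = generate_decay_histogram(DecayParams(), 10, seed=0)
        with pytest.raises(FitError):
            fit_biexponential(h)

    def test_too_few_bins_rejected(self):
        h = DecayHistogram(np.linspace(0, 12.5, 7), np.full(6, 100))
        with pytest.raises(FitError):
            fit_biexponential(h)

    def test_unknown_fixed_parameter_rejected(self):
        h = generate_decay_histogram(DecayParams(), 1000, seed=0)
        with pytest.raises(ValueError):
            fit_biexponential(h, fix={"tau3": 1.0})


class TestPopulationPeaks:
    def test_gaussian_population_peak_recovered(self):
        rng = np.random.default_rng(12)
        taus = rng.normal(2.05, 0.04, size=500)
        peak = lifetime_population_peaks(taus)
        assert peak.peak == pytest.approx(2.05, abs=0.01)
        assert peak.width == pytest.approx(0.04, abs=0.02)

    def test_identical_values_give_zero_width(self):
        peak = lifetime_population_peaks(np.full(50, 2.28))
        assert peak.peak == pytest.approx(2.28)
        assert peak.width == pytest.approx(0.0, abs=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            lifetime_population_peaks(np.full(5, 2.0))

    def test_non_finite_values_rejected(self):
        vals = np.full(30, 2.0)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            lifetime_population_peaks(vals)
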