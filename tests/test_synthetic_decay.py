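import numpy as np
import pytest
from scipy.optimize import brentq

from cln3topo.flim import filter_background
from cln3topo.synthetic import (DecayParams, generate_decay_histogram,
                                generate_flim_image)


def invert_truncated_mean(mean_t: float, window: float) -> float:
    """Closed-form oracle: lifetime whose window-truncated mean is ``mean_t``."""
    def trunc_mean(tau):
        return tau - window / np.expm1(window / tau)
    return brentq(lambda tau: trunc_mean(tau) - mean_t, 1e-3, 1e3)


def test_mean_arrival_time_matches_truncated_exponential_oracle():
    params = DecayParams(components=((1.0, 2.0),), time_window=25.0, n_bins=500)
    h = generate_decay_histogram(params, 10 ** 6, seed=42)
    centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
    mean_t = float(np.sum(centers * h.counts) / h.n_photons)
    assert invert_truncated_mean(mean_t, 25.0) == pytest.approx(2.0, abs=0.02)


@pytest.mark.parametrize("params,n", [
    (DecayParams(components=((0.5, 2.28), (0.5, 2.14))), 12345),
    (DecayParams(components=((1.0, 1.0),), background_fraction=0.2), 999),
])
def test_photon_conservation(params, n):
    h = generate_decay_histogram(params, n, seed=0)
    assert h.n_photons == n
    assert (h.counts >= 0).all()


def test_zero_photons_rejected():
    with pytest.raises(ValueError):
        generate_decay_histogram(DecayParams(), 0, seed=0)


@pytest.mark.parametrize("bad", [
    dict(components=((0.5, 2.0), (0.6, 1.0))),       # fractions sum > 1
    dict(components=((1.0, -2.0),)),                 # negative lifetime
    dict(components=((1.0, 2.0),), n_bins=4),        # too few bins
    dict(components=((1.0, 2.0),), background_fraction=1.0),
])
def test_invalid_decay_params_rejected(bad):
    with pytest.raises(ValueError):
        DecayParams(**bad)


def test_same_seed_reproduces_histogram_exactly():
    p = DecayParams(components=((0.5, 2.28), (0.5, 2.14)))
    a = generate_decay_histogram(p, 5000, seed=7)
    b = generate_decay_histogram(p, 5000, seed=7)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = generate_decay_histogram(p, 5000, seed=8)
    assert (a.counts != c.counts).any()


class TestFlimImage:
    def test_uniform_grid_conserves_counts_per_pixel(self):
        grid = generate_flim_image((16, 16), DecayParams(), 500, seed=0)
        np.testing.assert_array_equal(grid.totals, np.full((16, 16), 500))

    def test_pixels_missing_from_map_get_zero_counts(self):
        pmap = {(0, 0): DecayParams(), (2, 3): DecayParams()}
        grid = generate_flim_image((4, 4), pmap, 100, seed=0)
        assert grid.totals[0, 0] == 100 and grid.totals[2, 3] == 100
        assert grid.totals.sum() == 200

    def test_low_count_pixels_fail_the_background_filter(self):
        counts = np.full((6, 6), 10)
        counts[:3] = 200
        grid = generate_flim_image((6, 6), DecayParams(), counts, seed=1)
        mask = filter_background(grid, min_counts=25)
        assert mask[:3].all() and not mask[3:].any()

    def test_different_seeds_differ(self):
        a = generate_flim_image((4, 4), DecayParams(), 200, seed=0)
        b = generate_flim_image((4, 4), DecayParams(), 200, seed=1)
        assert (a.counts != b.counts).any()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_flim_image((2, 2), DecayParams(), -5, seed=0)
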