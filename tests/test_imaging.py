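import numpy as np
import pandas as pd
import pytest

from cln3topo.imaging import (colocalization_fraction, detect_small_vesicles,
                              rescue_experiment, rescue_ratio)
from cln3topo.synthetic import FieldScenario, generate_cell_field, \
    generate_coloc_pair


class TestColocalization:
    def test_identical_channels_fully_colocalize(self):
        f = generate_coloc_pair(1.0, 80, seed=3)
        res = colocalization_fraction(f.channels[0], f.channels[1])
        assert res.fraction >= 0.95

    def test_disjoint_channels_do_not_colocalize(self):
        f = generate_coloc_pair(0.0, 80, seed=3)
        res = colocalization_fraction(f.channels[0], f.channels[1])
        assert res.fraction <= 0.05

    def test_half_overlap_recovered(self):
        f = generate_coloc_pair(0.5, 200, seed=3, shape=(512, 512))
        res = colocalization_fraction(f.channels[0], f.channels[1])
        assert res.fraction == pytest.approx(0.5, abs=0.1)

    def test_symmetric_under_channel_swap_for_identical_objects(self):
        f = generate_coloc_pair(1.0, 60, seed=9)
        ab = colocalization_fraction(f.channels[0], f.channels[1]).fraction
        ba = colocalization_fraction(f.channels[1], f.channels[0]).fraction
        assert ab == pytest.approx(ba, abs=0.02)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            colocalization_fraction(np.ones((4, 4)), np.ones((5, 5)))

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            colocalization_fraction(np.zeros((8, 8)), np.ones((8, 8)))

    def test_overlap_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            generate_coloc_pair(1.2, 10, seed=0)


class TestVesicleDetection:
    def test_planted_two_micron_vesicles_recovered(self):
        sc = FieldScenario(n_cells=25, vesicle_diameter_range=(2.0, 2.0),
                           fold_change=1.0, seed=4)
        field = generate_cell_field(sc)
        detected = detect_small_vesicles(field.channels[1], sc.pixel_size)
        n_true = len(field.objects)
        recall = len(detected) / n_true
        assert recall >= 0.9
        # precision: every detection near a true object
        close = 0
        for v in detected:
            d = np.hypot(field.objects.x_um - v.x_um, field.objects.y_um - v.y_um)
            close += (d.min() <= 1.0)
        assert close / len(detected) >= 0.9

    def test_large_blobs_outside_gate_are_ignored(self):
        sc = FieldScenario(n_cells=10, vesicle_diameter_range=(5.0, 5.0),
                           base_vesicle_mean=4.0, fold_change=1.0, seed=4)
        field = generate_cell_field(sc)
        assert detect_small_vesicles(field.channels[1], sc.pixel_size,
                                     (1.0, 3.0)) == []

    def test_empty_image_gives_empty_list(self):
        assert detect_small_vesicles(np.zeros((64, 64)), 0.1) == []

    def test_count_invariant_to_uniform_intensity_scaling(self):
        sc = FieldScenario(n_cells=12, seed=8)
        field = generate_cell_field(sc)
        img = field.channels[1]
        n1 = len(detect_small_vesicles(img, sc.pixel_size))
        n2 = len(detect_small_vesicles(img * 3.7, sc.pixel_size))
        assert n1 == n2

    def test_unresolvable_diameter_range_rejected(self):
        with pytest.raises(ValueError):
            detect_small_vesicles(np.ones((10, 10)), pixel_size=1.0,
                                  diameter_range=(1.0, 3.0))


class TestRescueRatio:
    @staticmethod
    def table(t_counts, nt_counts):
        return pd.DataFrame({
            "cell_id": range(len(t_counts) + len(nt_counts)),
            "transfected": [True] * len(t_counts) + [False] * len(nt_counts),
            "n_vesicles": list(t_counts) + list(nt_counts)})

    def test_equal_groups_have_unit_ratio(self):
        res = rescue_ratio(self.table([5, 7, 6, 8], [8, 6, 7, 5]))
        assert res.ratio == pytest.approx(1.0)
        assert np.isfinite(res.p_value)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rescue_ratio(self.table([5, 6], [0, 0]))

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            rescue_ratio(self.table([5, 6], []))

    def test_sem_matches_error_propagation(self):
        t, nt = [10, 14, 12, 16], [8, 6, 7, 9]
        res = rescue_ratio(self.table(t, nt))
        st = np.std(t, ddof=1) / 2
        sn = np.std(nt, ddof=1) / 2
        expected = res.ratio * np.hypot(st / np.mean(t), sn / np.mean(nt))
        assert res.sem == pytest.approx(expected)


@pytest.mark.parametrize("fold", [0.5, 1.0, 2.0])
def test_end_to_end_fold_change_recovery(fold):
    """Detection + ratio recover the generator's fold change within 3 SE."""
    sc = FieldScenario(n_cells=250, fold_change=fold, seed=21)
    res = rescue_experiment(sc)
    assert res.ratio == pytest.approx(fold, abs=max(3 * res.sem, 0.05))
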