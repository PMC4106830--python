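import numpy as np
import pytest

from helpers import (brute_force_best, brute_force_min_tm,
                     random_feasible_constraints)

from cln3topo.synthetic import generate_planted_sequence
from cln3topo.topology import (PredictorParams, Segment, TopologyConstraint,
                               TopologyModel, check_model, min_tm_count,
                               predict_topology)

C = TopologyConstraint
AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize("trial", range(25))
def test_dp_matches_exhaustive_enumeration(trial):
    """DP optimum equals brute-force enumeration on short random inputs."""
    rng = np.random.default_rng(1000 + trial)
    length = int(rng.integers(20, 56))
    seq = "".join(AA[i] for i in rng.integers(0, 20, length))
    cons = random_feasible_constraints(rng, length)
    params = PredictorParams()
    model = predict_topology(seq, cons, params)
    oracle = brute_force_best(seq, cons, params)
    if model is None:
        assert oracle is None
    else:
        assert oracle is not None
        assert model.score == pytest.approx(oracle[0], abs=1e-6)
        assert model.n_tm == oracle[1]
        assert check_model(model, cons, params) == []


@pytest.mark.parametrize("trial", range(15))
def test_min_tm_count_matches_independent_recursion(trial):
    rng = np.random.default_rng(7000 + trial)
    length = int(rng.integers(20, 70))
    cons = random_feasible_constraints(rng, length)
    params = PredictorParams()
    try:
        oracle = brute_force_min_tm(length, cons, params)
    except ValueError:
        with pytest.raises(ValueError):
            min_tm_count(cons, length, params)
        return
    assert min_tm_count(cons, length, params) == oracle


@pytest.mark.parametrize("cons,expected", [
    ([C.at(5, "inside"), C.at(30, "outside")], 1),
    ([C.at(5, "inside"), C.at(30, "outside"), C.at(60, "inside")], 2),
    ([], 0),
])
def test_min_tm_count_alternation_examples(cons, expected):
    assert min_tm_count(cons, 90) == expected


def test_min_tm_count_none_when_crossing_cannot_fit():
    """A crossing with fewer residues than one helix is geometrically impossible."""
    assert min_tm_count([C.at(5, "inside"), C.at(20, "outside")], 60) is None


def test_contradictory_point_constraints_are_infeasible_not_an_exception():
    seq = "L" * 40
    model = predict_topology(seq, [C.at(10, "inside"), C.at(10, "outside")])
    assert model is None


def test_adding_constraints_never_improves_the_optimum():
    rng = np.random.default_rng(99)
    seq = "".join(AA[i] for i in rng.integers(0, 20, 50))
    base_model = predict_topology(seq)
    for state in ("inside", "outside", "membrane"):
        m = predict_topology(seq, [C.at(25, state)])
        if m is not None:
            assert m.score <= base_model.score + 1e-9


def test_prediction_is_deterministic(cln3_sequence):
    a = predict_topology(cln3_sequence)
    b = predict_topology(cln3_sequence)
    assert a.segments == b.segments
    assert a.score == b.score


class TestPlantedRecovery:
    def test_no_tms_planted_none_predicted(self):
        planted = generate_planted_sequence(0, 20, seed=1)
        model = predict_topology(planted.sequence)
        assert model is not None and model.n_tm == 0

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_single_tm_recovered_with_overlap(self, seed):
        planted = generate_planted_sequence(1, 30, seed=seed)
        tm = planted.tm_segments[0]
        model = predict_topology(planted.sequence)
        assert model.n_tm == 1
        pred = model.tm_segments[0]
        overlap = min(pred.end, tm.end) - max(pred.start, tm.start) + 1
        assert overlap >= 15

    @pytest.mark.parametrize("n_tms", [2, 6])
    def test_multi_tm_count_recovered(self, n_tms):
        planted = generate_planted_sequence(n_tms, 12, seed=5)
        model = predict_topology(planted.sequence)
        assert model.n_tm == n_tms

    def test_parity_oracle_on_truth_loop_constraints(self):
        """Loop-derived sidedness constraints of a 6-TM sequence demand 6 TMs."""
        planted = generate_planted_sequence(6, 12, seed=5)
        cons = [C.at((s.start + s.end) // 2, s.state)
                for s in planted.true_segments if s.state != "membrane"]
        assert min_tm_count(cons, len(planted.sequence)) == 6


class TestCheckModel:
    def test_violation_reported_per_constraint(self, published_model):
        violations = check_model(published_model, [C.at(1, "outside")])
        assert len(violations) == 1

    def test_structural_error_on_adjacent_loops(self):
        segs = (Segment(1, 10, "inside"), Segment(11, 30, "inside"))
        model = TopologyModel(segments=segs, score=0.0, length=30)
        with pytest.raises(ValueError):
            check_model(model, [])

    def test_structural_error_on_gap(self):
        segs = (Segment(1, 10, "inside"), Segment(12, 40, "membrane"))
        model = TopologyModel(segments=segs, score=0.0, length=40)
        with pytest.raises(ValueError):
            check_model(model, [])
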