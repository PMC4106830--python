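import pytest

from cln3topo import constraints as cb
from cln3topo.flim import FretMeasurement
from cln3topo.synthetic import generate_planted_sequence
from cln3topo.topology import PredictorParams, TopologyConstraint, predict_topology

C = TopologyConstraint


def measurement(clone, eff):
    return FretMeasurement.from_lifetimes(clone, 2.14, 2.14 * (1 - eff / 100))


class TestConstraintFromClone:
    @pytest.mark.parametrize("clone,eff,site", [
        ("myc1", 12.0, 37), ("myc6", 14.7, 204)])
    def test_significant_fret_pins_following_residue_to_anchor_side(self, clone, eff, site):
        ins = cb.get_insertion(clone)
        c = cb.constraint_from_clone(ins, measurement(clone, eff), "inside", 438)
        assert (c.start, c.end, c.state, c.provenance) == (site, site, "inside", "fret")

    def test_non_significant_fret_yields_no_constraint(self):
        c = cb.constraint_from_clone(cb.get_insertion("myc2"),
                                     measurement("myc2", 4.0), "inside", 438)
        assert c is None

    def test_above_range_fret_yields_no_constraint(self):
        c = cb.constraint_from_clone(cb.get_insertion("myc2"),
                                     measurement("myc2", 95.0), "inside", 438)
        assert c is None

    def test_insertion_outside_sequence_rejected(self):
        ins = cb.TagInsertion("x", "myc", 500)
        with pytest.raises(ValueError):
            cb.constraint_from_clone(ins, measurement("x", 12.0), "inside", 438)


class TestPriorRegistry:
    def test_expected_constraints_for_cln3_length(self):
        cons = cb.prior_constraints(438)
        as_tuples = {(c.start, c.end, c.state) for c in cons}
        assert as_tuples == {(250, 258, "inside"), (401, 401, "inside"),
                             (438, 438, "inside"), (71, 71, "outside"),
                             (85, 85, "outside")}

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            cb.prior_constraints(100)

    def test_registry_round_trips_through_tsv(self, tmp_path):
        from cln3topo.io import read_constraints_tsv, write_constraints_tsv
        cons = cb.prior_constraints(438)
        path = tmp_path / "c.tsv"
        write_constraints_tsv(cons, path)
        assert read_constraints_tsv(path) == cons


class TestEvaluateSite:
    def test_membrane_state_scores_highest_inside_a_planted_tm(self):
        planted = generate_planted_sequence(1, 30, seed=3)
        tm = planted.tm_segments[0]
        site = (tm.start + tm.end) // 2
        base = [C.at(1, "inside")]
        rels, scores = cb._evaluate_site_full(planted.sequence, base, site,
                                              None, PredictorParams(), None)
        assert scores["membrane"] == max(v for v in scores.values() if v is not None)

    def test_already_constrained_site_rejected(self):
        planted = generate_planted_sequence(1, 30, seed=3)
        with pytest.raises(ValueError, match="already constrained"):
            cb.evaluate_site(planted.sequence, [C.at(5, "inside")], 5)

    def test_impossible_state_reported_infeasible_not_raised(self):
        # membrane at residue 3 cannot host a 17-residue helix between the
        # pinned loops at 2 and 4
        seq = generate_planted_sequence(1, 30, seed=3).sequence
        base = [C.at(2, "inside"), C.at(4, "inside")]
        rels = cb.evaluate_site(seq, base, 3)
        assert rels["membrane"] is None
        assert rels["inside"] is not None


class TestAccumulation:
    def test_single_site_with_single_feasible_state(self):
        seq = generate_planted_sequence(1, 30, seed=3).sequence
        base = [C.at(2, "inside"), C.at(4, "inside")]
        trace = cb.iterative_accumulation(seq, [3], base, direction="N_start")
        assert trace.decisions[0].chosen == "inside"

    def test_trace_is_deterministic(self, cln3_sequence):
        base = cb.cln3_base_constraints(len(cln3_sequence))
        sites = cb.cln3_candidate_sites(base)[:3]
        t1 = cb.iterative_accumulation(cln3_sequence, sites, base, "C_start")
        t2 = cb.iterative_accumulation(cln3_sequence, sites, base, "C_start")
        assert t1.as_records() == t2.as_records()

    def test_scrambled_order_depends_only_on_seed(self):
        sites = [86, 102, 126, 239, 280, 346, 349]
        a = cb.order_sites(sites, "scrambled", seed=4)
        b = cb.order_sites(sites, "scrambled", seed=4)
        c = cb.order_sites(sites, "scrambled", seed=5)
        assert a == b
        assert sorted(a) == sorted(sites)
        assert a != c or True  # different seeds may coincide; identity is not required

    def test_scrambled_without_seed_rejected(self):
        with pytest.raises(ValueError):
            cb.order_sites([1, 2], "scrambled")

    def test_chosen_state_has_maximal_score_in_trace(self, cln3_sequence):
        base = cb.cln3_base_constraints(len(cln3_sequence))
        sites = cb.cln3_candidate_sites(base)[:4]
        trace = cb.iterative_accumulation(cln3_sequence, sites, base, "N_start")
        for d in trace.decisions:
            if d.skipped:
                continue
            finite = [v for v in d.scores.values() if v is not None]
            assert d.scores[d.chosen] == pytest.approx(max(finite))

    def test_final_constraint_set_is_mutually_consistent(self, cln3_sequence):
        base = cb.cln3_base_constraints(len(cln3_sequence))
        sites = cb.cln3_candidate_sites(base)
        trace = cb.iterative_accumulation(cln3_sequence, sites, base, "C_start")
        assert predict_topology(cln3_sequence, trace.constraints) is not None


def test_cln3_candidate_sites_exclude_significant_clones(cln3_sequence):
    base = cb.cln3_base_constraints(len(cln3_sequence))
    assert cb.cln3_candidate_sites(base) == [86, 102, 126, 239, 280, 346, 349]


def test_model_d_adds_membrane_constraint_at_151(cln3_sequence):
    base = cb.cln3_base_constraints(len(cln3_sequence), model_d=True)
    assert C.at(151, "membrane", provenance="fret") in base
    model = predict_topology(cln3_sequence, base)
    assert model is not None
    assert any(s.start <= 151 <= s.end for s in model.tm_segments)
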