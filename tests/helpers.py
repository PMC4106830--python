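"""Independent oracles for the topology grammar, used only by the tests.

These deliberately do not reuse the package's dynamic program: scores come
from explicit enumeration of every grammar-valid segmentation, and minimum
TM counts from a top-down recursion, so they can act as independent checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from cln3topo.hydropathy import residue_deltaG
from cln3topo.topology import PredictorParams, TopologyConstraint


def enumerate_segmentations(length: int, params: PredictorParams):
    """Yield every grammar-valid segmentation as [(start0, end0, state), ...]."""
    out = []

    def rec(pos, segs, last_side, prev_is_tm):
        if pos == length:
            if not prev_is_tm:
                out.append(list(segs))
            return
        if prev_is_tm or pos == 0:
            minlen = 1 if pos == 0 else params.loop_min
            for side in ("inside", "outside"):
                if prev_is_tm and side == last_side:
                    continue
                for ln in range(minlen, length - pos + 1):
                    segs.append((pos, pos + ln - 1, side))
                    rec(pos + ln, segs, side, False)
                    segs.pop()
        else:
            for t in range(params.min_tm, params.max_tm + 1):
                if pos + t >= length:  # a loop of >=1 residue must follow
                    continue
                segs.append((pos, pos + t - 1, "membrane"))
                rec(pos + t, segs, last_side, True)
                segs.pop()

    rec(0, [], None, False)
    return out


def segmentation_satisfies(segs, constraints):
    state_of = {}
    for a, b, s in segs:
        for i in range(a, b + 1):
            state_of[i] = s
    for c in constraints:
        for i in range(c.start - 1, c.end):
            if state_of[i] != c.state:
                return False
    return True


def brute_force_best(sequence: str, constraints, params: PredictorParams):
    """(score, n_tm) of the best segmentation by exhaustive enumeration, or None."""
    dg = residue_deltaG(sequence)
    gain = params.insertion_offset - dg
    rk = np.array([aa in "RK" for aa in sequence])
    best = None
    for segs in enumerate_segmentations(len(sequence), params):
        if not segmentation_satisfies(segs, constraints):
            continue
        score, ntm = 0.0, 0
        for a, b, s in segs:
            if s == "membrane":
                score += gain[a:b + 1].sum() - params.tm_cost
                ntm += 1
            elif s == "inside":
                score += params.rk_bonus * rk[a:b + 1].sum()
        if (best is None or score > best[0] + 1e-9
                or (abs(score - best[0]) <= 1e-9 and ntm < best[1])):
            best = (score, ntm)
    return best


def brute_force_min_tm(length: int, constraints, params: PredictorParams):
    """Minimal TM count via top-down recursion (independent of the DP)."""
    allow = {s: np.ones(length, dtype=bool) for s in ("inside", "membrane", "outside")}
    for c in constraints:
        for s in allow:
            if s != c.state:
                allow[s][c.start - 1:c.end] = False
    if not (allow["inside"] | allow["membrane"] | allow["outside"]).all():
        raise ValueError("contradictory constraints")
    INF = 10 ** 9
    flip = {"inside": "outside", "outside": "inside"}

    def loop_ok(a, b, side):  # 0-based inclusive
        return bool(allow[side][a:b + 1].all())

    def mem_ok(a, b):
        return bool(allow["membrane"][a:b + 1].all())

    @lru_cache(maxsize=None)
    def from_loop(pos, side):
        """Min TMs for residues pos..L-1 where pos starts a loop of ``side``."""
        best = INF
        minlen = params.loop_min if pos > 0 else 1
        for ln in range(minlen, length - pos + 1):
            end = pos + ln - 1
            if not loop_ok(pos, end, side):
                break
            if end == length - 1:
                best = min(best, 0)
                continue
            for t in range(params.min_tm, params.max_tm + 1):
                tm_end = end + t
                if tm_end >= length - 1:  # need >=1 residue after the TM
                    break
                if mem_ok(end + 1, tm_end):
                    sub = from_loop(tm_end + 1, flip[side])
                    if sub < INF:
                        best = min(best, 1 + sub)
        return best

    best = min(from_loop(0, "inside"), from_loop(0, "outside"))
    return None if best >= INF else best


def random_feasible_constraints(rng, length, n_max=3):
    """Random (possibly empty) constraint set; may or may not be feasible."""
    cons = []
    for _ in range(rng.integers(0, n_max + 1)):
        a = int(rng.integers(1, length + 1))
        b = min(length, a + int(rng.integers(0, 3)))
        state = ("inside", "outside", "membrane")[int(rng.integers(3))]
        cons.append(TopologyConstraint(a, b, state))
    return cons
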