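"""Constrained membrane-topology prediction.

The predictor segments a protein sequence into alternating loops and
transmembrane (TM) helices under a topology grammar:

* loop sides strictly alternate between cytosolic ("inside") and
  luminal/extracellular ("outside") across consecutive loops;
* every TM helix length lies within ``[min_tm, max_tm]`` residues;
* interior loops have at least ``loop_min`` residues, terminal loops at
  least one.

Each candidate segmentation is scored with a hydrophobicity ΔG scale: a
residue placed in the membrane contributes ``insertion_offset − ΔG(aa)``
(so hydrophobic residues reward membrane placement), every helix pays a
fixed insertion cost ``tm_cost`` that suppresses marginally hydrophobic
helices, and inside loops earn a positive-inside bonus per Arg/Lys. Hard sidedness/membrane constraints
restrict the states available to individual residues; when no grammar-valid
segmentation satisfies them the prediction is *infeasible* (returned as
``None``), mirroring the failed-to-compute behaviour of consensus topology
servers under contradictory constraints.

The optimum is found by dynamic programming over (position, current loop
side); an exhaustive enumeration oracle for short sequences lives in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .hydropathy import residue_deltaG

State = Literal["inside", "membrane", "outside"]

_STATE_ALIASES = {
    "inside": "inside", "in": "inside", "i": "inside", "cytosolic": "inside",
    "cyt": "inside", "outside": "outside", "out": "outside", "o": "outside",
    "luminal": "outside", "lumenal": "outside", "membrane": "membrane",
    "m": "membrane", "tm": "membrane",
}

_STATE_CHAR = {"inside": "i", "membrane": "M", "outside": "o"}
_EPS = 1e-9


def normalize_state(state: str) -> State:
    try:
        return _STATE_ALIASES[state.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown topology state {state!r}") from None


@dataclass(frozen=True)
class TopologyConstraint:
    """Pin a 1-based residue (or inclusive range) to a topological state."""

    start: int
    end: int
    state: State
    provenance: str = "assumption"

    def __post_init__(self):
        object.__setattr__(self, "state", normalize_state(self.state))
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid constraint range {self.start}..{self.end}")

    @classmethod
    def at(cls, residue: int, state: str, provenance: str = "assumption") -> "TopologyConstraint":
        return cls(residue, residue, state, provenance)


class Segment(NamedTuple):
    start: int  # 1-based inclusive
    end: int
    state: State


@dataclass(frozen=True)
class PredictorParams:
    """Tunable parameters of the topology engine.

    ``insertion_offset`` (kcal/mol per residue) is the engine's calibration
    constant: residues with apparent ΔG below it favour membrane placement.
    ``tm_cost`` (kcal/mol per helix) is a fixed helix-insertion cost that
    keeps marginally hydrophobic segments out of the membrane unless the
    grammar or constraints demand them. ``rk_bonus`` is the positive-inside
    reward per Arg/Lys in a cytosolic loop.
    """

    min_tm: int = 17
    max_tm: int = 25
    loop_min: int = 2
    insertion_offset: float = 0.35
    rk_bonus: float = 0.5
    tm_cost: float = 1.0
    on_unknown: str = "error"

    def __post_init__(self):
        if not (1 <= self.min_tm <= self.max_tm):
            raise ValueError("need 1 <= min_tm <= max_tm")
        if self.loop_min < 1:
            raise ValueError("loop_min must be >= 1")


DEFAULT_PARAMS = PredictorParams()


@dataclass(frozen=True)
class TopologyModel:
    """Alternating segmentation of a full sequence plus its score."""

    segments: tuple[Segment, ...]
    score: float
    length: int
    reliability: np.ndarray | None = None  # per-residue percent, optional

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.segments if s.state == "membrane")

    @property
    def tm_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.state == "membrane")

    @property
    def topology_string(self) -> str:
        out = []
        for seg in self.segments:
            out.append(_STATE_CHAR[seg.state] * (seg.end - seg.start + 1))
        return "".join(out)

    def state_at(self, residue: int) -> State:
        for seg in self.segments:
            if seg.start <= residue <= seg.end:
                return seg.state
        raise IndexError(f"residue {residue} outside model (1..{self.length})")

    @property
    def n_term_state(self) -> State:
        return self.segments[0].state

    @property
    def c_term_state(self) -> State:
        return self.segments[-1].state


def _allowed_masks(length: int, constraints: Iterable[TopologyConstraint]):
    """Boolean per-residue state availability; None when contradictory."""
    allow = {s: np.ones(length, dtype=bool) for s in ("inside", "membrane", "outside")}
    for c in constraints:
        if c.end > length:
            raise ValueError(f"constraint {c} beyond sequence length {length}")
        sl = slice(c.start - 1, c.end)
        for s in ("inside", "membrane", "outside"):
            if s != c.state:
                allow[s][sl] = False
    if not (allow["inside"] | allow["membrane"] | allow["outside"]).all():
        return None
    return allow


def _better(score_a, ntm_a, score_b, ntm_b) -> bool:
    """Maximize score; among (near-)ties prefer fewer TM segments."""
    if score_a > score_b + _EPS:
        return True
    if score_a < score_b - _EPS:
        return False
    return ntm_a < ntm_b


_NEG = -np.inf


def _run_dp(length: int, allow, loop_gain, mem_gain, params: PredictorParams):
    """Core DP. Returns (score, segments) of the optimum or None.

    ``loop_gain[side][i]`` is the reward for residue i in a loop of that side,
    ``mem_gain[i]`` the reward for residue i inside a TM helix.
    """
    sides = ("inside", "outside")
    flip = {"inside": "outside", "outside": "inside"}
    # prefix of consecutive residues allowed in each state, ending at i
    run = {}
    for s in ("inside", "outside", "membrane"):
        r = np.zeros(length, dtype=int)
        acc = 0
        for i in range(length):
            acc = acc + 1 if allow[s][i] else 0
            r[i] = acc
        run[s] = r
    cum_loop = {s: np.concatenate([[0.0], np.cumsum(loop_gain[s])]) for s in sides}
    cum_mem = np.concatenate([[0.0], np.cumsum(mem_gain)])

    Lm = {s: np.full(length, _NEG) for s in sides}        # best score, residue i in loop s
    Lm_ntm = {s: np.zeros(length, dtype=int) for s in sides}
    Lm_ptr: dict[str, list] = {s: [None] * length for s in sides}
    Te = {s: np.full(length, _NEG) for s in sides}        # best score, TM ends at i, next loop side s
    Te_ntm = {s: np.zeros(length, dtype=int) for s in sides}
    Te_ptr: dict[str, list] = {s: [None] * length for s in sides}

    lm, mt, lmin = params.min_tm, params.max_tm, params.loop_min
    tm_cost = params.tm_cost
    for i in range(length):
        for s in sides:
            # TM ending at i, oriented flip(s) -> s
            if run["membrane"][i] >= lm:
                tmax = min(mt, run["membrane"][i], i)  # need >=1 residue before the TM
                for t in range(lm, tmax + 1):
                    j = i - t  # previous loop's last residue
                    prev = Lm[flip[s]]
                    if prev[j] == _NEG:
                        continue
                    sc = prev[j] + (cum_mem[i + 1] - cum_mem[i - t + 1]) - tm_cost
                    nt = Lm_ntm[flip[s]][j] + 1
                    if _better(sc, nt, Te[s][i], Te_ntm[s][i]):
                        Te[s][i], Te_ntm[s][i], Te_ptr[s][i] = sc, nt, (t, j)
            # loop of side s with residue i as last residue so far
            if allow[s][i]:
                # extend an existing loop
                if i > 0 and Lm[s][i - 1] > _NEG:
                    sc = Lm[s][i - 1] + loop_gain[s][i]
                    nt = Lm_ntm[s][i - 1]
                    if _better(sc, nt, Lm[s][i], Lm_ntm[s][i]):
                        Lm[s][i], Lm_ntm[s][i], Lm_ptr[s][i] = sc, nt, ("ext",)
                # first loop covering 0..i
                if run[s][i] >= i + 1:
                    sc = cum_loop[s][i + 1]
                    if _better(sc, 0, Lm[s][i], Lm_ntm[s][i]):
                        Lm[s][i], Lm_ntm[s][i], Lm_ptr[s][i] = sc, 0, ("first",)
                # fresh interior loop of exactly loop_min residues after a TM
                j = i - lmin  # TM ends at j
                if j >= 0 and run[s][i] >= lmin and Te[s][j] > _NEG:
                    sc = Te[s][j] + (cum_loop[s][i + 1] - cum_loop[s][j + 1])
                    nt = Te_ntm[s][j]
                    if _better(sc, nt, Lm[s][i], Lm_ntm[s][i]):
                        Lm[s][i], Lm_ntm[s][i], Lm_ptr[s][i] = sc, nt, ("newloop", j)

    end_side, end_score, end_ntm = None, _NEG, 0
    for s in sides:
        if Lm[s][length - 1] > _NEG and (
            end_side is None or _better(Lm[s][length - 1], Lm_ntm[s][length - 1], end_score, end_ntm)
        ):
            end_side, end_score, end_ntm = s, Lm[s][length - 1], Lm_ntm[s][length - 1]
    if end_side is None:
        return None

    # backtrack
    segments: list[Segment] = []
    i, s = length - 1, end_side
    loop_end = i
    while True:
        ptr = Lm_ptr[s][i]
        if ptr[0] == "ext":
            i -= 1
        elif ptr[0] == "first":
            segments.append(Segment(1, loop_end + 1, s))
            break
        else:  # newloop: loop spans j+1..loop_end, TM ends at j
            j = ptr[1]
            segments.append(Segment(j + 2, loop_end + 1, s))
            t, k = Te_ptr[s][j]
            segments.append(Segment(j - t + 2, j + 1, "membrane"))
            s = flip[s]
            i = k
            loop_end = k
    segments.reverse()
    return end_score, tuple(segments)


def predict_topology(sequence: str,
                     constraints: Sequence[TopologyConstraint] = (),
                     params: PredictorParams | None = None,
                     scale: dict[str, float] | None = None) -> TopologyModel | None:
    """Maximum-score topology of ``sequence`` under hard constraints.

    Returns ``None`` when the constraint set is infeasible under the grammar
    (including directly contradictory point constraints).
    """
    params = params or DEFAULT_PARAMS
    length = len(sequence)
    if length == 0:
        raise ValueError("empty sequence")
    allow = _allowed_masks(length, constraints)
    if allow is None:
        return None
    dg = residue_deltaG(sequence, scale, on_unknown=params.on_unknown)
    mem_gain = params.insertion_offset - dg
    is_rk = np.array([aa in "RK" for aa in sequence.upper()], dtype=float)
    loop_gain = {"inside": params.rk_bonus * is_rk, "outside": np.zeros(length)}
    result = _run_dp(length, allow, loop_gain, mem_gain, params)
    if result is None:
        return None
    score, segments = result
    return TopologyModel(segments=segments, score=float(score), length=length)


def min_tm_count(constraints: Sequence[TopologyConstraint], length: int,
                 params: PredictorParams | None = None) -> int | None:
    """Smallest TM count of any grammar-valid topology satisfying the constraints.

    Counts one helix per inside/outside alternation, absorbing membrane
    constraints into adjacent crossings where the helix-length geometry
    allows. Raises on contradictory point constraints; returns ``None`` when
    the constraints are side-consistent but geometrically unsatisfiable.
    """
    params = params or DEFAULT_PARAMS
    allow = _allowed_masks(length, constraints)
    if allow is None:
        raise ValueError("contradictory constraints")
    zeros = np.zeros(length)
    # reward-free DP; each TM costs 1 via the tie-break channel
    result = _run_dp(length, allow, {"inside": zeros, "outside": zeros}, zeros, params)
    if result is None:
        return None
    _, segments = result
    return sum(1 for s in segments if s.state == "membrane")


def check_model(model: TopologyModel, constraints: Sequence[TopologyConstraint],
                params: PredictorParams | None = None) -> list[tuple[TopologyConstraint, int]]:
    """Constraint violations of ``model``; empty list iff all satisfied.

    Structural defects of the model itself (gaps, non-alternating loops,
    out-of-bound TM lengths) raise ``ValueError``.
    """
    params = params or DEFAULT_PARAMS
    segs = model.segments
    if not segs or segs[0].start != 1 or segs[-1].end != model.length:
        raise ValueError("model does not cover the sequence")
    prev_loop_side: State | None = None
    for k, seg in enumerate(segs):
        if k and seg.start != segs[k - 1].end + 1:
            raise ValueError(f"segments not contiguous at {seg}")
        if seg.state == "membrane":
            n = seg.end - seg.start + 1
            if not (params.min_tm <= n <= params.max_tm):
                raise ValueError(f"TM segment {seg} outside length bounds")
        else:
            if k and segs[k - 1].state != "membrane":
                raise ValueError("two adjacent loop segments")
            if prev_loop_side is not None and seg.state == prev_loop_side:
                raise ValueError("loop sides do not alternate")
            prev_loop_side = seg.state
    violations = []
    for c in constraints:
        if c.end > model.length:
            raise ValueError(f"constraint {c} beyond model length")
        for residue in range(c.start, c.end + 1):
            if model.state_at(residue) != c.state:
                violations.append((c, residue))
    return violations


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-residue agreement of an ensemble of predictor variants."""

    per_residue: np.ndarray      # percent, length L
    mean: float                  # whole-sequence average percent
    consensus: TopologyModel     # model predicted with the first (reference) member
    n_members: int               # feasible members used
    excluded: tuple[int, ...]    # indices of infeasible members


def default_ensemble(base: PredictorParams | None = None) -> tuple[PredictorParams, ...]:
    """Six engine variants: insertion offset ±0.1 × two positive-inside biases.

    Variation across members stands in for the independently trained
    algorithms of a consensus predictor; their disagreement is what the
    reliability score measures.
    """
    base = base or DEFAULT_PARAMS
    members = []
    for d_off in (0.0, -0.1, 0.1):
        for bonus in (base.rk_bonus, base.rk_bonus + 0.2):
            members.append(replace(base, insertion_offset=base.insertion_offset + d_off,
                                   rk_bonus=bonus))
    return tuple(members)


def reliability_score(sequence: str,
                      constraints: Sequence[TopologyConstraint] = (),
                      ensemble: Sequence[PredictorParams] | None = None,
                      scale: dict[str, float] | None = None) -> ReliabilityResult | None:
    """Ensemble-agreement reliability of the constrained prediction.

    For every residue, the score is the percentage of feasible ensemble
    members whose state label (i/M/o) matches the consensus (majority)
    label. Infeasible members are excluded; if all members are infeasible
    the model is infeasible and ``None`` is returned.
    """
    ensemble = tuple(ensemble) if ensemble is not None else default_ensemble()
    if len(ensemble) < 3:
        raise ValueError("reliability needs an ensemble of at least 3 predictor variants")
    models, excluded = [], []
    for k, member in enumerate(ensemble):
        m = predict_topology(sequence, constraints, member, scale)
        if m is None:
            excluded.append(k)
        else:
            models.append((k, m))
    if not models:
        return None
    length = len(sequence)
    labels = np.array([[m.topology_string[i] for i in range(length)] for _, m in models])
    per_residue = np.empty(length)
    for i in range(length):
        col = labels[:, i]
        states, counts = np.unique(col, return_counts=True)
        best = states[np.argmax(counts)]  # np.unique sorts: ties broken alphabetically (M<i<o)
        per_residue[i] = 100.0 * counts.max() / len(col)
    return ReliabilityResult(per_residue=per_residue, mean=float(per_residue.mean()),
                             consensus=models[0][1], n_members=len(models),
                             excluded=tuple(excluded))
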