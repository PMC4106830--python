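import pytest

from cln3topo.io import load_cln3_sequence
from cln3topo.topology import Segment, TopologyConstraint, TopologyModel


@pytest.fixture(scope="session")
def cln3_sequence() -> str:
    return load_cln3_sequence()


@pytest.fixture(scope="session")
def full_constraint_set(cln3_sequence):
    """The complete accumulated constraint set of the CLN3 study."""
    L = len(cln3_sequence)
    C = TopologyConstraint
    return [
        C.at(37, "inside"), C.at(204, "inside"), C.at(239, "inside"),
        C(250, 258, "inside"), C.at(401, "inside"), C.at(407, "inside"),
        C.at(L, "inside"),
        C.at(71, "outside"), C.at(85, "outside"), C.at(86, "outside"),
        C.at(102, "outside"), C.at(126, "outside"), C.at(346, "outside"),
        C.at(280, "membrane"), C.at(349, "membrane"),
    ]


@pytest.fixture(scope="session")
def published_model(cln3_sequence):
    """Published six-TMD CLN3 model (termini cytosolic) as a TopologyModel."""
    tms = [(38, 58), (128, 148), (152, 172), (183, 203), (278, 298), (347, 367)]
    L = len(cln3_sequence)
    segs, pos, side = [], 1, "inside"
    for a, b in tms:
        segs.append(Segment(pos, a - 1, side))
        segs.append(Segment(a, b, "membrane"))
        side = "outside" if side == "inside" else "inside"
        pos = b + 1
    segs.append(Segment(pos, L, side))
    return TopologyModel(segments=tuple(segs), score=0.0, length=L)
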