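"""Hydrophobicity (ΔG insertion) scale and sliding-window profiles.

The bundled scale contains the apparent free energy of membrane insertion
per residue, in kcal/mol, from the translocon-based biological hydrophobicity
scale: negative values favour insertion into the bilayer, large positive
values (charged and strongly polar residues) oppose it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


def load_scale() -> dict[str, float]:
    """Load the bundled per-residue ΔG insertion scale (kcal/mol)."""
    with resources.files("cln3topo.data").joinpath("hydrophobicity_scale.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return dict(zip(table["residue"], table["delta_g"].astype(float)))


_DEFAULT_SCALE: dict[str, float] | None = None


def default_scale() -> dict[str, float]:
    global _DEFAULT_SCALE
    if _DEFAULT_SCALE is None:
        _DEFAULT_SCALE = load_scale()
    return _DEFAULT_SCALE


def residue_deltaG(sequence: str, scale: dict[str, float] | None = None,
                   on_unknown: str = "error") -> np.ndarray:
    """Per-residue ΔG values for ``sequence``.

    Parameters
    ----------
    on_unknown:
        ``"error"`` raises on non-canonical residues; ``"skip"`` assigns them
        the scale's mean value so they are topologically neutral.
    """
    scale = scale or default_scale()
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"unknown policy {on_unknown!r}")
    fill = float(np.mean(list(scale.values())))
    out = np.empty(len(sequence))
    for i, aa in enumerate(sequence.upper()):
        if aa in scale:
            out[i] = scale[aa]
        elif on_unknown == "skip":
            out[i] = fill
        else:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}")
    return out


@dataclass(frozen=True)
class HydropathyProfile:
    """Window-summed ΔG profile.

    ``values[k]`` is the ΔG sum (kcal/mol) of the full window centred on
    1-based position ``positions[k]``; only positions where the whole window
    fits are defined.
    """

    positions: np.ndarray  # 1-based window centres
    values: np.ndarray     # kcal/mol per window
    window: int


def window_deltaG(sequence: str, scale: dict[str, float] | None = None,
                  window: int = 21, on_unknown: str = "error") -> HydropathyProfile:
    """Sliding-window ΔG insertion profile of ``sequence``.

    Lower values mean the window is a better candidate transmembrane helix.
    """
    if window % 2 != 1:
        raise ValueError("window length must be odd")
    if window > len(sequence):
        raise ValueError(f"window {window} longer than sequence ({len(sequence)} aa)")
    per_res = residue_deltaG(sequence, scale, on_unknown=on_unknown)
    kernel = np.ones(window)
    values = np.convolve(per_res, kernel, mode="valid")
    half = window // 2
    positions = np.arange(half + 1, len(sequence) - half + 1)
    return HydropathyProfile(positions=positions, values=values, window=window)
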