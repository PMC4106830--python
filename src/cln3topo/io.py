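"""File formats: FASTA sequences, TSV tables, TIFF images, decay grids.

Every tabular format has a header row and stable, documented columns:

* constraints TSV: ``start  end  state  provenance``
* segments TSV: ``start  end  state``
* reliability TSV: ``residue  state  reliability``
* FRET TSV: ``clone  tau_ref  tau_da  efficiency  sem  significance``
* vesicle TSV: ``cell_id  transfected  n_vesicles``
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .flim import FlimGrid, FretMeasurement
from .synthetic import ImageField
from .topology import Segment, TopologyConstraint, TopologyModel


class SequenceRecord(NamedTuple):
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records as (id, uppercase residue string) pairs."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (no '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def load_cln3_sequence() -> str:
    """Bundled 438-aa human CLN3 sequence (synthetic reconstruction)."""
    with resources.as_file(resources.files("cln3topo.data")
                           .joinpath("cln3_human_synthetic.fasta")) as p:
        return read_fasta(p)[0].sequence


# ----------------------------------------------------------------- constraints

def write_constraints_tsv(constraints: Sequence[TopologyConstraint],
                          path: str | Path) -> None:
    pd.DataFrame([{"start": c.start, "end": c.end, "state": c.state,
                   "provenance": c.provenance} for c in constraints]) \
        .to_csv(path, sep="\t", index=False)


def read_constraints_tsv(path: str | Path) -> list[TopologyConstraint]:
    table = pd.read_csv(path, sep="\t")
    required = {"start", "end", "state"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: constraint TSV needs columns {sorted(required)}")
    out = []
    for row in table.itertuples():
        prov = getattr(row, "provenance", "assumption")
        out.append(TopologyConstraint(int(row.start), int(row.end), str(row.state),
                                      str(prov)))
    return out


# -------------------------------------------------------------------- topology

def write_segments_tsv(model: TopologyModel, path: str | Path) -> None:
    pd.DataFrame([{"start": s.start, "end": s.end, "state": s.state}
                  for s in model.segments]).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path, length: int | None = None,
                      score: float = float("nan")) -> TopologyModel:
    table = pd.read_csv(path, sep="\t")
    segs = tuple(Segment(int(r.start), int(r.end), str(r.state))
                 for r in table.itertuples())
    return TopologyModel(segments=segs, score=score,
                         length=length or segs[-1].end)


def write_reliability_tsv(per_residue: np.ndarray, topology_string: str,
                          path: str | Path) -> None:
    pd.DataFrame({"residue": np.arange(1, len(per_residue) + 1),
                  "state": list(topology_string),
                  "reliability": np.round(per_residue, 3)}) \
        .to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------------ FRET

def write_fret_tsv(measurements: Sequence[FretMeasurement], path: str | Path) -> None:
    pd.DataFrame([{"clone": m.clone_id, "tau_ref": m.tau_reference,
                   "tau_da": m.tau_donor_acceptor, "efficiency": m.efficiency,
                   "sem": m.sem, "significance": m.significance}
                  for m in measurements]).to_csv(path, sep="\t", index=False)


def read_fret_tsv(path: str | Path) -> list[FretMeasurement]:
    table = pd.read_csv(path, sep="\t")
    return [FretMeasurement(clone_id=str(r.clone), tau_reference=float(r.tau_ref),
                            tau_donor_acceptor=float(r.tau_da),
                            efficiency=float(r.efficiency), sem=float(r.sem),
                            significance=str(r.significance))
            for r in table.itertuples()]


# ---------------------------------------------------------------------- images

def save_flim_grid(grid: FlimGrid, path: str | Path) -> None:
    """Decay-grid container: compressed arrays + bin edges (ns)."""
    np.savez_compressed(path, bin_edges=grid.bin_edges, counts=grid.counts)


def load_flim_grid(path: str | Path) -> FlimGrid:
    with np.load(path) as data:
        return FlimGrid(data["bin_edges"], data["counts"])


def write_field_tiff(field: ImageField, path: str | Path) -> None:
    """Multi-page TIFF, one page per channel; pixel size stored as metadata."""
    tifffile.imwrite(path, field.channels.astype(np.float32),
                     metadata={"pixel_size_um": field.pixel_size,
                               "channels": list(field.channel_names)})


def read_field_tiff(path: str | Path, pixel_size: float | None = None) -> ImageField:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    px = pixel_size or float(meta.get("pixel_size_um", 1.0))
    names = tuple(meta.get("channels", [f"channel_{i}" for i in range(len(data))]))
    return ImageField(channels=data, pixel_size=px, channel_names=names)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
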