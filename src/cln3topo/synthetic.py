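"""Seeded generators for every input of the pipeline.

All generators are pure functions of (parameters, seed): TCSPC decay
histograms with Poisson counting statistics, per-pixel FLIM grids,
two-channel cell fields with diffraction-blurred lysosome-like vesicles,
channel pairs with a controlled colocalized fraction, and artificial
protein sequences with planted transmembrane segments of known position.
Conservation is exact (histograms sum to the requested photon number,
object counts match the drawn Poisson counts); statistical contracts such
as per-group vesicle means hold to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .flim import DecayHistogram, FlimGrid
from .topology import Segment

# --------------------------------------------------------------------------
# decays

@dataclass(frozen=True)
class DecayParams:
    """Ground truth of a (multi)exponential decay within an acquisition window.

    ``components`` are (fraction, lifetime ns) pairs; fractions sum to 1 and
    are shares of the *non-background* photons. ``background_fraction`` of
    all photons arrive uniformly over the window (dark counts).
    """

    components: tuple[tuple[float, float], ...] = ((1.0, 2.28),)
    background_fraction: float = 0.0
    time_window: float = 12.5   # ns
    n_bins: int = 256

    def __post_init__(self):
        comps = tuple((float(f), float(tau)) for f, tau in self.components)
        object.__setattr__(self, "components", comps)
        fracs = np.array([f for f, _ in comps])
        taus = np.array([tau for _, tau in comps])
        if len(comps) == 0 or not np.isclose(fracs.sum(), 1.0, atol=1e-9):
            raise ValueError("component fractions must sum to 1")
        if np.any(fracs <= 0) or np.any(fracs > 1):
            raise ValueError("component fractions must lie in (0, 1]")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.n_bins < 8:
            raise ValueError("need at least 8 bins")
        if self.time_window <= 0:
            raise ValueError("time window must be positive")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.time_window, self.n_bins + 1)


def _sample_truncated_exp(rng: np.random.Generator, tau: float, window: float,
                          n: int) -> np.ndarray:
    """Inverse-CDF sampling of an exponential truncated to [0, window]."""
    u = rng.random(n)
    return -tau * np.log1p(-u * (1.0 - np.exp(-window / tau)))


def generate_decay_histogram(params: DecayParams, n_photons: int,
                             seed: int) -> DecayHistogram:
    """Simulate one TCSPC histogram; counts sum to ``n_photons`` exactly."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    probs = [params.background_fraction] + [
        f * (1.0 - params.background_fraction) for f, _ in params.components]
    counts_per_source = rng.multinomial(n_photons, probs)
    times = [rng.random(counts_per_source[0]) * params.time_window]
    for (f, tau), k in zip(params.components, counts_per_source[1:]):
        times.append(_sample_truncated_exp(rng, tau, params.time_window, k))
    t = np.concatenate(times)
    counts, _ = np.histogram(t, bins=params.bin_edges)
    return DecayHistogram(params.bin_edges, counts)


def generate_flim_image(grid_shape: tuple[int, int],
                        per_pixel_params: DecayParams | Mapping[tuple[int, int], DecayParams],
                        counts_per_pixel: int | np.ndarray,
                        seed: int) -> FlimGrid:
    """Simulate a grid of independent per-pixel decay histograms.

    ``per_pixel_params`` may be a single DecayParams applied everywhere or a
    mapping pixel → DecayParams; pixels absent from the mapping get zero
    counts. ``counts_per_pixel`` may be scalar or an (H, W) array.
    """
    h, w = grid_shape
    if h < 1 or w < 1:
        raise ValueError("grid must be non-empty")
    if isinstance(per_pixel_params, DecayParams):
        pixel_map = {(y, x): per_pixel_params for y in range(h) for x in range(w)}
    else:
        pixel_map = dict(per_pixel_params)
    counts_arr = np.broadcast_to(np.asarray(counts_per_pixel), (h, w))
    if np.any(counts_arr < 0):
        raise ValueError("negative photon counts")
    some_params = next(iter(pixel_map.values()))
    edges = some_params.bin_edges
    grid = np.zeros((h, w, some_params.n_bins), dtype=np.int64)
    ss = np.random.SeedSequence(seed)
    child = {pix: s for pix, s in zip(sorted(pixel_map), ss.spawn(len(pixel_map)))}
    for pix, p in sorted(pixel_map.items()):
        y, x = pix
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"pixel {pix} outside grid {grid_shape}")
        if not np.allclose(p.bin_edges, edges):
            raise ValueError("all pixels must share the same time base")
        n = int(counts_arr[y, x])
        if n > 0:
            sub = np.random.default_rng(child[pix])
            hgram = generate_decay_histogram(p, n, seed=int(sub.integers(2**31)))
            grid[y, x] = hgram.counts
    return FlimGrid(edges, grid)


# --------------------------------------------------------------------------
# cell fields / rescue assay

@dataclass(frozen=True)
class FieldScenario:
    """Ground truth of a simulated rescue-assay field.

    Per-cell small-vesicle counts are i.i.d. Poisson with mean
    ``base_vesicle_mean`` (non-transfected) or ``base_vesicle_mean ×
    fold_change`` (transfected). Distances are in µm.
    """

    n_cells: int
    transfected_fraction: float = 0.3
    base_vesicle_mean: float = 14.0
    fold_change: float = 1.4
    vesicle_diameter_range: tuple[float, float] = (1.0, 3.0)
    pixel_size: float = 0.1
    psf_sigma: float = 0.15
    noise_sd: float = 2.0
    seed: int = 0
    cell_radius: float = 12.5
    vesicle_amplitude: float = 1000.0
    marker_amplitude: float = 400.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.fold_change < 0:
            raise ValueError("fold_change must be >= 0")
        if not 0 <= self.transfected_fraction <= 1:
            raise ValueError("transfected_fraction in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        dmin, dmax = self.vesicle_diameter_range
        if not 0 < dmin <= dmax:
            raise ValueError("bad diameter range")
        if dmin < 2 * self.pixel_size:
            raise ValueError("smallest vesicle not resolvable at this pixel size")

    @property
    def tile_px(self) -> int:
        return int(np.ceil(2.0 * (self.cell_radius + 1.0) / self.pixel_size))


@dataclass
class ImageField:
    """Multi-channel image + pixel size + ground-truth tables."""

    channels: np.ndarray                  # (C, H, W) float32
    pixel_size: float                     # µm
    channel_names: tuple[str, ...]
    truth: pd.DataFrame | None = None     # per-cell table
    objects: pd.DataFrame | None = None   # per-vesicle table


def _cell_truth(scenario: FieldScenario, cell_id: int):
    """Deterministic per-cell ground truth (independent of chunking)."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, cell_id]))
    transfected = bool(rng.random() < scenario.transfected_fraction)
    mean = scenario.base_vesicle_mean * (scenario.fold_change if transfected else 1.0)
    n_ves = int(rng.poisson(mean)) if mean > 0 else 0
    dmin, dmax = scenario.vesicle_diameter_range
    centers, diameters = [], []
    min_gap = 0.3  # µm between vesicle boundaries
    for _ in range(n_ves):
        d = float(rng.uniform(dmin, dmax))
        placed = False
        for _try in range(300):
            r_max = max(scenario.cell_radius - d / 2 - 0.3, 0.1)
            rr = np.sqrt(rng.random()) * r_max
            th = rng.random() * 2 * np.pi
            x, y = rr * np.cos(th), rr * np.sin(th)
            ok = all(np.hypot(x - cx, y - cy) >= (d + dd) / 2 + min_gap
                     for (cx, cy), dd in zip(centers, diameters))
            if ok:
                placed = True
                break
        centers.append((x, y))
        diameters.append(d)
        if not placed:
            pass  # crowded cell: accept the last candidate position
    return transfected, centers, diameters, rng


_RGRID_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _radial_grid(n: int, px: float) -> np.ndarray:
    key = (n, px)
    if key not in _RGRID_CACHE:
        c0 = n / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        _RGRID_CACHE[key] = np.hypot((xx + 0.5 - c0) * px, (yy + 0.5 - c0) * px)
    return _RGRID_CACHE[key]


def _render_cell_tile(scenario: FieldScenario, transfected, centers, diameters,
                      rng: np.random.Generator, render_marker: bool = True):
    """Render (marker, vesicle) tile for one cell; marker may be skipped."""
    n = scenario.tile_px
    px = scenario.pixel_size
    c0 = n / 2.0  # tile centre in px
    marker = None
    if render_marker:
        marker = np.zeros((n, n), dtype=np.float32)
        level = scenario.marker_amplitude if transfected else 0.05 * scenario.marker_amplitude
        marker[_radial_grid(n, px) <= scenario.cell_radius] = level
    ves = np.zeros((n, n), dtype=np.float32)
    for (x, y), d in zip(centers, diameters):
        r_px = d / 2 / px
        cx, cy = c0 + x / px, c0 + y / px
        lo_x, hi_x = int(cx - r_px - 3), int(cx + r_px + 4)
        lo_y, hi_y = int(cy - r_px - 3), int(cy + r_px + 4)
        sub_y, sub_x = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        dist = np.hypot(sub_x + 0.5 - cx, sub_y + 0.5 - cy)
        disc = np.clip(r_px - dist + 0.5, 0.0, 1.0) * scenario.vesicle_amplitude
        ves[lo_y:hi_y, lo_x:hi_x] += disc.astype(np.float32)
    sigma_px = scenario.psf_sigma / px
    ves = gaussian_filter(ves, sigma_px)
    if render_marker:
        marker = gaussian_filter(marker, sigma_px)
        if scenario.noise_sd > 0:
            marker += rng.normal(0, scenario.noise_sd, marker.shape).astype(np.float32)
    if scenario.noise_sd > 0:
        ves += rng.normal(0, scenario.noise_sd, ves.shape).astype(np.float32)
    return marker, ves


def iter_cell_tiles(scenario: FieldScenario,
                    render_marker: bool = True) -> Iterator[tuple[dict, np.ndarray, np.ndarray]]:
    """Stream (cell record, marker tile, vesicle tile) without assembling a field.

    The per-cell ground truth is identical to :func:`generate_cell_field`
    with the same scenario (marker rendering is optional and does not
    perturb it).
    """
    for cell_id in range(scenario.n_cells):
        transfected, centers, diameters, rng = _cell_truth(scenario, cell_id)
        marker, ves = _render_cell_tile(scenario, transfected, centers, diameters, rng,
                                        render_marker=render_marker)
        record = {"cell_id": cell_id, "transfected": transfected,
                  "n_vesicles": len(centers), "centers": centers,
                  "diameters": diameters}
        yield record, marker, ves


def cell_truth_table(scenario: FieldScenario) -> pd.DataFrame:
    """Ground-truth per-cell table (no rendering)."""
    rows = []
    for cell_id in range(scenario.n_cells):
        transfected, centers, diameters, _ = _cell_truth(scenario, cell_id)
        rows.append({"cell_id": cell_id, "transfected": transfected,
                     "n_vesicles": len(centers),
                     "centers": ";".join(f"{x:.3f},{y:.3f}" for x, y in centers),
                     "diameters": ";".join(f"{d:.3f}" for d in diameters)})
    return pd.DataFrame(rows)


def generate_cell_field(scenario: FieldScenario) -> ImageField:
    """Assemble a mosaic field of cell tiles (marker + vesicle channels).

    Intended for modest ``n_cells``; large populations are better consumed
    through :func:`iter_cell_tiles`.
    """
    n = scenario.tile_px
    ncol = int(np.ceil(np.sqrt(scenario.n_cells)))
    nrow = int(np.ceil(scenario.n_cells / ncol))
    marker = np.zeros((nrow * n, ncol * n), dtype=np.float32)
    ves = np.zeros_like(marker)
    truth_rows, object_rows = [], []
    for record, m_tile, v_tile in iter_cell_tiles(scenario):
        k = record["cell_id"]
        r, c = divmod(k, ncol)
        marker[r * n:(r + 1) * n, c * n:(c + 1) * n] = m_tile
        ves[r * n:(r + 1) * n, c * n:(c + 1) * n] = v_tile
        off_x = (c * n + n / 2.0) * scenario.pixel_size
        off_y = (r * n + n / 2.0) * scenario.pixel_size
        for (x, y), d in zip(record["centers"], record["diameters"]):
            object_rows.append({"cell_id": k, "x_um": off_x + x, "y_um": off_y + y,
                                "diameter_um": d})
        truth_rows.append({"cell_id": k, "transfected": record["transfected"],
                           "n_vesicles": record["n_vesicles"]})
    return ImageField(
        channels=np.stack([marker, ves]), pixel_size=scenario.pixel_size,
        channel_names=("transfection_marker", "vesicles"),
        truth=pd.DataFrame(truth_rows),
        objects=pd.DataFrame(object_rows, columns=["cell_id", "x_um", "y_um", "diameter_um"]))


# --------------------------------------------------------------------------
# colocalization pairs

def generate_coloc_pair(true_overlap_fraction: float, n_objects: int, seed: int,
                        shape: tuple[int, int] = (256, 256), spot_sigma: float = 1.5,
                        amplitude: float = 200.0, noise_sd: float = 1.0) -> ImageField:
    """Two-channel field where a known fraction of channel-A spots recur in B.

    ``round(f · n_objects)`` of the channel-A spots are duplicated at the
    same coordinates in channel B; the remaining B spots are placed at
    disjoint positions.
    """
    if not 0 <= true_overlap_fraction <= 1:
        raise ValueError("overlap fraction must lie in [0, 1]")
    if n_objects < 1:
        raise ValueError("need at least one object")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = int(6 * spot_sigma) + 2
    # lay objects on a jittered grid so spots never merge
    pitch = max(int(4 * spot_sigma) + 3, 8)
    xs = np.arange(margin, w - margin, pitch)
    ys = np.arange(margin, h - margin, pitch)
    sites = [(y, x) for y in ys for x in xs]
    n_shared = int(round(true_overlap_fraction * n_objects))
    need = 2 * n_objects - n_shared
    if need > len(sites):
        raise ValueError("image too small for that many disjoint objects")
    chosen = rng.choice(len(sites), size=need, replace=False)
    coords = [sites[i] for i in chosen]
    a_sites = coords[:n_objects]
    b_sites = a_sites[:n_shared] + coords[n_objects:]
    yy, xx = np.mgrid[-margin:margin + 1, -margin:margin + 1]
    spot = amplitude * np.exp(-(xx**2 + yy**2) / (2 * spot_sigma**2))

    def paint(sites_):
        img = np.zeros(shape, dtype=np.float32)
        for (y, x) in sites_:
            img[y - margin:y + margin + 1, x - margin:x + margin + 1] += spot
        return img

    a, bimg = paint(a_sites), paint(b_sites)
    if noise_sd > 0:
        a += rng.normal(0, noise_sd, shape).astype(np.float32)
        bimg += rng.normal(0, noise_sd, shape).astype(np.float32)
    return ImageField(channels=np.stack([a, bimg]), pixel_size=1.0,
                      channel_names=("channel_a", "channel_b"))


# --------------------------------------------------------------------------
# planted-TM sequences

@dataclass(frozen=True)
class PlantedSequence:
    """Artificial sequence with known TM segments (1-based inclusive)."""

    sequence: str
    true_segments: tuple[Segment, ...]

    @property
    def tm_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.true_segments if s.state == "membrane")


_TM_RESIDUES = list("LLLIIVVFAM")           # strongly hydrophobic pool
_LOOP_RESIDUES = list("DDEEKKRRNQSTGP")     # polar/charged pool


def generate_planted_sequence(n_tms: int, loop_lengths: int | Sequence[int] = 12,
                              seed: int = 0, tm_length: tuple[int, int] = (19, 23),
                              first_side: str = "inside") -> PlantedSequence:
    """Sequence of alternating polar loops and strongly hydrophobic TM runs.

    Planted TM windows have strongly negative ΔG on the bundled scale; loop
    windows are strongly positive, so an unconstrained prediction recovers
    the planted count for generous margins.
    """
    if n_tms < 0:
        raise ValueError("n_tms must be >= 0")
    n_loops = n_tms + 1
    if isinstance(loop_lengths, int):
        loops = [loop_lengths] * n_loops
    else:
        loops = list(loop_lengths)
        if len(loops) != n_loops:
            raise ValueError(f"need {n_loops} loop lengths for {n_tms} TMs")
    if any(l < 3 for l in loops):
        raise ValueError("loops must have at least 3 residues to separate TMs")
    rng = np.random.default_rng(seed)
    side = "inside" if first_side in ("inside", "in", "cytosolic") else "outside"
    other = {"inside": "outside", "outside": "inside"}
    seq_parts: list[str] = []
    segments: list[Segment] = []
    pos = 1
    for k in range(n_loops):
        ll = loops[k]
        seq_parts.append("".join(rng.choice(_LOOP_RESIDUES, ll)))
        segments.append(Segment(pos, pos + ll - 1, side))
        pos += ll
        if k < n_tms:
            tl = int(rng.integers(tm_length[0], tm_length[1] + 1))
            seq_parts.append("".join(rng.choice(_TM_RESIDUES, tl)))
            segments.append(Segment(pos, pos + tl - 1, "membrane"))
            pos += tl
            side = other[side]
    return PlantedSequence(sequence="".join(seq_parts), true_segments=tuple(segments))
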