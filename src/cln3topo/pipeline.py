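"""End-to-end orchestration: simulate → fit → FRET → constraints → topology.

A run reproduces the study's logic on synthetic data: a donor-only FLIM
grid yields the two donor lifetime-population peaks; each chimeric clone's
donor+acceptor decay is simulated at its configured true FRET efficiency,
fitted, converted to an efficiency against the reference lifetime and
gated; significant clones contribute sidedness constraints which join the
prior experimental constraints; the greedy accumulation then fixes the
remaining insertion sites and the constrained predictor emits the final
topology model. All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import constraints as cb
from . import flim, io, synthetic
from .topology import DEFAULT_PARAMS, PredictorParams

log = logging.getLogger("cln3topo.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run (defaults follow the study setup)."""

    seed: int = 0
    out_dir: str = "cln3topo_run"
    # FLIM simulation / fitting
    donor_lifetimes: tuple[float, float] = (2.28, 2.14)  # ns, donor-only populations
    flim_grid: tuple[int, int] = (60, 50)
    photons_per_pixel: int = 200
    bin_factor: int = 5
    min_counts: int = 25
    time_window: float = 12.5   # ns
    n_bins: int = 256
    # FRET gating
    fret_lower: float = 8.4     # percent
    fret_upper: float = 91.2
    tau_reference: float | None = None  # default: fitted donor tau2 peak
    clone_photons: int = 200_000
    # clone ground truth: efficiencies (percent) and SEMs per myc clone
    fret_table: dict = field(default_factory=lambda: dict(cb.CLN3_FRET_TABLE))
    # topology engine
    direction: str = "C_start"
    model_d: bool = False
    predictor: PredictorParams = DEFAULT_PARAMS
    # additional user constraints as (start, end, state) triples
    extra_constraints: tuple = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "predictor" in kwargs and isinstance(kwargs["predictor"], dict):
            kwargs["predictor"] = PredictorParams(**kwargs["predictor"])
        for tup in ("donor_lifetimes", "flim_grid"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["predictor"] = dataclasses.asdict(self.predictor)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write stage outputs under ``config.out_dir``.

    Returns the machine-readable run report (also written as JSON).
    Identical configs (including seeds) produce identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.resolved(), "status": "ok", "stages": {}}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    try:
        # --- donor-only FLIM reference -----------------------------------
        t0 = stage("flim")
        t1, t2 = config.donor_lifetimes
        donor_params = synthetic.DecayParams(components=((0.5, t1), (0.5, t2)),
                                             time_window=config.time_window,
                                             n_bins=config.n_bins)
        grid = synthetic.generate_flim_image(config.flim_grid, donor_params,
                                             config.photons_per_pixel, seed=seeds[0])
        io.save_flim_grid(grid, out / "donor_flim_grid.npz")
        pops = flim.donor_population_analysis(grid, config.bin_factor, config.min_counts)
        tau_ref = config.tau_reference or pops.tau2_peak.peak
        report["stages"]["flim"] = {
            "tau1_peak": pops.tau1_peak.peak, "tau2_peak": pops.tau2_peak.peak,
            "tau_reference": tau_ref, "n_pixels": pops.n_pixels,
            "elapsed_s": round(time.time() - t0, 2)}

        # --- per-clone FRET ----------------------------------------------
        t0 = stage("fret")
        rng = np.random.default_rng(seeds[1])
        measurements = []
        for ins in cb.CLN3_INSERTIONS:
            if ins.tag != "myc" or ins.clone_id not in config.fret_table:
                continue
            eff_true, sem = config.fret_table[ins.clone_id]
            tau_da_true = tau_ref * (1.0 - eff_true / 100.0)
            da = synthetic.DecayParams(components=((1.0, tau_da_true),),
                                       time_window=config.time_window,
                                       n_bins=config.n_bins)
            h = synthetic.generate_decay_histogram(da, config.clone_photons,
                                                   seed=int(rng.integers(2**31)))
            fit = flim.fit_biexponential(h, fix={"f1": 0.5, "bg": 0.0})
            measurements.append(flim.FretMeasurement.from_lifetimes(
                ins.clone_id, tau_ref, fit.mean_lifetime, sem=sem,
                lower=config.fret_lower, upper=config.fret_upper))
        io.write_fret_tsv(measurements, out / "fret_measurements.tsv")
        report["stages"]["fret"] = {
            m.clone_id: {"efficiency": round(m.efficiency, 2), "call": m.significance}
            for m in measurements}

        # --- constraints --------------------------------------------------
        t0 = stage("constraints")
        sequence = io.load_cln3_sequence()
        anchor = cb.get_insertion("eGFP11")
        cons = [cb.TopologyConstraint.at(anchor.constrained_residue, "inside",
                                         provenance="assumption")]
        for m in measurements:
            if m.clone_id == "myc5" and not config.model_d:
                continue  # clone failed the rescue assay; site left to accumulation
            ins = cb.get_insertion(m.clone_id)
            if m.clone_id == "myc5" and config.model_d:
                cons.append(cb.TopologyConstraint.at(ins.constrained_residue,
                                                     "membrane", provenance="fret"))
                continue
            c = cb.constraint_from_clone(ins, m, "inside", len(sequence))
            if c is not None:
                cons.append(c)
        cons.extend(cb.prior_constraints(len(sequence)))
        for entry in config.extra_constraints:
            start, end, state = entry[0], entry[1], entry[2]
            cons.append(cb.TopologyConstraint(int(start), int(end), str(state),
                                              provenance="user"))
        io.write_constraints_tsv(cons, out / "base_constraints.tsv")
        report["stages"]["constraints"] = {
            "n_base": len(cons),
            "fret_sites": [c.start for c in cons if c.provenance == "fret"]}

        # --- iterative accumulation + final model -------------------------
        t0 = stage("topology")
        sites = cb.cln3_candidate_sites(cons)
        trace = cb.iterative_accumulation(sequence, sites, cons,
                                          direction=config.direction, seed=seeds[2],
                                          params=config.predictor)
        io.write_constraints_tsv(trace.constraints, out / "final_constraints.tsv")
        io.write_json({"direction": trace.direction,
                       "site_order": list(trace.site_order),
                       "decisions": trace.as_records()}, out / "accumulation_trace.json")
        if trace.final_model is None:
            report["status"] = "infeasible"
        else:
            model = trace.final_model
            io.write_segments_tsv(model, out / "topology_segments.tsv")
            rel = trace.final_reliability
            if rel is not None:
                io.write_reliability_tsv(rel.per_residue, model.topology_string,
                                         out / "topology_reliability.tsv")
            report["stages"]["topology"] = {
                "n_tm": model.n_tm,
                "segments": [[s.start, s.end, s.state] for s in model.segments],
                "n_term": model.n_term_state, "c_term": model.c_term_state,
                "topology_string": model.topology_string,
                "mean_reliability": None if rel is None else round(rel.mean, 2),
                "elapsed_s": round(time.time() - t0, 2)}
    except Exception as exc:  # surface the failing stage, keep partial outputs
        report["status"] = "error"
        report["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(report, out / "run_report.json")
        raise
    io.write_json(report, out / "run_report.json")
    return report
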