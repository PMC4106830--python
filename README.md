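# cln3topo

Membrane-topology inference for the human lysosomal protein CLN3
(battenin) from intramolecular FRET evidence — reimplemented as a tested,
reusable Python library.

Mutations in *CLN3* cause juvenile neuronal ceroid lipofuscinosis (Batten
disease), and the protein's structure is unresolved; topology models must
be assembled from sparse experimental constraints. The experimental logic
this package operationalises: clones of CLN3 carry a near C-terminal eGFP
(FRET donor) and one myc-tag (acceptor binding site) inserted elsewhere.
Because a lipid bilayer suppresses energy transfer, *significant* FRET —
measured as a drop in the donor fluorescence lifetime τ by FLIM —
indicates that the tag pair shares a membrane side. Those sidedness calls,
together with prior constraints (antibody epitopes, N-glycosylation
sites), feed a constrained topology predictor that outputs a
six-transmembrane-domain model of CLN3 with cytosolic N- and C-termini.

The package covers the whole chain, each stage usable on its own:

* **`synthetic`** — seeded generators for every input: TCSPC decay
  histograms and FLIM grids, rescue-assay cell fields with known vesicle
  counts, colocalization channel pairs, planted-TM protein sequences.
* **`flim`** — spatial binning (×5), background filtering (25 counts),
  Poisson-deviance biexponential decay fits, lifetime-population peak
  extraction, `%E = (1 − τ_DA/τ_ref)·100`, significance gating against
  the Förster band [8.4, 91.2] %.
* **`imaging`** — intensity-independent colocalized fraction
  (normalize → Wiener 3×3 → average 3×3 → blank → 10-count threshold →
  symmetry gate) and rescue-assay quantification (1–3 µm vesicles per
  cell, fold change, ANOVA).
* **`topology`** — dynamic programming over the alternating
  loop/helix grammar, scored with the translocon ΔG hydrophobicity scale
  under hard sidedness/membrane constraints; ensemble-agreement
  reliability; minimal-TM-count oracle; model checking.
* **`constraints`** — the CLN3 clone registry, FRET → constraint
  conversion, prior constraints, and the greedy iterative
  constraint-accumulation loop (C-start / N-start / scrambled).
* **`pipeline` / CLI** — one reproducible run from simulation to final
  model (`cln3topo run`, plus per-stage subcommands).

## Worked example

Constrained prediction on the bundled 438-aa CLN3 sequence
(`examples/topology_prediction.py`):

```
sequence length: 438 aa
minimal TM count demanded by the constraints alone: 4
predicted TM segments (6):
   38- 56
  128-144
  152-175
  179-202
  280-298
  347-368
N-terminus: inside, C-terminus: inside
mean ensemble reliability: 95.9%
```

The constraints alone only force four membrane crossings; hydrophobicity
adds the helix triplet between the luminal residue 126 and the cytosolic
residue 204, giving six helices with both termini cytosolic — segment
bounds within a few residues of the published six-TMD model. The FLIM
stage (`examples/flim_population_fit.py`) recovers the two donor lifetime
populations from synthetic decays:

```
retained pixels after binning/filtering: 200
pooled fit:  tau1 = 2.284 ns, tau2 = 2.130 ns
tau1 population peak: 2.283 ns (width 0.068)   truth 2.28 ns
tau2 population peak: 2.131 ns (width 0.065)   truth 2.14 ns
```

and the rescue assay (`examples/rescue_assay.py`) recovers a planted
1.4-fold vesicle increase as `1.395 ± 0.030` with ANOVA p ≈ 2×10⁻⁴⁷.
Each script in `examples/` exercises one capability and prints what the
numbers mean; `examples/full_pipeline.py` chains everything through
`run_pipeline`.

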