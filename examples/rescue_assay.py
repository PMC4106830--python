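"""Rescue-assay quantification: small-vesicle counts per cell and fold change.

Simulates a field of cells in which transfected cells carry 1.4x more
small (1-3 um) acidic vesicles, detects vesicles per cell with an Otsu +
connected-components + equivalent-diameter gate, and recovers the fold
change with its SEM and a one-way ANOVA p-value.
"""

from cln3topo import FieldScenario, rescue_experiment

scenario = FieldScenario(n_cells=600, transfected_fraction=0.3,
                         base_vesicle_mean=14.0, fold_change=1.4,
                         vesicle_diameter_range=(1.0, 3.0), pixel_size=0.1,
                         seed=7)
res = rescue_experiment(scenario)

print(f"mean vesicles, transfected cells:     {res.mean_transfected:.2f} "
      f"(n={res.n_transfected})")
print(f"mean vesicles, non-transfected cells: {res.mean_non_transfected:.2f} "
      f"(n={res.n_non_transfected})")
print(f"rescue ratio: {res.ratio:.3f} +/- {res.sem:.3f}   (truth 1.4)")
print(f"ANOVA p-value: {res.p_value:.3e}")
print()
print("A ratio near the simulated 1.4-fold increase shows the detection gate")
print("recovers the per-cell counts without density-dependent bias.")
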