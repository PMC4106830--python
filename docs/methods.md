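# Methods

`cln3topo` implements the analysis chain that converts intramolecular FRET
measurements on internally tagged membrane-protein clones into a
constrained membrane-topology model, with the human lysosomal protein CLN3
(battenin, 438 aa) as the worked system. This note records the models, the
parameters that matter, what the synthetic data do and do not emulate, and
the design choices made where the design was genuinely open.

## TCSPC decay model and fitting

A donor decay within the acquisition window `[0, T]` is modelled as a
truncated biexponential plus uniform background,

    p(t) ∝ f1·e^(−t/τ1) + (1−f1)·e^(−t/τ2) + bg/T,

integrated per time bin and fitted by minimising the Poisson deviance of
the binned counts (counts are Poisson; least squares is available as a
fallback). Defaults follow the analysis they reproduce: window 12.5 ns with
256 bins (the acquisition unit's bin width is not specified anywhere we
could find, so these are configurable), spatial binning factor 5, and a
25-count background filter applied after binning ("less than 25" semantics:
a 24-count pixel is dropped, a 25-count pixel kept). Fits are initialised
by a method-of-moments lifetime from the truncation-corrected mean arrival
time, optimised with a bounded Nelder–Mead simplex (gradient methods stall
on the flat τ1/τ2 ridge), lifetimes are sorted τ1 ≥ τ2 afterwards, and fits
with τ1/τ2 < 1.02 are flagged degenerate rather than discarded.

**Identifiability and the semi-global population analysis.** The two
donor-only populations sit at 2.28 and 2.14 ns — a lifetime ratio of 1.065.
A free biexponential fit of such a pair is statistically unidentifiable at
realistic per-pixel photon counts (the Kullback–Leibler distance between
the mixture and the best single exponential is of fourth order in the
lifetime separation), and unconstrained per-pixel fits wander over a wide
ridge. `donor_population_analysis` therefore uses the standard semi-global
scheme: (1) all retained pixels are pooled and fitted with the amplitude
fraction held at 1/2 — with equal, spatially uniform occupancy the
per-pixel fraction is not separable, so it is not estimated; (2) each pixel
is refitted twice, with one lifetime at a time anchored at its pooled
estimate and the other free, which keeps the per-pixel problem well
conditioned; (3) each per-pixel lifetime map is summarised by a
single-Gaussian fit to its histogram. The Gaussian is fitted to the central
part of the distribution (within 2.5 robust standard deviations of the
median) so rare fit failures in the tails cannot drag the peak; for a clean
symmetric population this coincides with a plain Gaussian fit. Even the
pooled fit operates near the identifiability limit: at ~10⁶ pooled photons
it occasionally collapses onto the degenerate single-lifetime point
(~2.21 ns). Tests pin the seeded experiment where the pair is resolved;
this residual fragility is intrinsic to the lifetime ratio, not to the
optimiser.

## FRET efficiency and gating

Efficiency is `%E = (1 − τ_DA/τ_ref)·100`, reported as-is (negative values
possible) and gated afterwards. The significance band [8.4, 91.2] % — the
efficiencies at donor–acceptor distances R₀ ± 50 % — is taken as a given
constant: the band cannot be re-derived from the standard sixth-power
efficiency–distance relation (which gives 1.6 %/98.6 % at r = 1.5 R₀ and
0.5 R₀), so re-derivation would silently change the gate. Both bounds are
inclusive on the significant side; the source analysis states a lower
"threshold" without boundary semantics, and inclusivity is the convention
that keeps the printed 8.4 % boundary case significant. The reference
lifetime is an explicit input defaulting to the shorter donor-only
population peak; note the printed donor-only background of ~4 % does not
follow arithmetically from (1 − 2.14/2.28)·100 = 6.1 %, so the reference
the original analysis used is ambiguous — taking τ_ref as explicit input
avoids baking in an irreproducible choice. Significant FRET pins the
residue following the myc insertion to the anchor side; non-significant
FRET yields *no* constraint, because absent transfer can reflect dipole
orientation or steric masking rather than a separating membrane.

## Colocalization

Both channels are rescaled to the 8-bit range by their own maxima, cleaned
with a 3×3 Wiener filter followed by 3×3 averaging, zero-blanked, and
thresholded at 10 counts (applied after filtering, on the 8-bit scale; the
source is silent on the order). A reference-channel pixel is colocalized
when both channels pass the threshold and the normalized intensity
asymmetry |a−b|/(a+b) is at most 0.3. The asymmetry statistic is a
clearly labelled stand-in: the underlying intensity-symmetry algorithm is
cited but not reproduced in the source, and |a−b|/(a+b) with a
configurable cutoff captures its intent (intensity-independence) with one
interpretable parameter.

## Rescue assay

Small acidic vesicles are segmented per cell by a light Gaussian smooth,
an Otsu threshold (scale-invariant, so detection counts are unaffected by
uniform intensity changes) and connected components, gated to equivalent
diameters in [1, 3] µm inclusive. The rescue statistic is the ratio of
mean per-cell counts in transfected vs non-transfected cells, with a SEM
from first-order error propagation and a one-way ANOVA across groups.
Cell assignment uses the synthetic ground-truth cell map; a
nearest-centroid rule would replace it on real images.

## Synthetic data

Generators are pure functions of (parameters, seed); conservation is exact
(histogram sums equal requested photons, object counts equal the drawn
Poisson counts). Decays are pure truncated exponentials — no instrument
response function (the reproduced analysis never mentions one, and its
absence keeps the fitting well-posed), no pile-up, afterpulsing or
bleaching. Background is uniform over the window (dark-count model). Cell
fields place each cell on its own tile (streamable one cell at a time, so
10⁴-cell experiments never hold a full field in memory) with vesicles as
PSF-blurred discs of uniform random diameter; vesicle boundaries keep a
0.3 µm minimum gap inside a 12.5 µm cell radius so that detection losses
are size-symmetric and density-independent — the property that makes the
recovered fold change unbiased (at a 10 µm radius, crowding in transfected
cells biased a 2.0-fold truth to 1.8; 12.5 µm removes the bias). What
passing tests show is therefore that the measurement chain is unbiased
under these idealised conditions; real micrographs add segmentation errors
from touching cells, uneven illumination and out-of-focus light that the
generator deliberately does not model. Planted-TM sequences draw helices
from strongly hydrophobic residues and loops from polar/charged ones, with
margins (≳2 kcal/mol per window) far above the engine's decision boundary.

## Topology engine

The predictor segments a sequence under an alternating grammar — loops
strictly alternate between cytosolic ("inside") and luminal ("outside")
across helices, helix lengths lie in [17, 25] (consistent with the
21-residue helices of the final model), interior loops have ≥ 2 residues —
and maximises

    Σ_TM Σ_{i∈TM} (μ − ΔG(aa_i))  −  c·n_TM  +  b·#{Arg/Lys in inside loops}

where ΔG is the bundled translocon-scale apparent insertion energy per
residue (summed uniformly over segments; the position-dependent end
corrections of the full published profile model are not reimplemented),
μ = 0.35 kcal/mol/residue is the insertion offset, c = 1.0 kcal/mol the
per-helix insertion cost, and b = 0.5 the positive-inside bonus per
Arg/Lys. The offset is needed because the translocon scale systematically
overestimates ΔG for helices in multi-spanning context — under a literal
−ΔG score virtually no natural TMD is favourable. The per-helix cost
plays the role of a helix-initiation penalty: without it, marginally
hydrophobic stretches of CLN3 (95–111, 297–313, 363–384 — exactly the
regions debated as spurious extra TMDs) enter the optimum in pairs. The
pair (μ, c) was calibrated jointly on the engine's qualitative behaviour:
planted sequences are recovered exactly, the unconstrained CLN3 prediction
overpredicts (9 TMs, as unconstrained consensus predictors do), and the
constrained prediction is stable across accumulation orders. Hard
constraints restrict per-residue states; an unsatisfiable set is reported
as infeasible (a value, not an exception), mirroring the failed-to-compute
behaviour of constrained consensus servers. The optimum is found by
dynamic programming over (position, loop side) — O(L·max_tm) — with
deterministic tie-breaks (fewer helices, then a fixed backtrack order);
exhaustive enumeration over all grammar-valid segmentations verifies DP
optimality on short sequences in the test suite. `min_tm_count` runs the
same grammar with a pure helix-count objective and is verified against an
independent top-down recursion.

**Reliability.** With no trained component predictors available offline,
the consensus-style reliability is the per-residue agreement (percent)
among six engine variants (insertion offset 0.35 ± 0.1 × two
positive-inside settings); infeasible members are excluded and noted. This
measures robustness of the prediction to the engine's least certain
parameter, not a trained posterior; its absolute values are not comparable
to published reliability scores.

**Site selection in the accumulation loop.** The greedy loop fixes, at
each remaining insertion site, the state whose constrained optimum has the
highest model score, with mean ensemble reliability breaking ties (both are
recorded in the trace). Selection by reliability alone proved degenerate:
agreement among variants often *rises* for constraints that rigidify the
prediction regardless of their correctness, whereas the model score — the
continuous analogue of prediction confidence — discriminates properly.
Traces are fully deterministic given (sequence, order, seed); scrambled
orders shuffle with an explicit seed.

## CLN3 specifics

The bundled 438-aa sequence is a synthetic reconstruction (see the FASTA
header): it matches the documented tag-flanking tripeptides at all eleven
insertion sites, the N-glycosylation sequons at N71/N85, the 250–258
epitope, and the full length, and is suitable for every analysis here; it
is not certified identical to the database entry. Prior constraints:
cytosolic 250–258, 401 and the C-terminus; luminal 71 and 85
(N-glycosylation). The eGFP anchor state (inside at residue 407) is an
explicit assumption input. The myc5 clone (site 151) carries significant
FRET but failed the functional rescue; it contributes no constraint by
default, and the optional model-d refinement instead adds membrane@151.
Coordinates are 1-based inclusive throughout, on the native (untagged)
sequence, with each tag reporting on the residue *after* its insertion
point.

## Problem sizes used by tests and the acceptance script

Donor-population experiment: 100×50 pixels × 200 photons, binned ×5 to 200
retained pixels × 5000 photons. Oracle equivalence: 100 random sequences
of ≤ 60 residues. Rescue recovery: 10⁴ cells at fold 1.4 (the null check
uses 3×10³ cells, where the ratio's standard error is ~0.01). These sizes
are the package's reference experiments; all are configurable.

## Known limitations

* The 2.28/2.14 ns pair is at the edge of statistical identifiability;
  population peaks can collapse to ~2.21 ns on unlucky realisations.
* The reliability score is an agreement measure over engine variants, not
  a trained consensus; boundary positions of individual helices carry a
  few residues of uncertainty and differ from trained predictors.
* The colocalization asymmetry statistic is a stand-in for the cited (but
  unspecified) algorithm.
* The synthetic cell fields idealise segmentation; conclusions about real
  micrographs require validation on real data.
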