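# Methods

`fluxsort` reconstructs, as a tested pipeline, the quantitative machinery
behind single-cell metabolic phenotyping of pancreatic ductal
adenocarcinoma (PDAC) cells: pH-based flux and permeability inference,
plate-level fermentation/respiration assays, heterogeneity statistics, a
spatial clustering statistic, and a mechanistic model of the
IL-6R/STAT3/SOCS3 delayed-negative-feedback circuit that reproduces
sorting-and-relaxation experiments in silico.

## pH biophysics (`ph_core`)

**Dye calibration.** A ratiometric dye (cSNARF1) maps fluorescence ratio R
to intracellular pH through a one-site sigmoid,

    pH = pKa_dye ± log10((R_max − R) / (R − R_min)),

with the sign set by the ratio-vs-pH sense of the dye (default:
ratio decreases with pH, the `+` branch). The mapping is strictly monotone
on the open interval (R_min, R_max); samples outside it raise an error
naming the offending value, and the inverse round-trips to 1e-9.

**Buffering capacity.** β(pH) converts pH rates to acid fluxes. For mobile
buffers it is the Van Slyke closed form,

    β(pH) = β₀ + ln(10) · Σᵢ Cᵢ Kaᵢ [H⁺] / (Kaᵢ + [H⁺])²,

where β₀ is a constant intrinsic term. The plate medium is 2 mM HEPES
(pKa 7.5) + 2 mM MES (pKa 6.15) — β ≈ 1.34 mM/pH at pH 7.0.
Intracellular buffering defaults to a constant β₀ = 20 mM/pH; the true
cytoplasmic values are not pinned by the source assays, so this is an
explicit placeholder, configurable per run. CO₂/HCO₃⁻ chemistry is out of
scope by design (the assays run in CO₂/HCO₃⁻-free buffer).

**Fermentative flux.** Blocking monocarboxylate transporters (MCT) with
2 mM CHC (with 30 µM DMA suppressing Na⁺/H⁺ exchange) traps lactic acid in
the cell, so the acidification rate reads out lactic-acid production:
J = −β · dpHi/dt (mM·min⁻¹). An alkalinizing slope under blockade is
biologically unexpected and is returned flagged, not raised.

**Lactic-acid permeability.** After equilibration with 30 mM extracellular
lactate, washout to lactate-free medium drives acid efflux; the
alkalinization rate gives J = β · dpHi/dt, and

    P_HLac = J / ([HLac]_in − [HLac]_out)

with the undissociated-acid concentrations from Henderson–Hasselbalch
speciation (pKa 3.86 at 25 °C, configurable). P_HLac is reported in min⁻¹
(flux per unit gradient, surface-to-volume folded in); conversion to
cm·s⁻¹ is exposed as a pass-through requiring a user-supplied S/V ratio,
because normalisation to membrane area is not defined by the assay. An
alternative driving-force formalism ([H⁺][Lac⁻] product, the MCT
thermodynamic force) is available behind a flag; the two are proportional
at fixed extracellular pH.

**Rate estimation.** Slopes are fitted over a window starting 5 s after
the solution switch (skipping the ~25 ms switch transient and mixing
artefacts). The default window length is 30 s — appropriate for the curved
washout transients, where the gradient decays as lactate leaves. For
CHC-block traces the flux is constant and the full post-switch record
(~3 min) should be fitted; the analysis drivers do so. Theil–Sen is the
default slope estimator for single-cell traces (robust to spike
contamination); OLS is used for averaged traces. A constant trace has
r² = 0 by convention.

Numerical note: evaluating the washout driving force at the window-start
pHi (rather than mid-window) under-estimates P_HLac by a few percent
because intracellular lactate and pHi drift within the window; at the
default noise level (0.005 pH read noise) individual-cell estimates carry
~15% sampling error, so recovery guarantees are stated for the cohort
aggregate (mean/median over ≥100 cells, within 10%), not per cell.

## Plate assay (`plate_assay`)

Medium pH (HPTS ratio) and dissolved O₂ (RuBPY luminescence via the
Stern–Volmer relation O₂ = (I₀/I − 1)/K_SV) are converted to cumulative
quantities:

* H⁺(t) = V · ∫ β_m(pH) (−dpH) along the measured trajectory — a path
  integral evaluated with the midpoint rule, invariant to time-axis
  resampling (<0.1% under grid refinement), not an endpoint product;
* O₂ consumed = V · c_sat · (O₂(0) − O₂(t))/100, plus an optional
  first-order oil-layer leak correction k_leak · ∫(100 − O₂)/100 ds
  (default k_leak = 0, treating the oil layer as sealing).

c_sat defaults to 0.2 nmol/µL (air-saturated aqueous medium, 37 °C).
The cumulative-quantity equations follow from the buffering/partition
physics above; they are this package's reconstruction of the assay
arithmetic, not a transcription of a published formula sheet.

**Initial rates** are OLS slopes over the first 60 min (configurable),
normalised per 10⁵ cells (equal seeding densities are assumed enforced
upstream).

**Contrast decay.** The high/low sorted-group contrast is fitted with
D(t) = d_inf + (d0 − d_inf)·exp(−t/τ). The default metric is the fold
ratio (high/low); a difference metric is retained for near-zero rates.
The asymptote is bounded below at the metric floor (1 for fold, 0 for
difference): sorted subpopulations relax symmetrically toward the parental
mixture and cannot cross parity. This constraint matters — with 4 time
points and multiplicative noise the unconstrained 3-parameter fit is
poorly determined. Bootstrap CIs on τ resample residuals (200 reps,
seeded, recorded in the output). Non-decaying data return a flagged fit
rather than raising.

## Feedback circuit (`population_model`)

Each cell carries receptor `rcv` (IL-6R), active transcription factor `s`
(pSTAT3), inhibitor transcript `m` (SOCS3 mRNA) and inhibitor protein `c`
(SOCS3); all cells share one autocrine ligand pool L (IL-6):

    ds/dt   = k_act · rcv · L/(K_L+L) · 1/(1 + (c/K_C)^h) − k_deph · s
    dm/dt   = k_m s − d_m m
    dc/dt   = k_c m − d_c c
    drcv/dt = r0 + r1 s − d_r rcv
    dL/dt   = mean(l0 + l1 s) − d_l L

The delay of the negative arm is realised Goodwin-style through the mRNA
stage rather than an explicit time lag — simpler integration, same
phenomenology. Sign structure matches the experimental epistasis:
pSTAT3 → IL-6 secretion (+), pSTAT3 → IL-6R synthesis (+),
pSTAT3 → SOCS3 (+), SOCS3 ⊣ pSTAT3 (−). The ligand operates saturated
(L ≫ K_L) by default, which is why IL-6 supplementation is a no-op in the
model, as observed. SOCS3 protein half-life is treated as a free parameter
(reported estimates span 1 to >24 h); the default delay stages are 2 h
(mRNA) and 4 h (protein).

**Heterogeneity sources.** (i) Static lognormal per-cell dispersion of
k_act and r0 (CV 5%) and (ii) a per-cell Ornstein–Uhlenbeck process η(t)
multiplying k_act as exp(η), exactly discretised. The noise model is a
design choice: the source experiments attribute heterogeneity to dynamic
receptor/STAT3 signalling without specifying a stochastic law. Static
dispersion is kept small so that sorted contrasts collapse fully, which is
what the relaxation experiments show.

**Metabolic coupling.** F = f_min + f_gain·s (fermentation),
O = o_min + o_gain·s (respiration, own gain so the two co-vary — a joint
activation, not a switchover; the experimental 4-fold-vs-3-fold asymmetry
is not modelled mechanistically), P_HLac = p_min + p_gain·F (flux balance:
high-fermenting cells need matching acid-export capacity), and biomass
grows at growth_gain·F.

**Calibration.** The OU amplitude and reversion time are the two free
knobs, set by `analysis/03_calibrate_model.py` against two targets:
stationary top-vs-bottom decile ratio of F ≈ 10 (the extrapolated
order-of-magnitude contrast at the instant of sorting) and a measured
sorted-contrast mixing time ≈ 30 h. Shipped values: stationary log-sd
1.05, OU reversion 42 h. The reversion time exceeds the realised mixing
time because sorting also captures fast-decaying circuit fluctuations,
which steepen the early contrast decay.

**Integration.** Explicit Euler, fixed dt = 0.5 min, states clipped at
zero, with a stability guard dt ≤ 0.1/max-rate; halving dt changes
day-scale outputs by <1% (tested on the deterministic circuit).
Populations are initialised at the approximate stationary distribution
(OU noise from its stationary law, circuit states at per-cell quasi-steady
values) and burned in 60 h with a drift check (<2%/day, warning-flagged);
identical seeds give bit-identical trajectories.

**In-silico experiments.** `insilico_sort` gates the instantaneous
readout deterministically (ties broken by cell index);
`relaxation_experiment` cultures the sorted subpopulations in separate
wells (independent ligand pools — the alternative, a shared medium, would
couple their relaxation and is noted but not default); `chc_snapshot`
converts 3 min of closed-cell acid accumulation into a per-cell pHi shift
(ΔpHi = −F·t/β) for distribution comparison.

**Known limitations.** The receptor positive arm is kept weak
(r1 = 3e-5): with the linear receptor-synthesis law, a strong arm makes
SOCS3-knockout cells at high noise linearly unstable
(k_eff·r1/d_r > k_deph). As a result, sorting by the receptor readout
yields a directionally correct but weak (~1.1-fold) fermentative contrast,
smaller than observed experimentally; sorting by P_HLac, the primary
readout, is unaffected. No spatial IL-6 gradients, no transcriptome
layer, no cell-cycle coupling.

## Heterogeneity statistics (`heterogeneity_stats`)

Gaussian fits use the closed-form MLE (denominator n); gamma fits maximise
the likelihood from a method-of-moments start and are guaranteed not to
score below it. Fitting is by maximum likelihood even though the source
histograms were fitted visually — a histogram least-squares mode exists
for parity. Variance ranking across lines uses raw variance (matching the
published ranking) with the CV reported alongside, since between-line mean
differences confound raw variance. Two-sample comparisons use the
Kolmogorov–Smirnov test (exact small-sample p where feasible).

## Spatial statistic (`spatial`)

Per-cell nuclear/cytoplasmic STAT3 ratios on segmented sections are
correlated with the mean ratio of each cell's k nearest neighbours
(Euclidean, self excluded, cumulative nearest-k — "next-nearest" is read
as cumulative, recorded as an interpretation), for
k ∈ {3, 10, 100, 1000, 10000}; ks at or above the cell count are skipped
with a marker. Both Spearman (default — the methods text of the source
governs over its figure legend) and Pearson are exposed. The Spearman
variant ranks values once globally and averages neighbour ranks, which
makes the profile exactly invariant under monotone transforms of the
ratio; Pearson is invariant under affine transforms, and both under rigid
motions of the coordinates. Exact-distance ties are broken by ascending
cell id (stable sort). Significance is judged against a seeded permutation
null band (200 permutations, 95%). A constant field returns an undefined
(NaN) correlation, not 0.

## Synthetic data (`synthetic_data`)

Generators are pure functions of their configuration (same seed → same
bytes) and emit ground-truth tables sufficient to score every downstream
estimator.

* **Single-cell traces:** per-cell fermentative flux ~ Normal(0.2, 0.07)
  mM/min (truncated positive) and P_HLac ~ Gamma(shape 4, scale 18) min⁻¹
  — the distribution families observed for the two readouts; washout
  traces are forward-simulated from the efflux ODE (30 → 0 mM lactate);
  read noise 0.005 pH per sample. Cohort sizes are configurable up to the
  published panel sizes (~300 cells).
* **Plate wells:** group rates follow a mono-exponential fold contrast
  (default 3-fold at day 1, τ = 30 h, asymptote 1) with 5% multiplicative
  well noise; pH traces are generated by inverting the cumulative-H⁺ path
  integral under the assay buffer, O₂ traces by linear depletion.
  Defaults: 4 wells/group/day, 70k cells/well, 200 µL.
* **Spatial fields:** uniform centroids, lognormal baseline ratios
  (median 1, log-sd 0.3), discs of radius `cluster_scale` elevating the
  ratio `effect`-fold; `cluster_scale = 0` gives an iid field.

What the generators do *not* emulate: instrument drift and photobleaching,
segmentation errors, FACS gate impurity, well-edge effects, non-circular
activation domains, and any transcriptome layer. Passing tests therefore
certify the estimators against the stated statistical structure, not
against every artefact of real recordings.

## Problem sizes

Default experiment sizes are chosen as the smallest that make the
statistical targets stable: 100 seeded plate experiments for the τ
recovery study; 2,000 cells × 20 seeds for the sort-and-relax contrast
(60 h burn-in from the stationary initialisation); 300–500 cells for
perturbation panels; 1,200–4,000 cells for spatial fields (fields of ≥10⁴
cells are supported for the largest neighbourhood rung).

## Reproducibility

Every pipeline run derives all randomness from one root seed through
named substreams (`fluxsort._utils.substream_seed`); the CLI writes a
manifest with the config hash, stage seeds and package version, and
seeded reruns are byte-identical on all data outputs.
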