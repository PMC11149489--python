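# fluxsort

Dynamic metabolic heterogeneity in pancreatic cancer cell populations:
single-cell pH-based flux phenotyping, in-silico permeability sorting, and
a delayed-negative-feedback model of IL-6R/STAT3/SOCS3 signalling.

## The problem

Within one clonal PDAC population, single cells differ widely in
fermentative (glycolytic lactic-acid) rate. Two single-cell readouts make
this measurable: blocking lactate export (MCT inhibition with CHC) turns
fermentation into intracellular acidification, so the rate of pHi fall
times buffering capacity is the fermentative flux, J = −β·dpHi/dt; and
washing out a 30 mM lactate load triggers acid efflux whose rate,
normalised to the undissociated-acid gradient, is the membrane's apparent
lactic-acid permeability,

    P_HLac = β·(dpHi/dt) / ([HLac]in − [HLac]out)   (min⁻¹).

Because glycolytic production must balance membrane export, P_HLac is a
sortable proxy of fermentative rate. Sorted high/low subpopulations show a
strong metabolic contrast that is *transient*: it decays mono-exponentially,

    D(t) = d∞ + (d0 − d∞)·e^(−t/τ),  τ ≈ 30 h,

collapsing below 1.25-fold by day 4. The package's mechanistic explanation
is a per-cell delayed negative feedback circuit — IL-6 activates STAT3
through IL-6R; pSTAT3 drives fermentation, its own receptor and ligand,
and its inhibitor SOCS3, whose transcription/translation delay closes a
slow negative loop — with slow stochastic modulation producing cells that
take turns being metabolically active. The library implements each stage;
`analysis/` contains the numbered drivers that run the studies;
`scripts/acceptance.py` recomputes the headline numbers.

## Worked example

Sort the calibrated feedback model by the permeability readout and watch
the contrast relax:

```python
import numpy as np
from fluxsort import population_model as pm
from fluxsort.plate_assay import fit_contrast_decay

params, coupling = pm.FeedbackParams(), pm.MetabolicCoupling()
table = pm.relaxation_experiment(
    params, coupling, sample_days=[1, 2, 3, 4, 5, 7],
    n_cells=2000, seed=400, burn_in_h=60.0,
)
print(table[["day", "fold_f", "fold_o"]].round(2).to_string(index=False))
fit = fit_contrast_decay([24.0 * d for d in table["day"]],
                         table["f_high"].to_numpy()[:, None],
                         table["f_low"].to_numpy()[:, None],
                         n_boot=200, seed=401)
print(f"tau = {fit.tau:.1f} h, CI {fit.ci_tau[0]:.1f}-{fit.ci_tau[1]:.1f} h")
```

prints

```
 day  fold_f  fold_o
   1    2.71    2.19
   2    1.74    1.56
   3    1.19    1.15
   4    1.11    1.09
   5    1.13    1.10
   7    0.94    0.95
tau = 26.3 h, CI 21.7-29.2 h
```

— a ~3-fold fermentative contrast one day after sorting (the stationary
decile ratio is ~10, so the contrast at the instant of sorting is an order
of magnitude), collapsed below 1.25-fold by day 4, with a fitted
relaxation time near the 30 h calibration target.

The same experiment on synthetic *plate* data (dual-dye well time courses
converted to cumulative H⁺/O₂ and initial rates per 10⁵ cells) is
`analysis/02_plate_contrast.py`:

```
day-1 fermentative contrast: 2.91-fold (O2: 2.94-fold)
fitted tau = 27.5 h (95% bootstrap CI 22.9-29.8 h), d_inf = 1.00
analytic collapse below 1.25-fold on day 4
```

## Layout

| Path | Contents |
| --- | --- |
| `src/fluxsort/ph_core.py` | dye calibration, buffering capacity, flux, P_HLac, CHC-shift statistic |
| `src/fluxsort/plate_assay.py` | Stern–Volmer O₂, cumulative H⁺/O₂, initial rates, contrast-decay fit |
| `src/fluxsort/population_model.py` | feedback circuit, in-silico sorting, perturbations, relaxation |
| `src/fluxsort/heterogeneity_stats.py` | Gaussian/gamma MLE fits, variance ranking, KS tests |
| `src/fluxsort/spatial.py` | kNN correlation profile of nuclear/cytoplasmic STAT3 ratios |
| `src/fluxsort/synthetic_data.py` | seeded generators with embedded truth |
| `src/fluxsort/cli.py` | `fluxsort synth/ph/plate/sim/stats/spatial/all` with run manifests |
| `analysis/01–06_*.py` | numbered study drivers writing tables under `results/` |
| `docs/methods.md` | model equations, parameter choices, limitations |

A thin CLI wraps the stages, e.g.

```bash
fluxsort all --out results/run --seed 42
```

which emits the stage outputs plus a `manifest.json` (config hash, named
seed substreams, versions); seeded reruns are byte-identical.

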