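#!/usr/bin/env python
"""Single-cell metabolic phenotyping on synthetic cSNARF1 cohorts.

Generates per-cell pHi time courses under the two superfusion protocols
(MCT blockade -> fermentative flux; lactate washout -> lactic-acid
permeability) for a panel of cell-line-like cohorts with prescribed
spread, runs the estimators, fits the distribution families (Gaussian for
flux, gamma for permeability), and ranks the cohorts by variance.

Writes results/single_cell/{rates.csv, fits.json, variance_ranking.csv}.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fluxsort import heterogeneity_stats as hs
from fluxsort import ph_core, synthetic_data as sd
from fluxsort.synthetic_data import GeneratorConfig

OUT = Path("results/single_cell")
OUT.mkdir(parents=True, exist_ok=True)

# cohort sizes mirror the single-cell panels (n up to ~300 cells per line);
# flux spread (sd, mM/min) increases across the panel
PANEL = {
    "lineA": (31, 0.02), "lineB": (48, 0.03), "lineC": (117, 0.04),
    "lineD": (37, 0.05), "lineE": (157, 0.06), "lineF": (299, 0.08),
}

rows = []
flux_samples = {}
for i, (line, (n, sd_flux)) in enumerate(PANEL.items()):
    cfg = GeneratorConfig(seed=100 + i, n_cells=n)
    traces, truth = sd.gen_single_cell_timecourses(
        cfg, "chc_block", mean_flux=0.2, sd_flux=sd_flux
    )
    est = []
    for tc in traces:
        # CHC-block acidification is linear (constant flux), so the slope is
        # fitted over the whole 3 min post-switch record; the short default
        # window is reserved for the curved washout transients
        slope, r2 = ph_core.estimate_rate(tc, window=(5.0 / 60.0, 3.0),
                                          method="robust_line")
        res = ph_core.fermentative_flux(slope, ph_core.INTRACELLULAR_BETA,
                                        r_squared=r2)
        est.append(res.flux)
        rows.append({"line": line, "cell_id": tc.cell_id,
                     "readout": "fermentative_flux", "value": res.flux})
    flux_samples[line] = np.array(est)

cfg = GeneratorConfig(seed=200, n_cells=304)
traces, truth = sd.gen_single_cell_timecourses(cfg, "lactate_washout")
ctx = ph_core.LactateContext(lac_out=0.0, lac_in=30.0)
p_est = []
for tc in traces:
    res = ph_core.permeability_from_washout(tc, ctx, ph_core.INTRACELLULAR_BETA)
    p_est.append(res.p_hlac)
    rows.append({"line": "lineF", "cell_id": tc.cell_id,
                 "readout": "p_hlac", "value": res.p_hlac})
p_est = np.array(p_est)

pd.DataFrame(rows).to_csv(OUT / "rates.csv", index=False)

# read noise can push the lowest-permeability estimates below zero; the
# gamma family needs the positive part (count reported alongside)
p_pos = p_est[p_est > 0]
fits = {
    "fermentative_flux_lineF": dataclasses.asdict(
        hs.fit_distribution(flux_samples["lineF"], "gaussian")
    ),
    "p_hlac_lineF": dataclasses.asdict(hs.fit_distribution(p_pos, "gamma")),
    "p_hlac_n_nonpositive": int((p_est <= 0).sum()),
}
(OUT / "fits.json").write_text(json.dumps(fits, indent=1))

ranking = hs.rank_by_variance(flux_samples)
ranking.to_csv(OUT / "variance_ranking.csv", index=False)

truth_mean = truth["p_hlac"].mean()
print(f"fermentative flux (lineF, n=299): Gaussian mu="
      f"{fits['fermentative_flux_lineF']['params'][0]:.3f} mM/min, "
      f"sigma={fits['fermentative_flux_lineF']['params'][1]:.3f}")
print(f"P_HLac (n=304): gamma shape={fits['p_hlac_lineF']['params'][0]:.2f}, "
      f"scale={fits['p_hlac_lineF']['params'][1]:.1f} "
      f"(estimated mean {p_est.mean():.1f} vs truth {truth_mean:.1f} min^-1)")
print("variance ranking (ascending):", ", ".join(ranking["line"]))
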