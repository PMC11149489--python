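#!/usr/bin/env python
"""Calibration of the feedback model's heterogeneity parameters.

The two free noise parameters of the circuit — the stationary log-sd of
the Ornstein-Uhlenbeck modulation of the pSTAT3 activation gain and its
reversion time — are set against two population-level targets:

* stationary top-vs-bottom decile ratio of the fermentative rate ~ 10
  (the extrapolated order-of-magnitude contrast at the moment of sorting);
* sorted-contrast mixing time ~ 30 h (the fitted mono-exponential decay
  of the in-silico sort-and-relax experiment).

This script scans a small grid around the shipped defaults and reports the
realised targets, confirming the defaults (stationary log-sd 1.05, OU
reversion 42 h; the circuit's fast filtering makes the realised mixing
time shorter than the OU reversion time).

Writes results/calibration/grid.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fluxsort import population_model as pm
from fluxsort.plate_assay import fit_contrast_decay

OUT = Path("results/calibration")
OUT.mkdir(parents=True, exist_ok=True)

coupling = pm.MetabolicCoupling()
rows = []
for sd_log in (0.9, 1.05, 1.2):
    for tau_ou_h in (30.0, 42.0, 54.0):
        theta = 1.0 / (tau_ou_h * 60.0)
        params = pm.FeedbackParams(
            sigma_noise=sd_log * np.sqrt(2.0 * theta), theta_noise=theta
        )
        rng = np.random.default_rng(1)
        state = pm.init_population(2000, params, rng)
        pm.simulate(state, params, coupling, 60.0 * 60.0, 0.5, rng)
        F = pm.fermentative_rate(state, coupling)
        q10, q90 = np.quantile(F, [0.1, 0.9])
        decile_ratio = F[F >= q90].mean() / F[F <= q10].mean()
        # the tau fit from a single sort-and-relax run is noisy: use the
        # median over a few seeds
        folds, taus = [], []
        for seed in (2, 3, 4):
            table = pm.relaxation_experiment(
                params, coupling, sample_days=[1, 2, 3, 4, 5, 7],
                n_cells=1500, seed=seed, burn_in_h=60.0,
            )
            folds.append(table["fold_f"].iloc[0])
            fit = fit_contrast_decay(
                [24.0 * d for d in table["day"]],
                table["f_high"].to_numpy()[:, None],
                table["f_low"].to_numpy()[:, None], n_boot=0,
            )
            taus.append(fit.tau)
        day1_fold = float(np.median(folds))
        mixing = float(np.median(taus))
        rows.append({
            "sd_log": sd_log, "tau_ou_h": tau_ou_h,
            "decile_ratio": decile_ratio, "day1_fold": day1_fold,
            "fitted_mixing_h": mixing,
        })
        print(f"sd_log={sd_log:.2f} tau_OU={tau_ou_h:4.0f} h -> decile ratio "
              f"{decile_ratio:5.2f}, day-1 fold {day1_fold:.2f}, "
              f"fitted mixing {mixing:5.1f} h")

grid = pd.DataFrame(rows)
grid.to_csv(OUT / "grid.csv", index=False)

default = pm.FeedbackParams()
sd_def = default.ou_stationary_sd
tau_def = 1.0 / default.theta_noise / 60.0
print(f"\nshipped defaults: stationary log-sd {sd_def:.2f}, OU reversion "
      f"{tau_def:.0f} h (targets: decile ratio ~10, mixing ~"
      f"{pm.FeedbackParams.MIXING_TIME_TARGET_H:.0f} h)")
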