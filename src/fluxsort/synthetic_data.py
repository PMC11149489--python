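"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (same seed, same
bytes) and returns the generated data together with a ground-truth table
sufficient to score every downstream estimator.

The generators emulate the study conditions of the wet assays:

* single-cell cSNARF1 pHi time courses under rapid solution switching
  (MCT blockade with 2 mM CHC, or 30 mM-lactate washout), with per-cell
  fermentative flux drawn from a Gaussian and lactic-acid permeability
  from a gamma distribution — the families that describe the respective
  single-cell histograms — plus Gaussian read noise (default sd 0.005 pH);
* plate-reader dual-dye well time courses for sorted subpopulations across
  days post-sorting, whose high/low rate contrast follows a
  mono-exponential decay with multiplicative well noise (default 5%);
* 2-D fields of segmented cells carrying nuclear/cytoplasmic STAT3 ratios
  with tunable circular-cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import ph_core, plate_assay
from .ph_core import BufferSpec, PhTimecourse, PKA_LACTIC_ACID
from .plate_assay import O2_SAT_DEFAULT, WellTimecourse

__all__ = [
    "GeneratorConfig",
    "gen_single_cell_timecourses",
    "gen_plate_timecourses",
    "gen_spatial_field",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Common generator knobs; per-generator keyword arguments refine them.

    ``noise_sd`` is the pH read noise on single-cell traces (pH units) and
    ``rate_noise`` the multiplicative sd on plate-well rates.
    """

    seed: int = 0
    n_cells: int = 300
    n_wells: int = 4
    noise_sd: float = 0.005
    rate_noise: float = 0.05

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# single-cell pHi time courses


def _washout_trace(
    p_hlac: float,
    t: np.ndarray,
    ph0: float,
    lac0: float,
    beta: float,
    pka: float,
    dt_int: float = 0.005,
) -> np.ndarray:
    """Forward-simulate lactic-acid efflux after washout (lac_out = 0).

    d[Lac]/dt = -P * [HLac](pHi, Lac);  dpHi/dt = +P * [HLac] / beta.
    Sampled at the (post-switch) times ``t``.
    """
    n_int = int(np.ceil(t[-1] / dt_int)) + 1
    ph, lac = ph0, lac0
    out = np.empty_like(t)
    ti = 0.0
    j = 0
    for _ in range(n_int + 1):
        while j < t.size and t[j] <= ti + 1e-12:
            out[j] = ph
            j += 1
        if j >= t.size:
            break
        hlac = lac / (1.0 + 10.0 ** (ph - pka))
        eff = p_hlac * hlac
        lac = max(lac - dt_int * eff, 0.0)
        ph = ph + dt_int * eff / beta
        ti += dt_int
    out[j:] = ph
    return out


def gen_single_cell_timecourses(
    cfg: GeneratorConfig,
    protocol: Literal["chc_block", "lactate_washout"],
    mean_flux: float = 0.2,
    sd_flux: float = 0.07,
    gamma_shape: float = 4.0,
    gamma_scale: float = 18.0,
    beta: float = ph_core.INTRACELLULAR_BETA,
    ph0: float = 7.3,
    lac0: float = 30.0,
    pka_lac: float = PKA_LACTIC_ACID,
    t_pre: float = 1.0,
    t_post: float = 3.0,
    sample_hz: float = 0.5,
) -> tuple[list[PhTimecourse], pd.DataFrame]:
    """Per-cell pHi time courses under one superfusion protocol + truth.

    ``chc_block``: fermentative flux J ~ Normal(mean_flux, sd_flux),
    truncated positive; closed-cell acidification at rate J/beta after the
    switch at t = 0.  ``lactate_washout``: P_HLac ~ Gamma(shape, scale);
    cells pre-equilibrated with ``lac0`` mM lactate alkalinize as acid
    leaves.  Gaussian read noise ``cfg.noise_sd`` is added to every sample.
    """
    rng = cfg.rng()
    t = np.arange(-t_pre, t_post + 1e-9, 1.0 / (60.0 * sample_hz))
    post_mask = t > 0
    traces: list[PhTimecourse] = []
    truth_rows = []
    for i in range(cfg.n_cells):
        cid = f"cell{i:04d}"
        if protocol == "chc_block":
            j_true = -1.0
            while j_true <= 0:
                j_true = rng.normal(mean_flux, sd_flux)
            ph = np.full_like(t, ph0)
            ph[post_mask] = ph0 - (j_true / beta) * t[post_mask]
            truth_rows.append({"cell_id": cid, "flux": j_true, "beta": beta})
        elif protocol == "lactate_washout":
            p_true = rng.gamma(gamma_shape, gamma_scale)
            ph = np.full_like(t, ph0)
            ph[post_mask] = _washout_trace(
                p_true, t[post_mask], ph0, lac0, beta, pka_lac
            )
            truth_rows.append(
                {"cell_id": cid, "p_hlac": p_true, "beta": beta,
                 "lac0": lac0, "ph0": ph0}
            )
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        if cfg.noise_sd > 0:
            ph = ph + rng.normal(0.0, cfg.noise_sd, ph.size)
        traces.append(
            PhTimecourse(t, np.clip(ph, 5.5, 8.5), protocol, cid, "ph", 0.0)
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = cfg.seed
    return traces, truth


def timecourses_to_frame(traces: Sequence[PhTimecourse]) -> pd.DataFrame:
    """Tidy CSV schema: cell_id, time_min, ratio_or_ph, signal_kind, protocol."""
    rows = []
    for tc in traces:
        for tm, v in zip(tc.time_min, tc.value):
            rows.append(
                {
                    "cell_id": tc.cell_id,
                    "time_min": tm,
                    "ratio_or_ph": v,
                    "signal_kind": tc.signal_kind,
                    "protocol": tc.protocol,
                }
            )
    return pd.DataFrame(rows)


def frame_to_timecourses(df: pd.DataFrame) -> list[PhTimecourse]:
    out = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_min")
        out.append(
            PhTimecourse(
                g["time_min"].to_numpy(),
                g["ratio_or_ph"].to_numpy(),
                str(g["protocol"].iloc[0]),
                str(cid),
                str(g["signal_kind"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# plate-reader well time courses


def _ph_trace_from_rate(
    rate_nmol_min: float,
    t: np.ndarray,
    buf: BufferSpec,
    volume_ul: float,
    ph_start: float,
) -> np.ndarray:
    """Integrate dpH/dt = -rate / (V beta(pH)) on the sampling grid."""
    ph = np.empty_like(t)
    ph[0] = ph_start
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        beta = ph_core.buffering_capacity(ph[i - 1], buf)
        ph[i] = ph[i - 1] - dt * rate_nmol_min / (volume_ul * beta)
    return ph


def gen_plate_timecourses(
    cfg: GeneratorConfig,
    contrast_truth: tuple[float, float, float] = (3.0, 30.0, 1.0),
    days: Sequence[float] = (1, 2, 4, 7),
    base_h_rate: float = 1.7,
    base_o2_rate: float = 0.2,
    o2_contrast_truth: tuple[float, float, float] | None = None,
    cells_per_well: float = 7e4,
    volume_ul: float = 200.0,
    buf: BufferSpec | None = None,
    ph_start: float = 7.4,
    duration_min: float = 60.0,
    dt_sample: float = 2.0,
    anchor_day: float = 1.0,
) -> tuple[list[WellTimecourse], pd.DataFrame]:
    """Dual-dye well time courses for sorted high/low groups across days.

    ``contrast_truth`` = (d0, tau_h, d_inf) defines the fold contrast of the
    H+ production rate, anchored so D(anchor_day) = d0; well rates are the
    group rate with multiplicative lognormal noise ``cfg.rate_noise``.
    pH traces are generated by inverting the cumulative-H+ path integral
    under the assay buffer, O2 traces by linear depletion.
    """
    if buf is None:
        buf = BufferSpec.assay_medium()
    if o2_contrast_truth is None:
        o2_contrast_truth = contrast_truth
    rng = cfg.rng()
    t = np.arange(0.0, duration_min + 1e-9, dt_sample)
    d0, tau, d_inf = contrast_truth
    od0, otau, od_inf = o2_contrast_truth
    wells: list[WellTimecourse] = []
    truth_rows = []
    for day in days:
        fold_h = plate_assay.contrast_at(24.0 * day, d0, tau, d_inf,
                                         anchor_h=24.0 * anchor_day)
        fold_o = plate_assay.contrast_at(24.0 * day, od0, otau, od_inf,
                                         anchor_h=24.0 * anchor_day)
        rates = {
            "p_hlac_high": (base_h_rate * np.sqrt(fold_h),
                            base_o2_rate * np.sqrt(fold_o)),
            "p_hlac_low": (base_h_rate / np.sqrt(fold_h),
                           base_o2_rate / np.sqrt(fold_o)),
        }
        for group, (rh, ro) in rates.items():
            for w in range(cfg.n_wells):
                noise_h = rng.lognormal(0.0, cfg.rate_noise)
                noise_o = rng.lognormal(0.0, cfg.rate_noise)
                rate_h = rh * noise_h
                rate_o = ro * noise_o
                ph = _ph_trace_from_rate(rate_h, t, buf, volume_ul, ph_start)
                o2 = np.clip(
                    100.0 - 100.0 * rate_o * t / (volume_ul * O2_SAT_DEFAULT),
                    0.0, 120.0,
                )
                wid = f"d{day:g}_{group}_{w}"
                wells.append(
                    WellTimecourse(t, ph, o2, wid, group, cells_per_well, day)
                )
                truth_rows.append(
                    {
                        "well_id": wid, "group": group, "day": day,
                        "rate_h_nmol_min": rate_h, "rate_o2_nmol_min": rate_o,
                        "fold_h": fold_h, "fold_o": fold_o,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = cfg.seed
    truth.attrs["contrast_truth"] = contrast_truth
    return wells, truth


# ---------------------------------------------------------------------------
# spatial fields


def gen_spatial_field(
    cfg: GeneratorConfig,
    cluster_scale: float = 0.0,
    effect: float = 2.0,
    field_um: float = 1000.0,
    n_clusters: int = 12,
    baseline_sigma: float = 0.3,
) -> tuple["pd.DataFrame", dict]:
    """Segmented-cell field with optional circular activation clusters.

    Centroids are uniform in a ``field_um`` square; ratios are lognormal
    baseline (median 1) multiplied by ``effect`` inside ``n_clusters``
    seeded discs of radius ``cluster_scale`` um.  ``cluster_scale = 0``
    yields an iid field.  Returns (tidy cell table, truth dict).
    """
    rng = cfg.rng()
    n = cfg.n_cells
    x = rng.uniform(0.0, field_um, n)
    y = rng.uniform(0.0, field_um, n)
    v = rng.lognormal(0.0, baseline_sigma, n)
    in_cluster = np.zeros(n, dtype=bool)
    centers = np.empty((0, 2))
    if cluster_scale > 0:
        centers = rng.uniform(0.0, field_um, (n_clusters, 2))
        for cx, cy in centers:
            in_cluster |= (x - cx) ** 2 + (y - cy) ** 2 <= cluster_scale**2
        v = np.where(in_cluster, v * effect, v)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "x_um": x,
            "y_um": y,
            "ratio": v,
        }
    )
    truth = {
        "seed": cfg.seed,
        "cluster_scale_um": cluster_scale,
        "effect": effect,
        "n_clusters": int(centers.shape[0]),
        "cluster_centers": centers.tolist(),
        "fraction_in_cluster": float(in_cluster.mean()),
    }
    df.attrs["seed"] = cfg.seed
    return df, truth
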