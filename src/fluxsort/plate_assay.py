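"""Dual-dye plate-reader assay: cumulative H+ production and O2 consumption
per well, initial rates per 10^5 cells, and the mono-exponential decay of
the sorted-subpopulation metabolic contrast.

Wells hold lightly buffered medium (2 mM HEPES / 2 mM MES) under a mineral
oil layer; medium pH is read from an HPTS ratio and dissolved O2 from
Stern-Volmer quenching of RuBPY luminescence.  Acid production is the path
integral of medium buffering capacity along the measured pH trajectory, not
an endpoint product, so it is invariant to re-sampling of the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ph_core import BufferSpec, InsufficientDataError, buffering_capacity

__all__ = [
    "WellTimecourse",
    "ContrastDecayFit",
    "stern_volmer_o2",
    "cumulative_h",
    "cumulative_o2",
    "initial_rate",
    "fit_contrast_decay",
    "contrast_at",
    "collapse_day",
    "O2_SAT_DEFAULT",
]

# Air-saturated aqueous medium at 37 C, nmol dissolved O2 per uL.
O2_SAT_DEFAULT = 0.2

GROUPS = (
    "p_hlac_high",
    "p_hlac_low",
    "il6r_high",
    "il6r_low",
    "control",
    "perturbed",
)


@dataclass
class WellTimecourse:
    """One well's medium-pH and dissolved-O2 time courses with metadata."""

    time_min: np.ndarray
    medium_ph: np.ndarray | None
    o2_percent: np.ndarray | None
    well_id: str
    group: str
    cells_per_well: float
    days_post_sort: float = 0.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"well {self.well_id}: time must be increasing")
        if self.cells_per_well <= 0:
            raise ValueError(f"well {self.well_id}: cells_per_well must be > 0")
        if self.medium_ph is not None:
            self.medium_ph = np.asarray(self.medium_ph, dtype=float)
            if self.medium_ph.size != self.time_min.size:
                raise ValueError("medium_ph length mismatch")
        if self.o2_percent is not None:
            self.o2_percent = np.asarray(self.o2_percent, dtype=float)
            if self.o2_percent.size != self.time_min.size:
                raise ValueError("o2_percent length mismatch")
            if np.any(self.o2_percent < 0) or np.any(self.o2_percent > 120):
                raise ValueError(f"well {self.well_id}: O2 outside [0, 120]%")


@dataclass(frozen=True)
class ContrastDecayFit:
    """Mono-exponential fit D(t) = d_inf + (d0 - d_inf) exp(-t / tau)."""

    tau: float                       # hours
    d0: float                        # contrast extrapolated to t = 0
    d_inf: float                     # asymptote
    metric: Literal["fold_ratio", "difference"]
    ci_tau: tuple[float, float]      # bootstrap CI, hours
    decaying: bool = True            # False when data show no decay
    n_boot: int = 0
    seed: int | None = None


def stern_volmer_o2(
    intensity: float | np.ndarray,
    i0: float,
    ksv: float,
    tolerance: float = 1e-6,
) -> float | np.ndarray:
    """Dissolved O2 (% of air saturation) from luminophore quenching.

    Inverts I0/I = 1 + ksv * O2, clipping to [0, 120]%.  ``i0`` is the
    unquenched (anoxic) intensity and ``ksv`` the Stern-Volmer constant per
    percent O2.
    """
    inten = np.asarray(intensity, dtype=float)
    if np.any(inten <= 0) or i0 <= 0:
        raise ValueError("intensities must be positive")
    if np.any(inten > i0 * (1.0 + tolerance)):
        raise ValueError("intensity exceeds unquenched I0: negative O2")
    o2 = (i0 / inten - 1.0) / ksv
    o2 = np.clip(o2, 0.0, 120.0)
    return float(o2) if np.isscalar(intensity) else o2


def cumulative_h(
    tc: WellTimecourse, buf: BufferSpec | None, volume_ul: float
) -> np.ndarray:
    """Cumulative H+ produced (nmol) along the medium-pH trajectory.

    H(t) = V * integral of beta_m(pH) (-dpH), evaluated with the midpoint
    rule on each sampling interval; non-decreasing whenever the pH trace is
    monotonically acidifying.
    """
    if buf is None:
        raise ValueError("cumulative_h requires the assay-medium BufferSpec")
    if tc.medium_ph is None:
        raise ValueError(f"well {tc.well_id}: no medium_ph trace")
    ph = tc.medium_ph
    mid = 0.5 * (ph[1:] + ph[:-1])
    beta_mid = buffering_capacity(mid, buf)
    increments = volume_ul * beta_mid * -(np.diff(ph))
    return np.concatenate(([0.0], np.cumsum(increments)))


def cumulative_o2(
    tc: WellTimecourse,
    volume_ul: float,
    o2_sat: float = O2_SAT_DEFAULT,
    k_leak: float = 0.0,
) -> np.ndarray:
    """Cumulative O2 consumed (nmol) from the dissolved-O2 trace.

    Closed-system depletion V*o2_sat*(O2(0)-O2(t))/100 plus an optional
    first-order correction for O2 leaking through the oil layer at rate
    k_leak (min^-1) proportional to the saturation deficit.
    """
    if tc.o2_percent is None:
        raise ValueError(f"well {tc.well_id}: no o2_percent trace")
    o2 = tc.o2_percent
    closed = volume_ul * o2_sat * (o2[0] - o2) / 100.0
    if k_leak == 0.0:
        return closed
    deficit = (100.0 - o2) / 100.0
    mid = 0.5 * (deficit[1:] + deficit[:-1])
    leak = np.concatenate(([0.0], np.cumsum(mid * np.diff(tc.time_min))))
    return closed + volume_ul * o2_sat * k_leak * leak


def initial_rate(
    time_min: np.ndarray,
    cumulative: np.ndarray,
    cells_per_well: float,
    window_min: float = 60.0,
) -> float:
    """Initial production/consumption rate, nmol min^-1 per 10^5 cells.

    OLS slope of the cumulative series over the first ``window_min`` minutes,
    normalised to a common seeding density of 10^5 cells.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(cumulative, dtype=float)
    mask = t <= t[0] + window_min
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points in the first {window_min:g} min"
        )
    slope = float(stats.linregress(t[mask], y[mask]).slope)
    return slope / (cells_per_well / 1e5)


def _mono_exp(t: np.ndarray, d_inf: float, d0: float, tau: float) -> np.ndarray:
    return d_inf + (d0 - d_inf) * np.exp(-t / tau)


def contrast_at(t_h: float | np.ndarray, d0: float, tau_h: float, d_inf: float = 1.0,
                anchor_h: float = 0.0) -> float | np.ndarray:
    """Mono-exponential contrast D(t) anchored at ``anchor_h`` where D = d0."""
    out = d_inf + (d0 - d_inf) * np.exp(-(np.asarray(t_h, float) - anchor_h) / tau_h)
    return float(out) if np.isscalar(t_h) else out


def collapse_day(
    fold_day1: float = 3.0,
    tau_h: float = 30.0,
    threshold: float = 1.25,
    d_inf: float = 1.0,
    max_day: int = 14,
) -> int:
    """First whole day post-sorting at which the analytic contrast model,
    anchored to the day-1 fold-difference, falls below the collapse
    threshold."""
    for day in range(2, max_day + 1):
        if contrast_at(24.0 * day, fold_day1, tau_h, d_inf, anchor_h=24.0) < threshold:
            return day
    raise ValueError(f"contrast never collapses below {threshold} by day {max_day}")


def fit_contrast_decay(
    times_h: Sequence[float],
    high_rates: Sequence[float] | np.ndarray,
    low_rates: Sequence[float] | np.ndarray,
    metric: Literal["fold_ratio", "difference"] = "fold_ratio",
    n_boot: int = 200,
    seed: int = 0,
) -> ContrastDecayFit:
    """Fit D(t) = d_inf + (d0 - d_inf) exp(-t/tau) to the high-vs-low
    metabolic contrast across days post-sorting.

    ``high_rates``/``low_rates`` may be per-time scalars or per-time arrays
    of replicate wells (averaged before forming the contrast).  The bootstrap
    CI on tau resamples residuals with replacement (seeded).  Non-decaying
    data return a fit flagged ``decaying=False`` rather than raising.
    """
    t = np.asarray(times_h, dtype=float)
    hi = np.array([np.mean(h) for h in high_rates], dtype=float)
    lo = np.array([np.mean(l) for l in low_rates], dtype=float)
    if t.size < 3 or hi.size != t.size or lo.size != t.size:
        raise InsufficientDataError("need >= 3 paired time points")
    if metric == "fold_ratio":
        d = hi / lo
        floor = 1.0
    elif metric == "difference":
        d = hi - lo
        floor = 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")

    def _fit(dvals: np.ndarray) -> tuple[float, float, float] | None:
        # asymptote bounded below at the metric floor: symmetric relaxation
        # of sorted subpopulations cannot cross parity
        d_inf0 = max(dvals.min(), floor)
        span = max(dvals[0] - d_inf0, 1e-6)
        # log-linear tau guess from first/last point
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = (dvals[-1] - d_inf0) / span
        tau0 = (t[-1] - t[0]) / max(-np.log(max(rel, 1e-3)), 1e-3)
        try:
            popt, _ = optimize.curve_fit(
                _mono_exp,
                t,
                dvals,
                p0=[d_inf0, dvals[0], tau0],
                bounds=([floor, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            return None
        return float(popt[2]), float(popt[1]), float(popt[0])

    decaying = d[-1] < d[0]
    res = _fit(d) if decaying else None
    if res is None:
        return ContrastDecayFit(
            tau=float("nan"),
            d0=float(d[0]),
            d_inf=float(d[-1]),
            metric=metric,
            ci_tau=(float("nan"), float("nan")),
            decaying=False,
            n_boot=0,
            seed=seed,
        )
    tau, d0, d_inf = res

    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = d - _mono_exp(t, d_inf, d0, tau)
        taus = []
        for _ in range(n_boot):
            d_b = _mono_exp(t, d_inf, d0, tau) + rng.choice(resid, size=t.size)
            r = _fit(d_b)
            if r is not None and np.isfinite(r[0]):
                taus.append(r[0])
        if taus:
            ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))
    return ContrastDecayFit(
        tau=tau,
        d0=d0,
        d_inf=d_inf,
        metric=metric,
        ci_tau=ci,
        decaying=True,
        n_boot=n_boot,
        seed=seed,
    )


def wells_to_frame(wells: Sequence[WellTimecourse]) -> pd.DataFrame:
    """Tidy CSV schema: well_id, group, days_post_sort, cells_per_well,
    time_min, medium_ph, o2_percent."""
    rows = []
    for w in wells:
        for i, tm in enumerate(w.time_min):
            rows.append(
                {
                    "well_id": w.well_id,
                    "group": w.group,
                    "days_post_sort": w.days_post_sort,
                    "cells_per_well": w.cells_per_well,
                    "time_min": tm,
                    "medium_ph": np.nan if w.medium_ph is None else w.medium_ph[i],
                    "o2_percent": np.nan if w.o2_percent is None else w.o2_percent[i],
                }
            )
    return pd.DataFrame(rows)


def frame_to_wells(df: pd.DataFrame) -> list[WellTimecourse]:
    """Parse the tidy well CSV schema back into WellTimecourse objects."""
    wells = []
    for well_id, g in df.groupby("well_id", sort=False):
        g = g.sort_values("time_min")
        ph = None if g["medium_ph"].isna().all() else g["medium_ph"].to_numpy()
        o2 = None if g["o2_percent"].isna().all() else g["o2_percent"].to_numpy()
        wells.append(
            WellTimecourse(
                time_min=g["time_min"].to_numpy(),
                medium_ph=ph,
                o2_percent=o2,
                well_id=str(well_id),
                group=str(g["group"].iloc[0]),
                cells_per_well=float(g["cells_per_well"].iloc[0]),
                days_post_sort=float(g["days_post_sort"].iloc[0]),
            )
        )
    return wells
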