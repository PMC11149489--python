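"""Mechanistic per-cell model of the IL-6R/STAT3/SOCS3 delayed-negative-
feedback circuit with a shared autocrine IL-6 pool.

Each cell carries four signalling states: surface receptor ``rcv`` (IL-6R),
active transcription factor ``s`` (pSTAT3), inhibitor transcript ``m``
(SOCS3 mRNA) and inhibitor protein ``c`` (SOCS3).  The feedback delay is
realised Goodwin-style through the intermediate mRNA species rather than an
explicit time-lag term.  Sign structure: pSTAT3 drives ligand secretion,
receptor synthesis and SOCS3 transcription (all positive arms); SOCS3
protein inhibits pSTAT3 production (the delayed negative arm) through a
Hill term 1/(1 + (c/K_C)^h).

    ds/dt   = k_act * rcv * L/(K_L + L) * 1/(1 + (c/K_C)^h) - k_deph * s
    dm/dt   = k_m * s - d_m * m
    dc/dt   = k_c * m - d_c * c
    drcv/dt = r0 + r1 * s - d_r * rcv
    dL/dt   = mean_cells(l0 + l1 * s) - d_l * L        (shared ligand)

Heterogeneity enters through (i) static lognormal per-cell dispersion of
k_act and r0 and (ii) a per-cell Ornstein-Uhlenbeck process eta(t) that
multiplies k_act as exp(eta).  Metabolic readouts are affine in pSTAT3:
fermentative rate F = f_min + f_gain*s, respiration O = o_min + o_gain*s,
and the sorting readout P_HLac = p_min + p_gain*F (flux-balance link:
high-fermenting cells need matching lactic-acid export capacity).

The ligand operates in the saturated regime by default (L >> K_L), matching
the observation that exogenous IL-6 supplementation adds nothing.

Default OU parameters are set by the calibration routine
(``analysis/03_calibrate_model.py``) so that the stationary top-vs-bottom
decile ratio of F is ~10 and the sorted-contrast mixing time is ~30 h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ph_core import INTRACELLULAR_BETA

__all__ = [
    "FeedbackParams",
    "MetabolicCoupling",
    "PopulationState",
    "IntegrationError",
    "init_population",
    "step_population",
    "simulate",
    "fermentative_rate",
    "respiratory_rate",
    "p_hlac_readout",
    "apply_perturbation",
    "insilico_sort",
    "relaxation_experiment",
    "chc_snapshot",
    "socs3_ko_fixed_point",
]


class IntegrationError(RuntimeError):
    """Fixed-step integration produced NaN or unbounded states."""


@dataclass(frozen=True)
class FeedbackParams:
    """Rate constants of the feedback circuit (all per minute unless noted).

    The defaults place pSTAT3 turnover on a ~10 min scale, the SOCS3
    transcript/protein delay stages on 2-4 h scales, and the receptor on an
    ~8 h scale.  The OU noise amplitude and reversion rate are set by the
    calibration routine (``analysis/03_calibrate_model.py``) to the two
    population targets: a stationary top-vs-bottom decile ratio of the
    fermentative readout of ~10, and a sorted-contrast mixing time of
    ~30 h (the feedback circuit adds fast-decaying variance on top of the
    slow OU component, so the OU reversion time, 42 h, is slower than the
    realised mixing time).
    """

    #: mixing-time calibration target for the sorted-contrast decay, hours
    MIXING_TIME_TARGET_H = 30.0

    k_act: float = 0.0292      # pSTAT3 production gain per receptor-occupancy
    k_deph: float = 0.1        # pSTAT3 dephosphorylation (~10 min)
    k_m: float = 0.005         # SOCS3 mRNA induction per pSTAT3
    d_m: float = 1.0 / 120.0   # mRNA decay (2 h)
    k_c: float = 0.01          # SOCS3 translation
    d_c: float = 1.0 / 240.0   # SOCS3 protein decay (4 h)
    K_C: float = 2.20          # SOCS3 inhibition constant (~30% inhibition at baseline)
    h: float = 2.0             # Hill coefficient of SOCS3 inhibition
    r0: float = 0.01           # basal receptor synthesis
    r1: float = 3.0e-5         # pSTAT3-driven receptor synthesis (weak positive arm)
    d_r: float = 1.0 / 500.0   # receptor decay (~8 h)
    l0: float = 0.001          # basal ligand secretion (per cell, mean-field)
    l1: float = 0.001          # pSTAT3-driven ligand secretion
    d_l: float = 0.01          # ligand clearance
    K_L: float = 0.005         # ligand half-saturation (saturated regime)
    l_ext: float = 0.0         # exogenous ligand source (IL-6 supplement)
    cv_params: float = 0.05    # lognormal sd of static per-cell k_act, r0
    sigma_noise: float = 0.0296  # OU diffusion on log k_act (stationary sd ~1.05)
    theta_noise: float = 3.968e-4  # OU reversion rate (1/theta ~ 42 h)

    def __post_init__(self) -> None:
        for name in (
            "k_act", "k_deph", "k_m", "d_m", "k_c", "d_c", "K_C", "r0", "r1",
            "d_r", "l0", "l1", "d_l", "K_L", "l_ext", "cv_params",
            "sigma_noise", "theta_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.h < 1:
            raise ValueError("Hill coefficient h must be >= 1")

    @property
    def ou_stationary_sd(self) -> float:
        """Stationary sd of the OU log-noise, sigma / sqrt(2 theta)."""
        if self.theta_noise == 0:
            return 0.0
        return self.sigma_noise / np.sqrt(2.0 * self.theta_noise)

    @property
    def max_rate(self) -> float:
        return max(self.k_deph, self.d_m, self.d_c, self.d_r, self.d_l,
                   self.theta_noise)


@dataclass(frozen=True)
class MetabolicCoupling:
    """Affine coupling of pSTAT3 to the metabolic readouts.

    F and O are in mM min^-1 of cell volume; P_HLac in min^-1.  Fermentation
    and respiration share the pSTAT3 driver (joint activation of
    energy-harnessing metabolism, not a switchover) but have independent
    gains.  growth_gain converts fermentative flux into relative biomass
    growth (min^-1 per mM min^-1).
    """

    f_min: float = 0.01
    f_gain: float = 0.2
    o_min: float = 0.05
    o_gain: float = 0.15
    p_min: float = 5.0
    p_gain: float = 350.0
    growth_gain: float = 1.6e-3

    def __post_init__(self) -> None:
        for name in ("f_min", "f_gain", "o_min", "o_gain", "p_min", "p_gain",
                     "growth_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PopulationState:
    """Vectorised per-cell states plus the shared ligand pool.

    ``k_act_i`` and ``r0_i`` are the frozen per-cell (static lognormal)
    parameter draws; ``noise`` is the per-cell OU log-modulation of k_act.
    """

    rcv: np.ndarray
    s: np.ndarray
    m: np.ndarray
    c: np.ndarray
    noise: np.ndarray
    biomass: np.ndarray
    k_act_i: np.ndarray
    r0_i: np.ndarray
    ligand: float = 0.1
    t_h: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.s.size

    def copy(self) -> "PopulationState":
        return PopulationState(
            rcv=self.rcv.copy(), s=self.s.copy(), m=self.m.copy(),
            c=self.c.copy(), noise=self.noise.copy(),
            biomass=self.biomass.copy(), k_act_i=self.k_act_i.copy(),
            r0_i=self.r0_i.copy(), ligand=self.ligand, t_h=self.t_h,
        )

    def subset(self, idx: np.ndarray) -> "PopulationState":
        """Independent subpopulation with its own (inherited) ligand pool."""
        return PopulationState(
            rcv=self.rcv[idx].copy(), s=self.s[idx].copy(),
            m=self.m[idx].copy(), c=self.c[idx].copy(),
            noise=self.noise[idx].copy(), biomass=self.biomass[idx].copy(),
            k_act_i=self.k_act_i[idx].copy(), r0_i=self.r0_i[idx].copy(),
            ligand=self.ligand, t_h=self.t_h,
        )


def fermentative_rate(state: PopulationState, coupling: MetabolicCoupling) -> np.ndarray:
    return coupling.f_min + coupling.f_gain * state.s


def respiratory_rate(state: PopulationState, coupling: MetabolicCoupling) -> np.ndarray:
    return coupling.o_min + coupling.o_gain * state.s


def p_hlac_readout(state: PopulationState, coupling: MetabolicCoupling) -> np.ndarray:
    return coupling.p_min + coupling.p_gain * fermentative_rate(state, coupling)


def init_population(
    n_cells: int,
    params: FeedbackParams,
    rng: np.random.Generator,
    equilibrate: bool = True,
) -> PopulationState:
    """Draw a population with per-cell parameter dispersion and OU noise at
    its stationary distribution, with signalling states at their per-cell
    quasi-steady values (damped fixed-point iteration)."""
    cv = params.cv_params
    if cv > 0:
        sig = np.sqrt(np.log(1.0 + cv**2))
        k_act_i = params.k_act * rng.lognormal(-0.5 * sig**2, sig, n_cells)
        r0_i = params.r0 * rng.lognormal(-0.5 * sig**2, sig, n_cells)
    else:
        k_act_i = np.full(n_cells, params.k_act)
        r0_i = np.full(n_cells, params.r0)
    sd = params.ou_stationary_sd
    noise = rng.normal(0.0, sd, n_cells) if sd > 0 else np.zeros(n_cells)

    s = np.full(n_cells, 1.0)
    ligand = max((params.l0 + params.l1) / max(params.d_l, 1e-12), params.K_L * 10)
    m = np.zeros(n_cells)
    c = np.zeros(n_cells)
    rcv = np.zeros(n_cells)
    if equilibrate:
        k_eff = k_act_i * np.exp(noise)
        for _ in range(200):
            sat = ligand / (params.K_L + ligand)
            m = params.k_m * s / max(params.d_m, 1e-12)
            c = params.k_c * m / max(params.d_c, 1e-12)
            rcv = (r0_i + params.r1 * s) / max(params.d_r, 1e-12)
            inh = 1.0 / (1.0 + (c / params.K_C) ** params.h)
            s_new = k_eff * rcv * sat * inh / max(params.k_deph, 1e-12)
            s = 0.7 * s + 0.3 * s_new
            ligand = (params.l0 + params.l1 * float(np.mean(s)) + params.l_ext) / max(
                params.d_l, 1e-12
            )
    return PopulationState(
        rcv=rcv, s=s, m=m, c=c, noise=noise,
        biomass=np.ones(n_cells), k_act_i=k_act_i, r0_i=r0_i,
        ligand=float(ligand), t_h=0.0,
    )


def step_population(
    state: PopulationState,
    params: FeedbackParams,
    coupling: MetabolicCoupling,
    dt: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population one explicit-Euler step of ``dt`` minutes.

    Mutates and returns ``state``.  All states are clipped at zero; the step
    size must satisfy dt <= 0.1 / max-rate for stability.
    """
    if dt > 0.1 / params.max_rate:
        raise ValueError(
            f"dt={dt} min violates the stability guard 0.1/max_rate="
            f"{0.1 / params.max_rate:.3g} min"
        )
    # OU noise on log k_act (exact discretisation of the OU process)
    if params.sigma_noise > 0 and params.theta_noise > 0:
        a = np.exp(-params.theta_noise * dt)
        sd = params.ou_stationary_sd * np.sqrt(1.0 - a * a)
        state.noise = a * state.noise + sd * rng.standard_normal(state.n_cells)
    k_eff = state.k_act_i * np.exp(state.noise)

    L = state.ligand
    sat = L / (params.K_L + L)
    inh = 1.0 / (1.0 + (state.c / params.K_C) ** params.h)
    ds = k_eff * state.rcv * sat * inh - params.k_deph * state.s
    dm = params.k_m * state.s - params.d_m * state.m
    dc = params.k_c * state.m - params.d_c * state.c
    drcv = state.r0_i + params.r1 * state.s - params.d_r * state.rcv
    dL = float(np.mean(params.l0 + params.l1 * state.s)) + params.l_ext \
        - params.d_l * L

    state.s = np.maximum(state.s + dt * ds, 0.0)
    state.m = np.maximum(state.m + dt * dm, 0.0)
    state.c = np.maximum(state.c + dt * dc, 0.0)
    state.rcv = np.maximum(state.rcv + dt * drcv, 0.0)
    state.ligand = max(L + dt * dL, 0.0)
    F = fermentative_rate(state, coupling)
    state.biomass = state.biomass * (1.0 + dt * coupling.growth_gain * F)
    state.t_h += dt / 60.0

    if not np.isfinite(state.s).all() or not np.isfinite(state.ligand):
        raise IntegrationError(
            "non-finite state encountered; check rate constants against the "
            f"step size dt={dt} min"
        )
    return state


def simulate(
    state: PopulationState,
    params: FeedbackParams,
    coupling: MetabolicCoupling,
    duration_min: float,
    dt: float,
    rng: np.random.Generator,
    record_every_min: float | None = None,
) -> pd.DataFrame | None:
    """Run the population forward ``duration_min`` minutes (in place).

    With ``record_every_min`` set, returns a tidy frame of population
    summaries (t_h, mean/sd of s, c, rcv, F, O, p_hlac, ligand).
    """
    n_steps = int(round(duration_min / dt))
    rec_stride = None if record_every_min is None else max(
        1, int(round(record_every_min / dt))
    )
    records = []
    for i in range(n_steps):
        step_population(state, params, coupling, dt, rng)
        if rec_stride is not None and (i + 1) % rec_stride == 0:
            F = fermentative_rate(state, coupling)
            records.append(
                {
                    "t_h": state.t_h,
                    "s_mean": float(np.mean(state.s)),
                    "s_sd": float(np.std(state.s)),
                    "c_mean": float(np.mean(state.c)),
                    "rcv_mean": float(np.mean(state.rcv)),
                    "F_mean": float(np.mean(F)),
                    "F_sd": float(np.std(F)),
                    "O_mean": float(np.mean(respiratory_rate(state, coupling))),
                    "p_hlac_mean": float(np.mean(p_hlac_readout(state, coupling))),
                    "ligand": state.ligand,
                }
            )
    if rec_stride is None:
        return None
    return pd.DataFrame(records)


PerturbationKind = Literal[
    "il6r_kd", "stat3_kd", "socs3_kd", "socs3_ko", "napabucasin", "il6_supplement"
]


def apply_perturbation(
    params: FeedbackParams,
    kind: PerturbationKind,
    strength: float,
    il6_dose: float = 1.0,
) -> FeedbackParams:
    """Return parameters under a genetic or pharmacological perturbation.

    * ``il6r_kd``    — receptor knockdown: scales r0 and r1 by (1-strength)
    * ``stat3_kd``   — STAT3 knockdown: scales k_act
    * ``socs3_kd``   — SOCS3 knockdown: scales k_m
    * ``socs3_ko``   — SOCS3 knockout (strength forced to 1): k_m = 0
    * ``napabucasin``— acute STAT3 inhibition: scales k_act
    * ``il6_supplement`` — adds ``strength * il6_dose`` to the ligand source
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    f = 1.0 - strength
    if kind == "il6r_kd":
        return replace(params, r0=params.r0 * f, r1=params.r1 * f)
    if kind in ("stat3_kd", "napabucasin"):
        return replace(params, k_act=params.k_act * f)
    if kind == "socs3_kd":
        return replace(params, k_m=params.k_m * f)
    if kind == "socs3_ko":
        return replace(params, k_m=0.0)
    if kind == "il6_supplement":
        return replace(params, l_ext=params.l_ext + strength * il6_dose)
    raise ValueError(f"unknown perturbation kind {kind!r}")


def insilico_sort(
    state: PopulationState,
    coupling: MetabolicCoupling,
    readout: Literal["p_hlac", "il6r"] = "p_hlac",
    top_frac: float = 0.1,
    bottom_frac: float = 0.1,
) -> tuple[PopulationState, PopulationState]:
    """FACS-like deterministic gate on the instantaneous readout.

    Returns (high, low) subpopulations holding the top/bottom quantiles,
    each with its own ligand pool (sorted cells go to separate wells).
    Ties are broken by cell index (stable mergesort).
    """
    if not (0.0 < top_frac <= 0.5 and 0.0 < bottom_frac <= 0.5):
        raise ValueError("sort fractions must lie in (0, 0.5]")
    n = state.n_cells
    if n < 50:
        raise ValueError(f"population of {n} cells too small to sort (need >= 50)")
    if readout == "p_hlac":
        values = p_hlac_readout(state, coupling)
    elif readout == "il6r":
        values = state.rcv
    else:
        raise ValueError(f"unknown sort readout {readout!r}")
    order = np.argsort(values, kind="stable")
    n_bottom = max(1, int(round(bottom_frac * n)))
    n_top = max(1, int(round(top_frac * n)))
    low_idx = np.sort(order[:n_bottom])
    high_idx = np.sort(order[n - n_top:])
    return state.subset(high_idx), state.subset(low_idx)


def socs3_ko_fixed_point(params: FeedbackParams) -> float:
    """pSTAT3 fixed point of the deterministic single-cell system with the
    SOCS3 arm removed (k_m = 0), by root finding on the reduced system."""
    from scipy import optimize

    p = replace(params, k_m=0.0)

    def _resid(s: float) -> float:
        ligand = (p.l0 + p.l1 * s + p.l_ext) / max(p.d_l, 1e-12)
        sat = ligand / (p.K_L + ligand)
        rcv = (p.r0 + p.r1 * s) / max(p.d_r, 1e-12)
        return p.k_act * rcv * sat - p.k_deph * s

    return float(optimize.brentq(_resid, 1e-9, 1e6))


def relaxation_experiment(
    params: FeedbackParams,
    coupling: MetabolicCoupling,
    sample_days: Sequence[float],
    n_cells: int = 2000,
    seed: int = 0,
    sort_readout: Literal["p_hlac", "il6r"] = "p_hlac",
    top_frac: float = 0.1,
    bottom_frac: float = 0.1,
    burn_in_h: float = 60.0,
    dt: float = 0.5,
    drift_tol_per_day: float = 0.02,
) -> pd.DataFrame:
    """In-silico sort-and-relax experiment.

    Equilibrates a parent population (stationary-initialised plus
    ``burn_in_h`` hours of burn-in, with a drift check), sorts the top and
    bottom quantiles of the chosen readout, then cultures the two
    subpopulations in separate wells (independent ligand pools), recording
    the fold contrast in mean fermentative and respiratory rate at each
    sampled day.  Columns: day, fold_f, fold_o, f_high, f_low, drift_flag.
    """
    rng = np.random.default_rng(seed)
    parent = init_population(n_cells, params, rng)
    # burn-in with drift monitoring over the final two half-windows
    half = burn_in_h * 60.0 / 2.0
    simulate(parent, params, coupling, half, dt, rng)
    f_mid = float(np.mean(fermentative_rate(parent, coupling)))
    simulate(parent, params, coupling, half, dt, rng)
    f_end = float(np.mean(fermentative_rate(parent, coupling)))
    drift_per_day = abs(f_end - f_mid) / max(f_mid, 1e-12) / (half / 60.0 / 24.0)
    drift_flag = drift_per_day > drift_tol_per_day

    high, low = insilico_sort(parent, coupling, sort_readout, top_frac, bottom_frac)
    rng_high = np.random.default_rng(rng.integers(2**31))
    rng_low = np.random.default_rng(rng.integers(2**31))

    rows = []
    t_sorted = 0.0
    for day in sorted(sample_days):
        advance = day * 24.0 * 60.0 - t_sorted
        if advance > 0:
            simulate(high, params, coupling, advance, dt, rng_high)
            simulate(low, params, coupling, advance, dt, rng_low)
            t_sorted = day * 24.0 * 60.0
        f_hi = float(np.mean(fermentative_rate(high, coupling)))
        f_lo = float(np.mean(fermentative_rate(low, coupling)))
        o_hi = float(np.mean(respiratory_rate(high, coupling)))
        o_lo = float(np.mean(respiratory_rate(low, coupling)))
        rows.append(
            {
                "day": day,
                "fold_f": f_hi / f_lo,
                "fold_o": o_hi / o_lo,
                "f_high": f_hi,
                "f_low": f_lo,
                "o_high": o_hi,
                "o_low": o_lo,
                "drift_flag": drift_flag,
            }
        )
    return pd.DataFrame(rows)


def chc_snapshot(
    state: PopulationState,
    coupling: MetabolicCoupling,
    duration_min: float = 3.0,
    beta: float = INTRACELLULAR_BETA,
    ph_baseline: float = 7.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell pHi snapshot after ``duration_min`` of MCT blockade.

    Closed-cell acid accumulation: delta pHi = -F_i * duration / beta.
    Returns (pre, post) pHi samples suitable for :func:`ph_core.chc_shift`.
    """
    F = fermentative_rate(state, coupling)
    pre = np.full(state.n_cells, ph_baseline)
    post = ph_baseline - F * duration_min / beta
    return pre, post
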