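"""Biophysical conversions between dye ratios, intracellular pH, acid flux,
and apparent lactic-acid permeability.

The single-cell assays work in three steps.  A ratiometric pH dye (cSNARF1)
reports intracellular pH (pHi) through a sigmoidal calibration curve.  The
rate of pHi change during a protocol manoeuvre, multiplied by the cytoplasmic
buffering capacity beta (mM per pH unit), gives an acid flux J in
mM min^-1.  Two protocols are supported:

* ``chc_block`` — abrupt monocarboxylate-transporter (MCT) blockade with CHC
  traps lactic acid inside the cell, so the acidification rate measures the
  fermentative (glycolytic lactic-acid production) rate.
* ``lactate_washout`` — after equilibration with extracellular lactate, a
  switch to lactate-free superfusate drives lactic-acid efflux; the
  alkalinization rate, normalised to the undissociated-acid gradient, gives
  the apparent membrane permeability to lactic acid (P_HLac, min^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "PhTimecourse",
    "BufferSpec",
    "LactateContext",
    "FluxResult",
    "PermeabilityResult",
    "ChcShiftResult",
    "ratio_to_ph",
    "ph_to_ratio",
    "buffering_capacity",
    "hlac_concentration",
    "estimate_rate",
    "fermentative_flux",
    "permeability_from_washout",
    "chc_shift",
    "OutOfRangeError",
    "InsufficientDataError",
    "ProtocolError",
    "DegenerateGradientError",
    "ZeroBufferingError",
    "PKA_LACTIC_ACID",
    "INTRACELLULAR_BETA",
    "DEFAULT_RATE_WINDOW",
]

# Literature pKa of lactic acid at 25 C; configurable per LactateContext.
PKA_LACTIC_ACID = 3.86

# Constant intracellular (intrinsic) buffering default, mM per pH unit.
INTRACELLULAR_BETA = 20.0

# Rate window relative to the solution switch: start 5 s after the switch to
# skip the ~25 ms switch transient and local mixing, fit the next 30 s.
DEFAULT_RATE_WINDOW = (5.0 / 60.0, 35.0 / 60.0)


class OutOfRangeError(ValueError):
    """A ratio sample lies outside the open calibration interval."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested estimate."""


class ProtocolError(ValueError):
    """Operation applied to a time course with the wrong protocol tag."""


class DegenerateGradientError(ValueError):
    """Undissociated-acid gradient too small to normalise a flux."""


class ZeroBufferingError(ValueError):
    """Buffer spec with no components and zero intrinsic buffering."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Sigmoidal mapping between a fluorescence ratio and pH.

    ``direction`` gives the sense of the ratio-vs-pH relation:
    ``"decreasing"`` means the ratio falls as pH rises (pH = pKa +
    log10((ratio_max - R)/(R - ratio_min))); ``"increasing"`` flips the sign
    of the log term.
    """

    ratio_min: float
    ratio_max: float
    pka_dye: float
    direction: Literal["increasing", "decreasing"] = "decreasing"

    def __post_init__(self) -> None:
        if not self.ratio_min < self.ratio_max:
            raise ValueError("ratio_min must be strictly below ratio_max")
        if not 4.0 <= self.pka_dye <= 10.0:
            raise ValueError(f"pKa_dye {self.pka_dye} outside [4, 10]")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def _sign(self) -> float:
        return 1.0 if self.direction == "decreasing" else -1.0


@dataclass
class PhTimecourse:
    """One cell's dye-ratio or calibrated-pHi samples over time.

    ``time_min`` is in minutes with the solution switch at ``t_switch``
    (0 by convention).  ``signal_kind`` records whether ``value`` holds raw
    ratios or calibrated pHi.
    """

    time_min: np.ndarray
    value: np.ndarray
    protocol: Literal["chc_block", "lactate_washout", "chc_shift_snapshot"]
    cell_id: str = "cell"
    signal_kind: Literal["ratio", "ph"] = "ph"
    t_switch: float = 0.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_min.size < 4:
            raise InsufficientDataError(
                f"cell {self.cell_id}: need >= 4 samples, got {self.time_min.size}"
            )
        if self.time_min.size != self.value.size:
            raise ValueError("time and value arrays differ in length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"cell {self.cell_id}: time must be strictly increasing")
        if self.signal_kind == "ph" and (
            np.any(self.value < 5.5) or np.any(self.value > 8.5)
        ):
            raise ValueError(f"cell {self.cell_id}: calibrated pHi outside [5.5, 8.5]")

    def calibrated(self, cal: CalibrationCurve) -> "PhTimecourse":
        """Return a pH-unit copy, converting raw ratios if necessary."""
        if self.signal_kind == "ph":
            return self
        ph = ratio_to_ph(self.value, cal, label=self.cell_id)
        return PhTimecourse(
            self.time_min, ph, self.protocol, self.cell_id, "ph", self.t_switch
        )


@dataclass(frozen=True)
class BufferSpec:
    """Extracellular or intracellular buffering: mobile components plus a
    constant intrinsic offset ``beta0`` (mM per pH unit)."""

    components: tuple[tuple[float, float], ...] = ()  # (total mM, pKa)
    beta0: float = 0.0

    def __post_init__(self) -> None:
        for conc, pka in self.components:
            if conc < 0:
                raise ValueError(f"negative buffer concentration {conc}")
            if not 3.0 <= pka <= 11.0:
                raise ValueError(f"buffer pKa {pka} outside [3, 11]")
        if self.beta0 < 0:
            raise ValueError("beta0 must be >= 0")
        if not self.components and self.beta0 == 0.0:
            raise ZeroBufferingError(
                "buffer spec has no components and beta0=0; pH excursions "
                "would be unbounded"
            )

    @classmethod
    def assay_medium(cls) -> "BufferSpec":
        """The lightly buffered plate-assay medium: 2 mM HEPES + 2 mM MES."""
        return cls(components=((2.0, 7.5), (2.0, 6.15)))

    @classmethod
    def intracellular(cls, beta0: float = INTRACELLULAR_BETA) -> "BufferSpec":
        """Constant intrinsic cytoplasmic buffering (default 20 mM/pH)."""
        return cls(components=(), beta0=beta0)


@dataclass(frozen=True)
class LactateContext:
    """Total lactate on both membrane sides plus the acid dissociation pKa."""

    lac_out: float
    lac_in: float
    ph_out: float = 7.4
    pka_lac: float = PKA_LACTIC_ACID

    def __post_init__(self) -> None:
        if self.lac_out < 0 or self.lac_in < 0:
            raise ValueError("total lactate concentrations must be >= 0")


@dataclass(frozen=True)
class FluxResult:
    """Acid-equivalent flux J = -beta * dpHi/dt from a CHC-block window."""

    flux: float                     # mM min^-1, positive = fermentative
    rate_dph: float                 # pH min^-1
    window: tuple[float, float]     # minutes
    r_squared: float
    alkalinizing: bool = False      # warning flag: unexpected sign under CHC


@dataclass(frozen=True)
class PermeabilityResult:
    """Apparent lactic-acid permeability from a washout transient."""

    p_hlac: float                   # min^-1 (flux per unit HLac gradient)
    flux: float                     # mM min^-1 acid efflux
    driving_force: float            # mM undissociated lactic acid
    rate_dph: float = float("nan")
    r_squared: float = float("nan")

    def to_cm_per_s(self, surface_to_volume_per_cm: float) -> float:
        """Convert to cm s^-1 given a surface-to-volume ratio (cm^-1)."""
        return self.p_hlac / 60.0 / surface_to_volume_per_cm


@dataclass(frozen=True)
class ChcShiftResult:
    """Distribution shift of pHi snapshots before vs after MCT blockade."""

    median_shift: float
    ks_distance: float
    ks_pvalue: float
    left_shift_fraction: float
    major_acid_shift: bool
    threshold: float


def ratio_to_ph(
    ratio: float | np.ndarray, cal: CalibrationCurve, label: str = "sample"
) -> float | np.ndarray:
    """Convert a fluorescence ratio to pH through the calibration sigmoid."""
    r = np.asarray(ratio, dtype=float)
    bad = (r <= cal.ratio_min) | (r >= cal.ratio_max)
    if np.any(bad):
        offending = np.atleast_1d(r)[np.atleast_1d(bad)][0]
        raise OutOfRangeError(
            f"{label}: ratio {offending} outside open calibration interval "
            f"({cal.ratio_min}, {cal.ratio_max})"
        )
    ph = cal.pka_dye + cal._sign * np.log10((cal.ratio_max - r) / (r - cal.ratio_min))
    return float(ph) if np.isscalar(ratio) else ph


def ph_to_ratio(
    ph: float | np.ndarray, cal: CalibrationCurve
) -> float | np.ndarray:
    """Inverse calibration: pH back to fluorescence ratio."""
    p = np.asarray(ph, dtype=float)
    x = np.power(10.0, cal._sign * (p - cal.pka_dye))
    r = (cal.ratio_max + cal.ratio_min * x) / (1.0 + x)
    return float(r) if np.isscalar(ph) else r


def buffering_capacity(
    ph: float | np.ndarray, buf: BufferSpec
) -> float | np.ndarray:
    """Closed-form (Van Slyke) buffering capacity, mM per pH unit.

    beta(pH) = beta0 + ln(10) * sum_i C_i * Ka_i [H+] / (Ka_i + [H+])^2.
    """
    p = np.asarray(ph, dtype=float)
    if np.any(p < 3.0) or np.any(p > 11.0):
        raise ValueError("pH outside supported range [3, 11]")
    h = np.power(10.0, -p)
    beta = np.full_like(p, buf.beta0, dtype=float)
    for conc, pka in buf.components:
        ka = 10.0 ** (-pka)
        beta = beta + math.log(10.0) * conc * ka * h / (ka + h) ** 2
    return float(beta) if np.isscalar(ph) else beta


def hlac_concentration(
    ctx: LactateContext, side: Literal["in", "out"], ph_side: float
) -> float:
    """Undissociated lactic-acid concentration (mM) on one membrane side,
    by Henderson-Hasselbalch speciation of the total lactate pool."""
    total = ctx.lac_in if side == "in" else ctx.lac_out
    return total / (1.0 + 10.0 ** (ph_side - ctx.pka_lac))


def _theil_sen(t: np.ndarray, y: np.ndarray) -> float:
    slope, _, _, _ = stats.theilslopes(y, t)
    return float(slope)


def estimate_rate(
    tc: PhTimecourse,
    window: tuple[float, float] | None = None,
    method: Literal["ols_line", "robust_line"] = "robust_line",
    cal: CalibrationCurve | None = None,
) -> tuple[float, float]:
    """Slope of calibrated pHi vs time over a window -> (pH/min, r_squared).

    ``robust_line`` uses the Theil-Sen median-of-slopes estimator, which
    tolerates spike contamination in single-cell traces; ``ols_line`` is the
    ordinary least-squares fit used for averaged traces.  For a constant
    trace r_squared is 0 by convention.
    """
    if tc.signal_kind == "ratio":
        if cal is None:
            raise ValueError("raw-ratio time course needs a CalibrationCurve")
        tc = tc.calibrated(cal)
    if window is None:
        window = (tc.t_switch + DEFAULT_RATE_WINDOW[0], tc.t_switch + DEFAULT_RATE_WINDOW[1])
    t0, t1 = window
    mask = (tc.time_min >= t0) & (tc.time_min <= t1)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"cell {tc.cell_id}: only {int(mask.sum())} samples in window "
            f"({t0:g}, {t1:g}) min; need >= 3"
        )
    t, y = tc.time_min[mask], tc.value[mask]
    if method == "ols_line":
        res = stats.linregress(t, y)
        slope = float(res.slope)
        r2 = 0.0 if np.allclose(y, y[0]) else float(res.rvalue**2)
    elif method == "robust_line":
        slope = _theil_sen(t, y)
        pred = np.median(y - slope * t) + slope * t
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot)
    else:
        raise ValueError(f"unknown method {method!r}")
    return slope, r2


def fermentative_flux(
    rate_dph: float,
    beta: float,
    window: tuple[float, float] = DEFAULT_RATE_WINDOW,
    r_squared: float = float("nan"),
) -> FluxResult:
    """Fermentative acid flux from a CHC-block acidification rate.

    J = -beta * dpHi/dt: MCT blockade traps lactic acid, so acidification
    (negative slope) means positive fermentative flux.  An alkalinizing
    slope is biologically unexpected under CHC and is flagged.
    """
    if beta <= 0:
        raise ValueError("buffering capacity must be positive")
    flux = -beta * rate_dph
    return FluxResult(
        flux=flux,
        rate_dph=rate_dph,
        window=window,
        r_squared=r_squared,
        alkalinizing=flux < 0,
    )


def permeability_from_washout(
    tc: PhTimecourse,
    ctx: LactateContext,
    beta: float,
    window: tuple[float, float] | None = None,
    method: Literal["ols_line", "robust_line"] = "robust_line",
    formalism: Literal["undissociated", "ion_product"] = "undissociated",
    cal: CalibrationCurve | None = None,
    gradient_tol: float = 1e-9,
) -> PermeabilityResult:
    """Apparent lactic-acid permeability from a washout transient.

    At washout onset (extracellular lactate 0) the efflux J = beta * dpHi/dt
    (alkalinization = acid leaving).  The driving force is the
    undissociated-acid gradient [HLac]_in - [HLac]_out evaluated at the
    window-start pHi; P_HLac = J / driving_force.  The ``ion_product``
    formalism instead normalises by the [H+][Lac-] product difference
    (the MCT thermodynamic driving force); both are proportional at fixed
    extracellular pH.
    """
    if tc.protocol != "lactate_washout":
        raise ProtocolError(
            f"cell {tc.cell_id}: permeability needs a lactate_washout trace, "
            f"got {tc.protocol!r}"
        )
    if ctx.lac_out != 0:
        raise ProtocolError("washout requires zero extracellular lactate")
    if tc.signal_kind == "ratio":
        tc = tc.calibrated(cal) if cal else tc
    if window is None:
        window = (tc.t_switch + DEFAULT_RATE_WINDOW[0], tc.t_switch + DEFAULT_RATE_WINDOW[1])
    slope, r2 = estimate_rate(tc, window=window, method=method, cal=cal)
    flux = beta * slope  # mM/min acid efflux, positive for alkalinization

    # pHi at window start from the fitted line (robust to sample noise)
    mask = (tc.time_min >= window[0]) & (tc.time_min <= window[1])
    t, y = tc.time_min[mask], tc.value[mask]
    ph_start = float(np.median(y - slope * t) + slope * window[0])

    if formalism == "undissociated":
        driving = hlac_concentration(ctx, "in", ph_start) - hlac_concentration(
            ctx, "out", ctx.ph_out
        )
    elif formalism == "ion_product":
        ka = 10.0 ** (-ctx.pka_lac)
        h_in, h_out = 10.0 ** (-ph_start), 10.0 ** (-ctx.ph_out)
        lac_ion_in = ctx.lac_in * ka / (ka + h_in)
        lac_ion_out = ctx.lac_out * ka / (ka + h_out)
        driving = h_in * lac_ion_in - h_out * lac_ion_out
    else:
        raise ValueError(f"unknown formalism {formalism!r}")

    if flux == 0.0:
        return PermeabilityResult(0.0, 0.0, driving, slope, r2)
    if abs(driving) < gradient_tol:
        raise DegenerateGradientError(
            f"cell {tc.cell_id}: driving force {driving:g} mM below tolerance"
        )
    return PermeabilityResult(flux / driving, flux, driving, slope, r2)


def chc_shift(
    pre_phi: Sequence[float] | np.ndarray,
    post_phi: Sequence[float] | np.ndarray,
    major_shift_threshold: float = -0.1,
    min_cells: int = 30,
) -> ChcShiftResult:
    """Shift of the population pHi distribution evoked by 3 min of MCT
    blockade: median shift, full-distribution KS distance, and the fraction
    of matched quantiles shifted acid-ward.  A median shift at or below the
    threshold (default -0.1 pH) is flagged as a major acid shift."""
    pre = np.asarray(pre_phi, dtype=float)
    post = np.asarray(post_phi, dtype=float)
    if pre.size < min_cells or post.size < min_cells:
        raise InsufficientDataError(
            f"need >= {min_cells} cells per sample, got {pre.size} and {post.size}"
        )
    median_shift = float(np.median(post) - np.median(pre))
    ks = stats.ks_2samp(pre, post)
    qs = np.linspace(0.05, 0.95, 19)
    left_frac = float(np.mean(np.quantile(post, qs) < np.quantile(pre, qs)))
    return ChcShiftResult(
        median_shift=median_shift,
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        left_shift_fraction=left_frac,
        major_acid_shift=median_shift <= major_shift_threshold,
        threshold=major_shift_threshold,
    )
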