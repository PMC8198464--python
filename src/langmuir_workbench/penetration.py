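"""Monolayer penetration kinetics: delta-pi(t) from paired trough traces.

In a penetration experiment a pre-compressed phospholipid monolayer is held
at fixed barrier position while a substance is injected underneath; adsorption
into the film raises the surface pressure.  A reference trough, run
simultaneously without injection, tracks evaporation and ambient drifts, and

    delta-pi(t) = pi_PE(t) - pi_R(t)

isolates the adsorption signal.  Positive delta-pi indicates insertion of the
injected material into the monolayer; a drop below zero indicates extraction
of phospholipid from the interface.

The endpoint value (6 h by convention here) is the primary summary; an
exponential-saturation fit ``delta-pi(t) = dpi_max (1 - exp(-k t))`` is
provided as a derived summary of the adsorption rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PenetrationError",
    "KineticsTrace",
    "DeltaPiSeries",
    "PenetrationResult",
    "delta_pi",
    "adsorption_summary",
]


class PenetrationError(ValueError):
    """Invalid kinetics trace or incompatible trace pair."""


@dataclass
class KineticsTrace:
    """Surface pressure vs time (min) from one trough.

    ``role`` is either ``"penetration"`` (injected trough) or ``"reference"``
    (no injection).  Time zero is the injection instant; traces must start
    within one minute of it.
    """

    time: np.ndarray
    pressure: np.ndarray
    role: str
    label: str = ""
    concentration: float = 3.5

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float).copy()
        p = np.asarray(self.pressure, dtype=float).copy()
        if t.ndim != 1 or t.size != p.size or t.size < 2:
            raise PenetrationError("time and pressure must be equal-length series")
        if np.any(np.diff(t) <= 0):
            raise PenetrationError("time must be strictly increasing")
        if t[0] > 1.0:
            raise PenetrationError(
                f"trace starts at t = {t[0]:.2f} min; must start within 1 min "
                "of injection time zero"
            )
        if self.role not in ("penetration", "reference"):
            raise PenetrationError(
                f"role must be 'penetration' or 'reference', got {self.role!r}"
            )
        self.time, self.pressure = t, p


@dataclass
class DeltaPiSeries:
    """Differential pressure series on the common time grid (min, mN/m)."""

    time: np.ndarray
    delta: np.ndarray
    label: str = ""


@dataclass
class PenetrationResult:
    """Summary of an adsorption/extraction kinetics series."""

    time: np.ndarray = field(repr=False)
    delta: np.ndarray = field(repr=False)
    delta_at_6h: float = np.nan
    endpoint_time: float = 360.0
    short_span: bool = False
    regime: str = "adsorption"
    delta_min: Optional[float] = None
    dpi_max: Optional[float] = None
    k_ads: Optional[float] = None
    residual_sd: Optional[float] = None
    fit_message: str = ""
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "delta_pi_at_6h_mN_m": float(self.delta_at_6h),
            "endpoint_time_min": self.endpoint_time,
            "short_span": self.short_span,
            "regime": self.regime,
            "delta_pi_min_mN_m": self.delta_min,
            "fitted_dpi_max_mN_m": self.dpi_max,
            "fitted_k_ads_per_min": self.k_ads,
            "fit_residual_sd_mN_m": self.residual_sd,
            "fit_message": self.fit_message,
        }


def delta_pi(pe: KineticsTrace, ref: KineticsTrace) -> DeltaPiSeries:
    """delta-pi(t) = pi_PE(t) - pi_R(t) on the intersection time grid.

    Both traces are linearly interpolated onto the union of their sample
    times inside the overlap; no extrapolation is performed.  The overlap
    must cover at least 80% of the shorter trace.
    """
    if pe.role != "penetration" or ref.role != "reference":
        raise PenetrationError(
            f"role mismatch: expected (penetration, reference), got "
            f"({pe.role!r}, {ref.role!r})"
        )
    t0 = max(pe.time[0], ref.time[0])
    t1 = min(pe.time[-1], ref.time[-1])
    shorter = min(pe.time[-1] - pe.time[0], ref.time[-1] - ref.time[0])
    if t1 - t0 < 0.8 * shorter - 1e-9:
        raise PenetrationError(
            f"traces overlap over {max(t1 - t0, 0):.1f} min, less than 80% of "
            f"the shorter trace ({shorter:.1f} min)"
        )
    grid = np.union1d(
        pe.time[(pe.time >= t0) & (pe.time <= t1)],
        ref.time[(ref.time >= t0) & (ref.time <= t1)],
    )
    d = np.interp(grid, pe.time, pe.pressure) - np.interp(
        grid, ref.time, ref.pressure
    )
    return DeltaPiSeries(time=grid, delta=d, label=pe.label or ref.label)


def _saturation(t: np.ndarray, dpi_max: float, k: float) -> np.ndarray:
    return dpi_max * (1.0 - np.exp(-k * t))


def adsorption_summary(
    series: DeltaPiSeries,
    endpoint_time: float = 360.0,
    min_span: float = 60.0,
) -> PenetrationResult:
    """Summarise a delta-pi series: endpoint value and saturation-rate fit.

    The endpoint is read at ``endpoint_time`` (min) by linear interpolation
    when covered, otherwise at the last sample with a short-span flag.
    Adsorption series (positive trend) are fitted with the bounded
    exponential-saturation model; extraction series (endpoint below zero)
    are summarised by their minimum instead.  A failed or degenerate fit
    leaves the fit fields absent but still reports the endpoint.
    """
    t, d = series.time, series.delta
    span = t[-1] - t[0]
    if span < min_span:
        raise PenetrationError(f"series spans {span:.1f} min; >= {min_span} required")
    covered = t[-1] >= endpoint_time and t[0] <= endpoint_time
    d_end = float(np.interp(endpoint_time, t, d)) if covered else float(d[-1])
    res = PenetrationResult(
        time=t,
        delta=d,
        delta_at_6h=d_end,
        endpoint_time=endpoint_time,
        short_span=not covered,
        label=series.label,
    )
    if d_end < 0:
        res.regime = "extraction"
        res.delta_min = float(d.min())
        res.fit_message = "extraction regime: summarised by minimum"
        return res
    if np.max(np.abs(d)) < 1e-9:
        res.regime = "flat"
        res.fit_message = "degenerate: no signal to fit"
        return res
    # initial guesses: final value; rate from the time to half-final
    above = np.nonzero(d >= 0.5 * d_end)[0]
    t_half = float(t[above[0]]) if above.size and t[above[0]] > 0 else span / 10.0
    p0 = (max(d_end, 1e-6), np.log(2.0) / t_half)
    try:
        popt, _ = curve_fit(
            _saturation, t, d, p0=p0, bounds=(0.0, np.inf), maxfev=10000
        )
        fit_resid = d - _saturation(t, *popt)
        res.dpi_max = float(popt[0])
        res.k_ads = float(popt[1])
        res.residual_sd = float(np.std(fit_resid, ddof=min(2, t.size - 1)))
    except (RuntimeError, ValueError) as exc:
        res.fit_message = f"saturation fit failed: {exc}"
    return res
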