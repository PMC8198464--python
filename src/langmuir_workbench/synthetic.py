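"""Synthetic trough-instrument outputs with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole chain can be exercised closed-loop without laboratory data:

* ``generate_isotherm`` -- a piecewise pi-A model (quadratic liquid-expanded
  branch, linearly tilted LE-LC coexistence plateau, linear condensed branch)
  whose knots, tangents and shifts all have closed forms;
* ``generate_oscillation_trace`` -- sinusoidal area forcing with the exact
  linear viscoelastic pressure response for prescribed (E', E'');
* ``generate_penetration_pair`` -- reference/penetration traces with a shared
  drift and an exponential-saturation adsorption signal;
* ``generate_contact_angles`` -- Young angles from the inverse Owens-Wendt
  relation for a prescribed solid surface.

Noise is Gaussian and independent per sample; seeds are explicit arguments
(never global state) and equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .energy import (
    ContactAngleSet,
    DEFAULT_LIQUIDS,
    InfeasibleSurfaceError,
    ProbeLiquid,
    owens_wendt_cosine,
)
from .isotherm import Isotherm
from .penetration import KineticsTrace
from .rheology import OscillationTrace

__all__ = [
    "ParameterError",
    "IsothermModelParams",
    "OscillationModelParams",
    "PenetrationModelParams",
    "SolidSurface",
    "model_pressure",
    "collapse_area",
    "generate_isotherm",
    "generate_oscillation_trace",
    "generate_penetration_pair",
    "generate_contact_angles",
]


class ParameterError(ValueError):
    """Generator parameters violate the model's ordering constraints."""


@dataclass(frozen=True)
class IsothermModelParams:
    """Knot parameters of the piecewise pi-A reference model.

    The unshifted (pure-phospholipid) curve is zero above ``lift_off_area``,
    rises quadratically to the plateau onset (``plateau_onset_area``,
    ``plateau_onset_pressure``), crosses the coexistence plateau linearly to
    (``plateau_end_area``, onset pressure + ``plateau_tilt``), then climbs
    the condensed branch with slope ``lc_slope`` until
    ``collapse_pressure``.  Binary nanoparticle/phospholipid films are
    expressed as horizontal shifts: ``le_shift`` displaces the curve below
    the plateau onset, ``lc_shift`` (signed) above the plateau end, blended
    linearly across the plateau.

    Areas are nm^2 per phospholipid molecule, pressures mN/m, slopes
    mN/m/nm^2.
    """

    lift_off_area: float
    plateau_onset_area: float
    plateau_onset_pressure: float
    plateau_end_area: float
    plateau_tilt: float = 0.5
    lc_slope: float = 250.0
    collapse_pressure: float = 55.0
    le_shift: float = 0.0
    lc_shift: float = 0.0
    label: str = ""
    x_w: float = 0.0

    def __post_init__(self) -> None:
        if not (
            self.lift_off_area
            > self.plateau_onset_area
            > self.plateau_end_area
            > 0.0
        ):
            raise ParameterError(
                "need lift_off_area > plateau_onset_area > plateau_end_area > 0"
            )
        if self.plateau_onset_pressure <= 0:
            raise ParameterError("plateau_onset_pressure must be positive")
        if self.plateau_tilt < 0:
            raise ParameterError("plateau_tilt must be non-negative")
        if self.lc_slope <= 0:
            raise ParameterError("lc_slope must be positive")
        if self.collapse_pressure <= self.plateau_onset_pressure + self.plateau_tilt:
            raise ParameterError(
                "collapse_pressure must exceed the plateau exit pressure"
            )
        if (
            self.plateau_onset_area + self.le_shift
            <= self.plateau_end_area + self.lc_shift
        ):
            raise ParameterError("shifts fold the plateau; curve not monotone")
        if not 0.0 <= self.x_w < 1.0:
            raise ParameterError("x_w must be in [0, 1)")


def _knots(p: IsothermModelParams) -> tuple:
    """(lift-off, plateau-onset, plateau-end) areas after shifting."""
    return (
        p.lift_off_area + p.le_shift,
        p.plateau_onset_area + p.le_shift,
        p.plateau_end_area + p.lc_shift,
    )


def model_pressure(params: IsothermModelParams, area) -> np.ndarray:
    """Noise-free model pressure pi(A) of the (shifted) piecewise isotherm."""
    a_lift, a_on, a_end = _knots(params)
    w = params.lift_off_area - params.plateau_onset_area
    pc, tilt, k = (
        params.plateau_onset_pressure,
        params.plateau_tilt,
        params.lc_slope,
    )
    a = np.asarray(area, dtype=float)
    le = pc * ((a_lift - a) / w) ** 2
    plateau = pc + tilt * (a_on - a) / (a_on - a_end)
    lc = pc + tilt + k * (a_end - a)
    return np.select(
        [a >= a_lift, a >= a_on, a >= a_end], [0.0, le, plateau], default=lc
    )


def collapse_area(params: IsothermModelParams) -> float:
    """Area (nm^2) at which the model reaches the collapse pressure."""
    _, _, a_end = _knots(params)
    return a_end - (
        params.collapse_pressure
        - params.plateau_onset_pressure
        - params.plateau_tilt
    ) / params.lc_slope


def generate_isotherm(
    params: IsothermModelParams,
    n_points: int = 400,
    noise_sd: float = 0.05,
    seed: Optional[int] = None,
) -> Isotherm:
    """Sample the model on a strictly decreasing area grid with noise.

    The grid runs from 5% above the (shifted) lift-off area down to the
    collapse cut; Gaussian noise of sd ``noise_sd`` (mN/m) is added to the
    pressure.  Identical parameters and seed give bit-identical output.
    """
    if n_points < 50:
        raise ParameterError("n_points must be >= 50")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    a_lift, _, _ = _knots(params)
    a_col = collapse_area(params)
    start = a_lift + 0.05 * (a_lift - a_col)
    grid = np.linspace(start, a_col, n_points)
    pressure = model_pressure(params, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sd, n_points)
    return Isotherm(
        area=grid, pressure=pressure, label=params.label, x_w=params.x_w
    )


@dataclass(frozen=True)
class OscillationModelParams:
    """Ground truth for one oscillating-barrier burst.

    ``relative_amplitude`` is the peak (half peak-to-peak) relative area
    excursion u; the protocol value is 1% and the model caps it at 5% to
    stay in the linear-response regime.  ``sampling_rate`` defaults to 64
    samples per cycle.
    """

    e_prime: float
    e_loss: float
    frequency: float = 0.1
    relative_amplitude: float = 0.01
    baseline_pressure: float = 30.0
    baseline_area: float = 273.0
    n_cycles: int = 10
    sampling_rate: Optional[float] = None
    noise_sd: float = 0.0
    seed: Optional[int] = None
    label: str = ""
    x_w: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_amplitude <= 0.05:
            raise ParameterError("relative_amplitude must be in (0, 0.05]")
        if self.frequency <= 0:
            raise ParameterError("frequency must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.e_prime < 0:
            raise ParameterError("e_prime must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def generate_oscillation_trace(params: OscillationModelParams) -> OscillationTrace:
    """Area forcing A0(1 + u sin wt) with the linear viscoelastic response
    pi0 - u (E' sin wt + E'' cos wt) plus optional Gaussian noise."""
    f = params.frequency
    rate = params.sampling_rate if params.sampling_rate is not None else 64.0 * f
    if rate < 8.0 * f:
        raise ParameterError(
            f"sampling_rate {rate} Hz under-samples the {f} Hz harmonic "
            "(need >= 8 samples per cycle)"
        )
    n = int(round(params.n_cycles * rate / f))
    t = np.arange(n + 1) / rate
    w = 2.0 * np.pi * f
    u = params.relative_amplitude
    area = params.baseline_area * (1.0 + u * np.sin(w * t))
    pressure = params.baseline_pressure - u * (
        params.e_prime * np.sin(w * t) + params.e_loss * np.cos(w * t)
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pressure = pressure + rng.normal(0.0, params.noise_sd, t.size)
    return OscillationTrace(
        time=t,
        area=area,
        pressure=pressure,
        frequency=f,
        label=params.label,
        x_w=params.x_w,
        baseline_pressure=params.baseline_pressure,
    )


@dataclass(frozen=True)
class PenetrationModelParams:
    """Ground truth for a penetration/reference trace pair.

    The reference trough follows ``30 + reference_drift * t``; the
    penetration trough adds the exponential-saturation adsorption signal
    ``dpi_max (1 - exp(-k_ads t))``.  Each trough gets independent Gaussian
    noise (two physical sensors).  Times in minutes.
    """

    dpi_max: float
    k_ads: float
    reference_drift: float = 0.0
    duration: float = 360.0
    sampling_interval: float = 1.0
    noise_sd: float = 0.0
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.dpi_max < 0 or self.k_ads < 0:
            raise ParameterError("dpi_max and k_ads must be non-negative")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ParameterError("duration and sampling_interval must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def generate_penetration_pair(
    params: PenetrationModelParams,
) -> tuple:
    """Return (penetration, reference) traces on a common time grid."""
    t = np.arange(0.0, params.duration + params.sampling_interval / 2.0,
                  params.sampling_interval)
    base = 30.0 + params.reference_drift * t
    signal = params.dpi_max * (1.0 - np.exp(-params.k_ads * t))
    noise_ref = np.zeros_like(t)
    noise_pe = np.zeros_like(t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        noise_ref = rng.normal(0.0, params.noise_sd, t.size)
        noise_pe = rng.normal(0.0, params.noise_sd, t.size)
    pe = KineticsTrace(
        time=t,
        pressure=base + signal + noise_pe,
        role="penetration",
        label=params.label,
    )
    ref = KineticsTrace(
        time=t,
        pressure=base + noise_ref,
        role="reference",
        label=params.label,
    )
    return pe, ref


@dataclass(frozen=True)
class SolidSurface:
    """Prescribed dispersive/polar surface-energy components (mJ/m^2)."""

    gamma_d: float
    gamma_p: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.gamma_d < 0 or self.gamma_p < 0:
            raise ParameterError("surface-energy components must be non-negative")


def generate_contact_angles(
    solid: SolidSurface,
    liquids: Sequence[ProbeLiquid] = DEFAULT_LIQUIDS,
    n_drops: int = 10,
    noise_deg: float = 0.0,
    seed: Optional[int] = None,
) -> ContactAngleSet:
    """Young angles per probe liquid from the inverse Owens-Wendt relation.

    Each liquid gets ``n_drops`` angles: the exact Young angle plus Gaussian
    noise of sd ``noise_deg``, clipped to the open interval (0, 180) deg.
    A surface/liquid combination whose Owens-Wendt cosine leaves [-1, 1]
    raises :class:`InfeasibleSurfaceError` naming the liquid.
    """
    if n_drops < 1:
        raise ParameterError("n_drops must be >= 1")
    if noise_deg < 0:
        raise ParameterError("noise_deg must be non-negative")
    rng = np.random.default_rng(seed)
    angles = {}
    for liq in liquids:
        c = owens_wendt_cosine(solid.gamma_d, solid.gamma_p, liq)
        if not -1.0 <= c <= 1.0:
            raise InfeasibleSurfaceError(liq.name, c)
        theta = float(np.degrees(np.arccos(c)))
        drops = theta + rng.normal(0.0, noise_deg, n_drops) if noise_deg > 0 \
            else np.full(n_drops, theta)
        angles[liq.name] = np.clip(drops, 1e-6, 180.0 - 1e-6)
    return ContactAngleSet(angles=angles, label=solid.label)
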