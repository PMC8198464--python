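"""Dilatational viscoelasticity from oscillating-barrier traces.

In the oscillating-barrier experiment the trough area is driven sinusoidally
with a small relative amplitude u around A0 while the surface pressure
response is recorded.  The complex dilatational modulus E = E' + iE'' relates
the two through ``delta-pi = -E * delta-A / A``: the elastic modulus E' is the
in-phase (with -delta-A/A) part of the response and the viscous modulus E''
the quadrature part.  With this sign convention an ideally elastic film (pi
exactly antiphase with area) has phase lag 0 and E'' = 0; a perfectly viscous
film has E' = 0 and lag pi/2.

Moduli are extracted by least-squares harmonic regression at the known
barrier frequency, which is robust to non-integer cycle counts and short
records.  Traces that contain rest intervals between oscillation bursts are
split at the gaps, fitted burst by burst and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "RheologyError",
    "OscillationTrace",
    "HarmonicFit",
    "ViscoelasticResult",
    "fit_harmonic",
    "viscoelastic_moduli",
    "frequency_sweep",
]


class RheologyError(ValueError):
    """Invalid oscillation trace or an unusable harmonic fit."""


def _wrap_phase(phi: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    out = (phi + np.pi) % (2.0 * np.pi) - np.pi
    if out == -np.pi:
        out = np.pi
    return float(out)


@dataclass
class OscillationTrace:
    """Forced-oscillation record: time (s), area (absolute or relative) and
    surface pressure (mN/m) at a known barrier frequency (Hz)."""

    time: np.ndarray
    area: np.ndarray
    pressure: np.ndarray
    frequency: float
    label: str = ""
    x_w: float = 0.0
    baseline_pressure: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float).copy()
        a = np.asarray(self.area, dtype=float).copy()
        p = np.asarray(self.pressure, dtype=float).copy()
        if not (t.ndim == a.ndim == p.ndim == 1 and t.size == a.size == p.size):
            raise RheologyError("time, area and pressure must be equal-length series")
        if t.size < 8:
            raise RheologyError("trace too short")
        if np.any(np.diff(t) <= 0):
            raise RheologyError("time must be strictly increasing")
        if self.frequency <= 0:
            raise RheologyError("frequency must be positive")
        self.time, self.area, self.pressure = t, a, p


@dataclass
class HarmonicFit:
    """Least-squares fit of ``y = mean + a sin(wt) + b cos(wt)``."""

    mean: float
    sin_coeff: float
    cos_coeff: float
    residual_sd: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.sin_coeff, self.cos_coeff))

    @property
    def phase(self) -> float:
        """Phase of the fitted phasor, such that y ~ R sin(wt + phase)."""
        return float(np.arctan2(self.cos_coeff, self.sin_coeff))


@dataclass
class ViscoelasticResult:
    """Complex dilatational modulus extracted from one trace."""

    e_prime: float
    e_loss: float
    magnitude: float
    phase: float
    u: float
    frequency: float
    residual_sd: float
    n_bursts: int = 1
    e_prime_sd: Optional[float] = None
    e_loss_sd: Optional[float] = None
    label: str = ""
    x_w: float = 0.0


def fit_harmonic(
    t: Sequence[float], y: Sequence[float], f: float
) -> HarmonicFit:
    """Demodulate a signal at a known frequency by linear least squares.

    Requires the record to span at least three oscillation periods; shorter
    (rank-deficient) designs raise :class:`RheologyError`.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 4:
        raise RheologyError("need equal-length series with >= 4 samples")
    span = t[-1] - t[0]
    if span * f < 3.0 - 1e-9:
        raise RheologyError(
            f"record spans {span * f:.2f} periods at {f} Hz; >= 3 required"
        )
    w = 2.0 * np.pi * f
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise RheologyError("rank-deficient harmonic design (span << 1/f?)")
    resid = y - design @ coef
    dof = max(t.size - 3, 1)
    return HarmonicFit(
        mean=float(coef[0]),
        sin_coeff=float(coef[1]),
        cos_coeff=float(coef[2]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def _split_bursts(time: np.ndarray, gap_factor: float) -> list:
    dt = np.diff(time)
    base = float(np.median(dt))
    cuts = np.nonzero(dt > gap_factor * base)[0]
    edges = [0, *(c + 1 for c in cuts), time.size]
    return [slice(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _fit_one_burst(
    t: np.ndarray,
    area: np.ndarray,
    pressure: np.ndarray,
    f: float,
    min_relative_amplitude: float,
) -> tuple:
    abar = float(np.mean(area))
    x = area / abar - 1.0
    hx = fit_harmonic(t, x, f)
    hp = fit_harmonic(t, pressure, f)
    u = hx.amplitude
    if u < min_relative_amplitude:
        raise RheologyError(
            f"relative area amplitude {u:.2e} below {min_relative_amplitude}; no forcing"
        )
    # phase of the *negated* pressure harmonic relative to the area harmonic:
    # an elastic film (pi antiphase with area) then has zero lag.
    phi = _wrap_phase(
        np.arctan2(-hp.cos_coeff, -hp.sin_coeff) - hx.phase
    )
    mag = hp.amplitude / u
    return mag * np.cos(phi), mag * np.sin(phi), u, hp.residual_sd


def viscoelastic_moduli(
    trace: OscillationTrace,
    discard_first_cycle: bool = True,
    refine_frequency: bool = False,
    burst_gap_factor: float = 5.0,
    min_relative_amplitude: float = 1e-4,
) -> ViscoelasticResult:
    """Extract (E', E'') from one oscillating-barrier trace.

    The trace is split into bursts at sampling gaps larger than
    ``burst_gap_factor`` times the median step (rest intervals between
    oscillation cycles); each burst is demodulated separately, optionally
    after discarding its first cycle as a transient, and the moduli are
    averaged across bursts (sd reported when more than one).

    ``refine_frequency`` searches +-5% around the nominal frequency for the
    value minimising the pressure-fit residual, guarding against metadata
    drift.
    """
    f = trace.frequency
    t = trace.time
    dt = np.diff(t)
    bursts = _split_bursts(t, burst_gap_factor)
    for sl in bursts:
        seg = dt[sl.start : sl.stop - 1]
        if seg.size and seg.max() > 1.5 * seg.min():
            raise RheologyError("non-uniform time step inside a burst")
        if seg.size and float(np.median(seg)) > 1.0 / (8.0 * f) + 1e-12:
            raise RheologyError(
                "fewer than 8 samples per cycle; under-sampled harmonic"
            )

    if refine_frequency:
        sl0 = bursts[0]

        def _resid(ff: float) -> float:
            try:
                return fit_harmonic(t[sl0], trace.pressure[sl0], ff).residual_sd
            except RheologyError:
                return np.inf

        res = minimize_scalar(
            _resid, bounds=(0.95 * f, 1.05 * f), method="bounded"
        )
        f = float(res.x)

    eps, evs, us, resids = [], [], [], []
    for sl in bursts:
        tb = t[sl]
        ab = trace.area[sl]
        pb = trace.pressure[sl]
        if discard_first_cycle and (tb[-1] - tb[0]) * f >= 4.0:
            keep = tb >= tb[0] + 1.0 / f
            tb, ab, pb = tb[keep], ab[keep], pb[keep]
        ep, ev, u, rsd = _fit_one_burst(tb, ab, pb, f, min_relative_amplitude)
        eps.append(ep)
        evs.append(ev)
        us.append(u)
        resids.append(rsd)

    e_prime = float(np.mean(eps))
    e_loss = float(np.mean(evs))
    phi = _wrap_phase(np.arctan2(e_loss, e_prime))
    if abs(phi) > np.pi / 2 + 1e-9:
        warnings.warn(
            f"phase lag {phi:.2f} rad exceeds pi/2: non-physical response, "
            "likely a sign or frequency mismatch",
            stacklevel=2,
        )
    nb = len(bursts)
    return ViscoelasticResult(
        e_prime=e_prime,
        e_loss=e_loss,
        magnitude=float(np.hypot(e_prime, e_loss)),
        phase=phi,
        u=float(np.mean(us)),
        frequency=f,
        residual_sd=float(np.mean(resids)),
        n_bursts=nb,
        e_prime_sd=float(np.std(eps, ddof=1)) if nb > 1 else None,
        e_loss_sd=float(np.std(evs, ddof=1)) if nb > 1 else None,
        label=trace.label,
        x_w=trace.x_w,
    )


def frequency_sweep(
    traces: Iterable[OscillationTrace], **moduli_kwargs
) -> pd.DataFrame:
    """Tabulate (E', E'') for a collection of traces across compositions.

    Returns one row per trace sorted by (x_w, frequency); duplicate
    (label, frequency) pairs are kept and numbered by a replicate index.
    Per-trace failures are recorded in the ``error`` column rather than
    aborting the sweep.
    """
    traces = list(traces)
    if not traces:
        raise RheologyError("empty trace collection")
    rows = []
    for tr in traces:
        row = {
            "label": tr.label,
            "x_w": tr.x_w,
            "frequency_hz": tr.frequency,
            "e_prime_mN_m": np.nan,
            "e_loss_mN_m": np.nan,
            "magnitude_mN_m": np.nan,
            "phase_rad": np.nan,
            "u": np.nan,
            "residual_sd_mN_m": np.nan,
            "error": "",
        }
        try:
            res = viscoelastic_moduli(tr, **moduli_kwargs)
            row.update(
                e_prime_mN_m=res.e_prime,
                e_loss_mN_m=res.e_loss,
                magnitude_mN_m=res.magnitude,
                phase_rad=res.phase,
                u=res.u,
                residual_sd_mN_m=res.residual_sd,
            )
        except (RheologyError, ValueError) as exc:  # recorded, not fatal
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["replicate"] = df.groupby(["label", "frequency_hz"]).cumcount()
    return df.sort_values(
        ["x_w", "frequency_hz", "replicate"], kind="stable"
    ).reset_index(drop=True)
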