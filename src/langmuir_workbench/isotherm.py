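"""Surface pressure-area (pi-A) isotherm analysis for Langmuir monolayers.

A compressed amphiphile film at the air-water interface is characterised by its
pi-A isotherm: surface pressure pi (mN/m, measured by a Wilhelmy plate) against
the mean molecular area A (nm^2 per phospholipid molecule).  This module
provides the standard thermodynamic post-processing of such isotherms:

* the compression modulus ``Cs^-1 = -A dpi/dA`` (reciprocal compressibility),
* Davies-Rideal phase classification from the modulus value,
* the extrapolated area ``A_EXT`` (tangent of the first linear slope taken to
  pi = 0),
* detection of the liquid-expanded/liquid-condensed (LE-LC) coexistence
  plateau and its onset/exit parameters (A_C, pi_C, pi'_C, pi''_C),
* horizontal shifts between two isotherms at a common pressure.

All pressures are in mN/m and areas in nm^2 per molecule throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "AVOGADRO",
    "DPPC_MOLAR_MASS",
    "PHASE_BREAKPOINTS",
    "Isotherm",
    "IsothermError",
    "PlateauInversionError",
    "ModulusCurve",
    "TransitionReport",
    "ExtrapolationResult",
    "compression_modulus",
    "classify_phase",
    "smooth_isotherm",
    "extrapolated_area",
    "detect_transitions",
    "analyze",
    "isotherm_shift",
    "mean_molecular_area",
]

AVOGADRO = 6.02214076e23
#: Molar mass of dipalmitoylphosphatidylcholine (g/mol).
DPPC_MOLAR_MASS = 734.039
#: Davies-Rideal compression-modulus breakpoints (mN/m).
PHASE_BREAKPOINTS = (12.5, 50.0, 100.0, 250.0)


class IsothermError(ValueError):
    """Invalid isotherm data or an operation that cannot be applied to it."""


class PlateauInversionError(IsothermError):
    """Inverse lookup A(pi) requested at a pressure inside a coexistence plateau."""

    def __init__(self, label: str, lower: float, upper: float):
        self.label = label
        self.lower = float(lower)
        self.upper = float(upper)
        super().__init__(
            f"pressure lies on the plateau of isotherm {label!r} "
            f"({self.lower:.3f}..{self.upper:.3f} mN/m); the inverse A(pi) is "
            "multi-valued there"
        )


@dataclass
class Isotherm:
    """A pi-A isotherm in compression order (area strictly decreasing).

    Parameters
    ----------
    area : array-like
        Mean molecular area, nm^2 per phospholipid molecule, strictly
        monotone.  Increasing input is reversed into compression order.
    pressure : array-like
        Surface pressure, mN/m.  Small negative values (>= -0.5) are
        tolerated as sensor noise.
    label, x_w, temperature
        Film metadata: name, nanoparticle weight fraction in [0, 1), and
        subphase temperature in deg C.
    """

    area: np.ndarray
    pressure: np.ndarray
    label: str = ""
    x_w: float = 0.0
    temperature: float = 20.0

    def __post_init__(self) -> None:
        a = np.asarray(self.area, dtype=float).copy()
        p = np.asarray(self.pressure, dtype=float).copy()
        if a.ndim != 1 or p.ndim != 1 or a.size != p.size:
            raise IsothermError("area and pressure must be 1-d series of equal length")
        if a.size < 10:
            raise IsothermError(f"isotherm needs >= 10 points, got {a.size}")
        d = np.diff(a)
        if np.all(d > 0):  # increasing-area order: flip into compression order
            a, p = a[::-1], p[::-1]
        elif not np.all(d < 0):
            raise IsothermError("area series must be strictly monotone")
        if not (np.isfinite(a).all() and np.isfinite(p).all()):
            raise IsothermError("non-finite values in isotherm")
        if p.min() < -0.5:
            raise IsothermError(
                f"pressure {p.min():.3f} mN/m below the -0.5 sensor-noise floor"
            )
        if not 0.0 <= self.x_w < 1.0:
            raise IsothermError("nanoparticle weight fraction x_w must be in [0, 1)")
        self.area, self.pressure = a, p

    @property
    def n(self) -> int:
        return int(self.area.size)


@dataclass
class ModulusCurve:
    """Compression modulus Cs^-1 = -A dpi/dA aligned with its source grid."""

    pressure: np.ndarray
    modulus: np.ndarray
    area: np.ndarray


@dataclass
class ExtrapolationResult:
    """Tangent extrapolation of the first linear slope to pi = 0."""

    a_ext: float
    slope: float
    intercept: float
    r_squared: float
    window: tuple
    n_points: int
    flags: list = field(default_factory=list)


@dataclass
class TransitionReport:
    """LE-LC transition parameters extracted from a modulus curve.

    ``pi_c_prime``/``pi_c_double_prime`` bracket the coexistence interval
    (modulus below the coexistence threshold between the LE and LC maxima);
    they are ``None`` when the plateau is nearly horizontal (single
    transition point reported) or when no transition is detected.
    """

    a_ext: Optional[float] = None
    a_c: Optional[float] = None
    pi_c: Optional[float] = None
    pi_c_prime: Optional[float] = None
    pi_c_double_prime: Optional[float] = None
    max_modulus_le: Optional[float] = None
    max_modulus_lc: Optional[float] = None
    label: str = ""
    _curve: Optional[ModulusCurve] = field(default=None, repr=False, compare=False)

    @property
    def has_transition(self) -> bool:
        return self.a_c is not None

    def phase_at(self, pressure: float) -> str:
        """Davies-Rideal phase label at a given surface pressure."""
        if self._curve is None:
            raise IsothermError("report carries no modulus curve")
        order = np.argsort(self._curve.pressure, kind="stable")
        m = np.interp(
            pressure, self._curve.pressure[order], self._curve.modulus[order]
        )
        return classify_phase(float(m))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "a_ext_nm2": self.a_ext,
            "a_c_nm2": self.a_c,
            "pi_c_mN_m": self.pi_c,
            "pi_c_prime_mN_m": self.pi_c_prime,
            "pi_c_double_prime_mN_m": self.pi_c_double_prime,
            "max_modulus_le_mN_m": self.max_modulus_le,
            "max_modulus_lc_mN_m": self.max_modulus_lc,
        }


def compression_modulus(iso: Isotherm) -> ModulusCurve:
    """Compute Cs^-1(A) = -A dpi/dA by finite differences.

    Interior points use the three-point Lagrange derivative on the (possibly
    irregular) area grid, which is exact for quadratics; the two boundary
    points use one-sided two-point differences.
    """
    x, y = iso.area, iso.pressure
    n = x.size
    if n < 3:
        raise IsothermError("need at least 3 points to differentiate")
    d = np.empty(n)
    x0, x1, x2 = x[:-2], x[1:-1], x[2:]
    y0, y1, y2 = y[:-2], y[1:-1], y[2:]
    d[1:-1] = (
        y0 * (x1 - x2) / ((x0 - x1) * (x0 - x2))
        + y1 * (2.0 * x1 - x0 - x2) / ((x1 - x0) * (x1 - x2))
        + y2 * (x1 - x0) / ((x2 - x0) * (x2 - x1))
    )
    d[0] = (y[1] - y[0]) / (x[1] - x[0])
    d[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    return ModulusCurve(pressure=y.copy(), modulus=-x * d, area=x.copy())


def classify_phase(modulus: float) -> str:
    """Davies-Rideal phase label for a compression-modulus value (mN/m).

    Breakpoints {12.5, 50, 100, 250}: below 12.5 gaseous/expanded-gas,
    [12.5, 50) liquid-expanded, [50, 100) liquid, [100, 250] liquid-condensed
    and strictly above 250 solid.  Negative moduli are flagged rather than
    classified.
    """
    m = float(modulus)
    if not np.isfinite(m):
        raise IsothermError("modulus must be finite")
    if m < 0:
        return "unstable/artifact"
    if m < PHASE_BREAKPOINTS[0]:
        return "G/LE-gas"
    if m < PHASE_BREAKPOINTS[1]:
        return "LE"
    if m < PHASE_BREAKPOINTS[2]:
        return "L"
    if m <= PHASE_BREAKPOINTS[3]:
        return "LC"
    return "S"


def smooth_isotherm(iso: Isotherm, window: int = 11, polyorder: int = 3) -> Isotherm:
    """Savitzky-Golay-type local polynomial smoothing of pressure over area.

    Works on irregular grids; endpoints are handled by shifting the full
    window inside the series (so polynomials of degree <= ``polyorder`` are
    reproduced exactly everywhere).  The area grid is unchanged.
    """
    n = iso.n
    if window % 2 == 0:
        raise IsothermError("window must be odd")
    if window < polyorder + 2:
        raise IsothermError("window must be >= polyorder + 2")
    if window >= n:
        raise IsothermError(f"window {window} must be smaller than series length {n}")
    x, y = iso.area, iso.pressure
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        sl = slice(lo, lo + window)
        coef = np.polynomial.polynomial.polyfit(x[sl] - x[i], y[sl], polyorder)
        out[i] = coef[0]
    return Isotherm(
        area=x.copy(),
        pressure=out,
        label=iso.label,
        x_w=iso.x_w,
        temperature=iso.temperature,
    )


def _contiguous_first_segment(mask: np.ndarray) -> Optional[slice]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return None
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    end = idx[breaks[0]] if breaks.size else idx[-1]
    return slice(int(idx[0]), int(end) + 1)


def extrapolated_area(
    iso: Isotherm,
    fit_window: Optional[tuple] = None,
    onset_pressure: Optional[float] = None,
    min_points: int = 5,
    min_r_squared: float = 0.98,
) -> ExtrapolationResult:
    """A_EXT: extrapolate the first linear slope of the isotherm to pi = 0.

    A least-squares line ``pi = a + b*A`` is fitted over the first
    (largest-area) contiguous run of points whose pressure lies inside
    ``fit_window``; ``A_EXT = -a/b``.  The default window is
    ``[0.3, 0.9] * onset_pressure`` where the plateau-onset pressure is
    either supplied or estimated by transition detection (falling back to
    60% of the maximum pressure if no plateau exists).
    """
    if fit_window is None:
        if onset_pressure is None:
            rep = detect_transitions(
                iso, compression_modulus(iso), compute_a_ext=False
            )
            onset_pressure = (
                rep.pi_c if rep.pi_c is not None else 0.6 * float(iso.pressure.max())
            )
        fit_window = (0.3 * onset_pressure, 0.9 * onset_pressure)
    lo, hi = float(fit_window[0]), float(fit_window[1])
    if not lo < hi:
        raise IsothermError("fit_window must be an increasing pressure interval")
    if iso.pressure.max() < hi:
        raise IsothermError(
            f"isotherm (max pi = {iso.pressure.max():.2f}) does not reach the "
            f"upper fit-window bound {hi:.2f}"
        )
    seg = _contiguous_first_segment((iso.pressure >= lo) & (iso.pressure <= hi))
    if seg is None:
        raise IsothermError("no points inside the fit window")
    a_seg, p_seg = iso.area[seg], iso.pressure[seg]
    flags: list = []
    if a_seg.size < 2:
        raise IsothermError("fewer than 2 points in the fit window")
    if a_seg.size < min_points:
        flags.append(f"low-confidence: only {a_seg.size} points in window")
    b, a = np.polyfit(a_seg, p_seg, 1)
    if b >= 0:
        raise IsothermError("non-negative slope in the fit window; not an LE rise")
    resid = p_seg - (a + b * a_seg)
    ss_tot = float(np.sum((p_seg - p_seg.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if r2 < min_r_squared:
        flags.append(f"low-confidence: R^2 = {r2:.4f} < {min_r_squared}")
    return ExtrapolationResult(
        a_ext=float(-a / b),
        slope=float(b),
        intercept=float(a),
        r_squared=r2,
        window=(lo, hi),
        n_points=int(a_seg.size),
        flags=flags,
    )


def _fit_line(x: np.ndarray, y: np.ndarray, lo: int, hi: int) -> Optional[tuple]:
    """Least-squares line over indices [lo, hi] clamped into range."""
    n = x.size
    lo, hi = max(lo, 0), min(hi, n - 1)
    if hi - lo < 1:
        return None
    sl = slice(lo, hi + 1)
    b, a = np.polyfit(x[sl], y[sl], 1)
    return float(b), float(a)


def _refine_knot(
    area: np.ndarray,
    pressure: np.ndarray,
    left: tuple,
    right: tuple,
) -> Optional[tuple]:
    """Intersect branch tangent lines fitted left/right of a slope break.

    Returns (pi, A) at the intersection, or None if either side cannot be
    fitted or the branches are parallel.
    """
    f1 = _fit_line(area, pressure, *left)
    f2 = _fit_line(area, pressure, *right)
    if f1 is None or f2 is None:
        return None
    (m1, c1), (m2, c2) = f1, f2
    if abs(m1 - m2) < 1e-12:
        return None
    a_x = (c2 - c1) / (m1 - m2)
    return (m1 * a_x + c1, a_x)


def detect_transitions(
    iso: Isotherm,
    curve: Optional[ModulusCurve] = None,
    coexistence_threshold: float = 50.0,
    min_plateau_rise: float = 0.5,
    min_pressure: float = 0.5,
    knot_gap: int = 3,
    min_prominence: float = 5.0,
    compute_a_ext: bool = True,
) -> TransitionReport:
    """Locate the LE-LC coexistence region from the Cs^-1(pi) curve.

    The two principal maxima of the modulus (LE and LC packing maxima) are
    separated by the plateau dip; the coexistence interval is where the
    modulus stays below ``coexistence_threshold`` between them.  Entry and
    exit pressures (pi'_C, pi''_C) are refined to sub-grid accuracy by
    intersecting straight-line fits of the pi-A branches on either side of
    each slope break, ``knot_gap`` points away from the detected crossing
    (increase the gap for smoothed data, where the break is smeared over
    roughly half the smoothing window).  A near-horizontal plateau
    (pi''_C - pi'_C below ``min_plateau_rise``) is reported as a single
    transition point (A_C, pi_C).

    Monotone modulus curves with no interior dip yield a report with the
    transition fields absent.
    """
    if curve is None:
        curve = compression_modulus(iso)
    A, P, C = curve.area, curve.pressure, curve.modulus

    def _absent() -> TransitionReport:
        rep = TransitionReport(label=iso.label, _curve=curve)
        if compute_a_ext:
            try:
                rep.a_ext = extrapolated_area(
                    iso, onset_pressure=0.6 * float(P.max())
                ).a_ext
            except IsothermError:
                rep.a_ext = None
        return rep

    dom = np.nonzero(P > min_pressure)[0]
    if dom.size < 10:
        return _absent()
    cd = C[dom]
    c_range = float(cd.max() - cd.min())
    if c_range <= 0:
        return _absent()
    # the LE and LC packing maxima are the two most prominent peaks of
    # Cs^-1; noise spikes have far smaller prominence than the coexistence
    # dip that separates the principal maxima
    peaks, props = find_peaks(cd, prominence=min_prominence)
    if peaks.size < 2:
        return _absent()
    top2 = np.sort(peaks[np.argsort(props["prominences"])[::-1][:2]])
    ile, ig = int(dom[top2[0]]), int(dom[top2[1]])
    between = np.arange(ile, ig + 1)
    idip = int(between[np.argmin(C[between])])
    if not C[idip] < coexistence_threshold:
        return _absent()

    # The coexistence dip sits between the LE and LC packing maxima.  The
    # entry/exit slope breaks are located where the modulus crosses half its
    # prominence on either flank, scanning outward from the dip -- a level
    # crossing on a steep flank is robust to noise, unlike an argmax on the
    # flat LE branch.
    half_le = C[idip] + 0.5 * (C[ile] - C[idip])
    i1 = next(
        (i for i in range(idip, ile - 1, -1) if C[i] >= half_le), ile
    )
    g = int(knot_gap)
    onset = _refine_knot(
        A, P, left=(i1 - g - 4, i1 - g), right=(i1 + g, i1 + g + 6)
    ) or (float(P[i1]), float(A[i1]))
    half_lc = C[idip] + 0.5 * (C[ig] - C[idip])
    i2 = next(
        (i for i in range(idip, ig + 1) if C[i] >= half_lc), ig
    )
    exit_ = _refine_knot(
        A, P, left=(i2 - g - 6, i2 - g), right=(i2 + g, i2 + g + 4)
    ) or (float(P[i2]), float(A[i2]))

    pi1, a1 = onset
    pi2, _ = exit_
    rep = TransitionReport(
        a_c=a1,
        pi_c=pi1,
        max_modulus_le=float(C[ile]),
        max_modulus_lc=float(C[ig]),
        label=iso.label,
        _curve=curve,
    )
    if pi2 - pi1 >= min_plateau_rise:
        rep.pi_c_prime = pi1
        rep.pi_c_double_prime = pi2
    if compute_a_ext:
        try:
            rep.a_ext = extrapolated_area(iso, onset_pressure=pi1).a_ext
        except IsothermError:
            rep.a_ext = None
    return rep


def analyze(
    iso: Isotherm,
    smooth_window: Optional[int] = None,
    polyorder: int = 3,
    **detect_kwargs,
) -> tuple:
    """Smooth (optionally), differentiate and detect transitions in one call.

    Returns ``(ModulusCurve, TransitionReport)``.  When smoothing is applied
    the knot-refinement gap defaults to half the smoothing window, since the
    slope breaks are smeared by the filter.
    """
    work = iso
    if smooth_window is not None:
        work = smooth_isotherm(iso, window=smooth_window, polyorder=polyorder)
        detect_kwargs.setdefault("knot_gap", smooth_window // 2 + 2)
    curve = compression_modulus(work)
    report = detect_transitions(work, curve, **detect_kwargs)
    return curve, report


def _area_at_pressure(
    iso: Isotherm, pi: float, plateau_slope_threshold: float
) -> float:
    """Inverse lookup A(pi) on the monotone-rising branch, plateau-aware."""
    a, p = iso.area, iso.pressure
    # keep the running-maximum envelope so pressure is non-decreasing
    env = np.maximum.accumulate(p)
    keep = p >= env - 1e-12
    ak, pk = a[keep], p[keep]
    # drop repeated pressures (flat zero-pressure head) for interpolation
    first = np.concatenate(([True], np.diff(pk) > 0))
    ak, pk = ak[first], pk[first]
    if not (pk[0] - 1e-9 <= pi <= pk[-1] + 1e-9):
        raise IsothermError(
            f"pressure {pi} outside the rising range "
            f"[{pk[0]:.3f}, {pk[-1]:.3f}] of isotherm {iso.label!r}"
        )
    # plateau guard: runs of low |dpi/dA| spanning the requested pressure
    slopes = np.diff(pk) / np.diff(ak)
    low = np.abs(slopes) < plateau_slope_threshold
    run = _contiguous_first_segment(low)
    while run is not None:
        if run.stop - run.start >= 3:
            lo_p, hi_p = pk[run.start], pk[run.stop]
            if lo_p - 1e-9 <= pi <= hi_p + 1e-9:
                raise PlateauInversionError(iso.label, lo_p, hi_p)
        nxt = low.copy()
        nxt[: run.stop] = False
        run = _contiguous_first_segment(nxt)
    return float(np.interp(pi, pk, ak))


def isotherm_shift(
    a: Isotherm, b: Isotherm, pi: float, plateau_slope_threshold: float = 5.0
) -> float:
    """Horizontal shift Delta-A = A_a(pi) - A_b(pi) at a common pressure.

    Both isotherms are inverted by linear interpolation on their monotone
    rising branch.  Pressures falling on a coexistence plateau (local
    |dpi/dA| below ``plateau_slope_threshold`` over >= 3 consecutive
    segments) raise :class:`PlateauInversionError` naming the plateau bounds.
    """
    return _area_at_pressure(a, pi, plateau_slope_threshold) - _area_at_pressure(
        b, pi, plateau_slope_threshold
    )


def mean_molecular_area(
    trough_area_cm2: float,
    deposited_volume_ul: float,
    mixture_concentration_mg_ml: float,
    x_w: float = 0.0,
    molar_mass_g_mol: float = DPPC_MOLAR_MASS,
) -> float:
    """Mean molecular area per phospholipid molecule, nm^2.

    The deposited mixture contains a nanoparticle weight fraction ``x_w``;
    only the phospholipid mass ``(1 - x_w)`` counts towards the number of
    molecules, so nanoparticles dilute nothing in the normalisation:

    ``A = trough_area / (V * c * (1 - x_w) / M * N_A)``

    with the trough area converted from cm^2 to nm^2.
    """
    if x_w >= 1.0:
        raise IsothermError("x_w >= 1 leaves no phospholipid in the mixture")
    if min(trough_area_cm2, deposited_volume_ul, mixture_concentration_mg_ml) <= 0:
        raise IsothermError("trough area, volume and concentration must be positive")
    if x_w < 0:
        raise IsothermError("x_w must be non-negative")
    grams = deposited_volume_ul * mixture_concentration_mg_ml * 1e-6 * (1.0 - x_w)
    n_molecules = grams / molar_mass_g_mol * AVOGADRO
    return trough_area_cm2 * 1e14 / n_molecules
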