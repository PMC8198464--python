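"""Owens-Wendt surface free energy from sessile-drop contact angles.

The Owens-Wendt (geometric-mean) scheme splits the surface free energy of a
solid into a dispersive and a polar component, ``gamma_s = gamma_d + gamma_p``,
determined from the Young contact angles theta_i of two (or more) probe
liquids with known components via

    gamma_L,i (1 + cos theta_i) = 2 sqrt(gamma_d gamma_L,i^d)
                                 + 2 sqrt(gamma_p gamma_L,i^p).

Substituting x = sqrt(gamma_d), y = sqrt(gamma_p) makes the system linear;
two liquids give an exact solve, more give least squares.  Negative roots
(infeasible geometry, usually noise) are clamped to zero and flagged.
Uncertainties are propagated by a seeded parametric bootstrap over the drop
angles, since the square of a near-zero root is strongly non-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceEnergyError",
    "InfeasibleSurfaceError",
    "SingularSystemError",
    "ProbeLiquid",
    "ContactAngleSet",
    "SurfaceEnergyResult",
    "GLYCERIN",
    "DIIODOMETHANE",
    "DEFAULT_LIQUIDS",
    "owens_wendt_cosine",
    "young_angle",
    "aggregate_angles",
    "owens_wendt_solve",
    "surface_energy_from_drops",
]


class SurfaceEnergyError(ValueError):
    """Invalid contact-angle data or an unsolvable Owens-Wendt system."""


class InfeasibleSurfaceError(SurfaceEnergyError):
    """The prescribed surface components admit no Young angle for a liquid."""

    def __init__(self, liquid: str, cosine: float):
        self.liquid = liquid
        self.cosine = float(cosine)
        super().__init__(
            f"Owens-Wendt cosine {cosine:.3f} outside [-1, 1] for liquid "
            f"{liquid!r}: surface/liquid combination is infeasible"
        )


class SingularSystemError(SurfaceEnergyError):
    """The probe liquids are (nearly) dispersively proportional."""


@dataclass(frozen=True)
class ProbeLiquid:
    """A probe liquid with total, dispersive and polar tension (mJ/m^2)."""

    name: str
    gamma: float
    gamma_d: float
    gamma_p: float

    def __post_init__(self) -> None:
        if min(self.gamma, self.gamma_d, self.gamma_p) < 0:
            raise SurfaceEnergyError(f"negative tension component for {self.name!r}")
        if abs(self.gamma - self.gamma_d - self.gamma_p) > 0.1:
            raise SurfaceEnergyError(
                f"{self.name!r}: gamma must equal gamma_d + gamma_p within 0.1"
            )


#: Literature Owens-Wendt components for the two probe liquids (mJ/m^2).
GLYCERIN = ProbeLiquid("glycerin", 63.4, 37.0, 26.4)
DIIODOMETHANE = ProbeLiquid("diiodomethane", 50.8, 50.8, 0.0)
DEFAULT_LIQUIDS = (GLYCERIN, DIIODOMETHANE)


@dataclass
class ContactAngleSet:
    """Per-liquid collections of sessile-drop contact angles (degrees)."""

    angles: dict
    label: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, vals in self.angles.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise SurfaceEnergyError(f"empty drop group for liquid {name!r}")
            if np.any((arr <= 0) | (arr >= 180)):
                raise SurfaceEnergyError(
                    f"angles for {name!r} must lie strictly inside (0, 180) deg"
                )
            clean[name] = arr
        self.angles = clean


@dataclass
class SurfaceEnergyResult:
    """Solved surface free energy components, mJ/m^2 (gamma_s = d + p)."""

    label: str
    gamma_d: float
    gamma_p: float
    gamma_s: float
    gamma_d_sd: Optional[float] = None
    gamma_p_sd: Optional[float] = None
    gamma_s_sd: Optional[float] = None
    infeasible: bool = False
    per_liquid: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "gamma_s_mJ_m2": self.gamma_s,
            "gamma_d_mJ_m2": self.gamma_d,
            "gamma_p_mJ_m2": self.gamma_p,
            "gamma_s_sd_mJ_m2": self.gamma_s_sd,
            "gamma_d_sd_mJ_m2": self.gamma_d_sd,
            "gamma_p_sd_mJ_m2": self.gamma_p_sd,
            "infeasible": self.infeasible,
        }


def owens_wendt_cosine(gamma_d: float, gamma_p: float, liquid: ProbeLiquid) -> float:
    """cos(theta) predicted for a solid (gamma_d, gamma_p) against a liquid."""
    return (
        2.0
        * (
            np.sqrt(gamma_d * liquid.gamma_d)
            + np.sqrt(gamma_p * liquid.gamma_p)
        )
        / liquid.gamma
        - 1.0
    )


def young_angle(gamma_d: float, gamma_p: float, liquid: ProbeLiquid) -> float:
    """Young contact angle (degrees) from the inverse Owens-Wendt relation."""
    c = owens_wendt_cosine(gamma_d, gamma_p, liquid)
    if not -1.0 <= c <= 1.0:
        raise InfeasibleSurfaceError(liquid.name, c)
    return float(np.degrees(np.arccos(c)))


def aggregate_angles(raw: ContactAngleSet, protocol_n: int = 10) -> pd.DataFrame:
    """Per-liquid mean, sample sd and count of the drop angles.

    Groups with fewer than ``protocol_n`` drops are flagged as
    below-protocol (the goniometer protocol averages at least ten drops)
    but still aggregated.  Fewer than two drops in a group is an error.
    """
    rows = []
    for name, arr in raw.angles.items():
        if arr.size < 2:
            raise SurfaceEnergyError(
                f"liquid {name!r} has {arr.size} drop(s); >= 2 required"
            )
        rows.append(
            {
                "liquid": name,
                "mean_deg": float(arr.mean()),
                "sd_deg": float(arr.std(ddof=1)),
                "n": int(arr.size),
                "below_protocol": bool(arr.size < protocol_n),
            }
        )
    return pd.DataFrame(rows)


def _solve_components(
    mean_angles: Mapping[str, float], liquids: Sequence[ProbeLiquid]
) -> tuple:
    """Solve the linearised system; returns (x, y) = (sqrt g_d, sqrt g_p)."""
    design = np.array(
        [[np.sqrt(liq.gamma_d), np.sqrt(liq.gamma_p)] for liq in liquids]
    )
    rhs = np.array(
        [
            liq.gamma * (1.0 + np.cos(np.radians(mean_angles[liq.name]))) / 2.0
            for liq in liquids
        ]
    )
    if np.linalg.cond(design) > 1e8:
        names = ", ".join(liq.name for liq in liquids)
        raise SingularSystemError(
            f"probe liquids ({names}) are dispersively proportional; the "
            "Owens-Wendt system is singular"
        )
    if len(liquids) == 2:
        sol = np.linalg.solve(design, rhs)
    else:
        sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return float(sol[0]), float(sol[1])


def owens_wendt_solve(
    mean_angles: Mapping[str, float],
    liquids: Sequence[ProbeLiquid] = DEFAULT_LIQUIDS,
    label: str = "",
) -> SurfaceEnergyResult:
    """Solve (gamma_d, gamma_p, gamma_s) from per-liquid mean angles (deg).

    Exactly two liquids give an exact solve; more are combined by least
    squares on the same linearisation.  Negative square roots are clamped
    to zero and the result flagged infeasible.  The solution is invariant
    under the ordering of the liquids.
    """
    liquids = sorted(liquids, key=lambda liq: liq.name)
    missing = [liq.name for liq in liquids if liq.name not in mean_angles]
    if missing:
        raise SurfaceEnergyError(f"no mean angle supplied for {missing}")
    if len(liquids) < 2:
        raise SurfaceEnergyError("need at least two probe liquids to solve")
    x, y = _solve_components(mean_angles, liquids)
    infeasible = x < -1e-9 or y < -1e-9
    x, y = max(x, 0.0), max(y, 0.0)
    gd, gp = x * x, y * y
    return SurfaceEnergyResult(
        label=label,
        gamma_d=gd,
        gamma_p=gp,
        gamma_s=gd + gp,
        infeasible=infeasible,
    )


def surface_energy_from_drops(
    raw: ContactAngleSet,
    liquids: Sequence[ProbeLiquid] = DEFAULT_LIQUIDS,
    n_boot: int = 2000,
    seed: int = 0,
) -> SurfaceEnergyResult:
    """Aggregate drop angles, solve Owens-Wendt and bootstrap uncertainties.

    The parametric bootstrap redraws each liquid's drop angles from
    N(mean, sd) (equivalently the group mean from N(mean, sd/sqrt(n))),
    re-solves with clamping, and reports component standard deviations over
    ``n_boot`` seeded resamples.
    """
    agg = aggregate_angles(raw)
    means = dict(zip(agg["liquid"], agg["mean_deg"]))
    base = owens_wendt_solve(means, liquids, label=raw.label)
    base.per_liquid = agg
    rng = np.random.default_rng(seed)
    sds = dict(zip(agg["liquid"], agg["sd_deg"]))
    ns = dict(zip(agg["liquid"], agg["n"]))
    samples = np.empty((n_boot, 3))
    liq_sorted = sorted(liquids, key=lambda liq: liq.name)
    for b in range(n_boot):
        draw = {
            name: rng.normal(means[name], sds[name] / np.sqrt(ns[name]))
            for name in means
        }
        draw = {k: float(np.clip(v, 1e-6, 180.0 - 1e-6)) for k, v in draw.items()}
        try:
            x, y = _solve_components(draw, liq_sorted)
        except SingularSystemError:  # pragma: no cover - fixed design matrix
            continue
        gd, gp = max(x, 0.0) ** 2, max(y, 0.0) ** 2
        samples[b] = (gd, gp, gd + gp)
    base.gamma_d_sd = float(samples[:, 0].std(ddof=1))
    base.gamma_p_sd = float(samples[:, 1].std(ddof=1))
    base.gamma_s_sd = float(samples[:, 2].std(ddof=1))
    return base
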