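"""Calibrated default scenarios for the DPPC / coated-magnetite system.

These parameter sets define the reference study conditions the package is
tested against: a pure DPPC monolayer at 20 C with its LE-LC coexistence
plateau at (A_C = 0.77 nm^2, pi_C = 5 mN/m); binary films of DPPC with
starch-coated (Fe3O4-S) and aminated-starch-coated (Fe3O4-AS) magnetite
nanoparticles at weight fraction X_W = 0.36, expanded in the LE region by
0.19 and 0.14 nm^2 with plateau onsets at 12 and 10 mN/m and opposite-signed
high-pressure shifts (squeeze-out vs retention); penetration kinetics whose
6 h endpoints are ~4.2 (S) and 7.1 (AS) mN/m at an injection concentration of
3.5 ug/mL; and the native/aminated starch coating surfaces with
(gamma_d, gamma_p) = (28.8, 5.6) and (26.1, 18.0) mJ/m^2.

The oscillating-barrier series (20-140 mHz, 1% amplitude, baseline 30 mN/m)
uses a monotone composition table with the elastic modulus decreasing as the
nanoparticle fraction grows; the moduli values themselves are free model
choices of plausible magnitude for DPPC at 30 mN/m.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .synthetic import (
    IsothermModelParams,
    OscillationModelParams,
    PenetrationModelParams,
    SolidSurface,
)

__all__ = [
    "DPPC_ISOTHERM",
    "FE3O4_S_DPPC_036",
    "FE3O4_AS_DPPC_036",
    "ISOTHERM_SCENARIOS",
    "PENETRATION_FE3O4_S",
    "PENETRATION_FE3O4_AS",
    "PENETRATION_SCENARIOS",
    "STARCH",
    "AMINATED_STARCH",
    "SOLID_SCENARIOS",
    "RHEOLOGY_COMPOSITIONS",
    "RHEOLOGY_FREQUENCIES",
    "rheology_series",
]

#: Pure DPPC reference isotherm (20 C): plateau onset at 0.77 nm^2 / 5 mN/m.
DPPC_ISOTHERM = IsothermModelParams(
    lift_off_area=1.02,
    plateau_onset_area=0.77,
    plateau_onset_pressure=5.0,
    plateau_end_area=0.55,
    plateau_tilt=0.5,
    lc_slope=250.0,
    collapse_pressure=55.0,
    label="DPPC",
)

#: Starch-coated binary film, X_W = 0.36: LE expansion 0.19 nm^2, onset at
#: 12 mN/m, squeezed out at high pressure (negative condensed-branch shift).
FE3O4_S_DPPC_036 = replace(
    DPPC_ISOTHERM,
    plateau_onset_pressure=12.0,
    le_shift=0.19,
    lc_shift=-0.05,
    label="Fe3O4-S/DPPC",
    x_w=0.36,
)

#: Aminated-starch binary film, X_W = 0.36: LE expansion 0.14 nm^2, onset at
#: 10 mN/m, retained at high pressure (positive condensed-branch shift).
FE3O4_AS_DPPC_036 = replace(
    DPPC_ISOTHERM,
    plateau_onset_pressure=10.0,
    le_shift=0.14,
    lc_shift=0.05,
    label="Fe3O4-AS/DPPC",
    x_w=0.36,
)

ISOTHERM_SCENARIOS = {
    "dppc": DPPC_ISOTHERM,
    "fe3o4_s": FE3O4_S_DPPC_036,
    "fe3o4_as": FE3O4_AS_DPPC_036,
}

#: Penetration kinetics calibrated so delta-pi(360 min) reproduces the
#: 6 h endpoints (~4.2 and 7.1 mN/m) with a common rate of 0.01 /min.
PENETRATION_FE3O4_S = PenetrationModelParams(
    dpi_max=4.32, k_ads=0.01, label="Fe3O4-S"
)
PENETRATION_FE3O4_AS = PenetrationModelParams(
    dpi_max=7.3, k_ads=0.01, label="Fe3O4-AS"
)

PENETRATION_SCENARIOS = {
    "fe3o4_s": PENETRATION_FE3O4_S,
    "fe3o4_as": PENETRATION_FE3O4_AS,
}

#: Coating-polymer surfaces (mJ/m^2): native starch is weakly polar, the
#: aminated starch more than three times as polar.
STARCH = SolidSurface(gamma_d=28.8, gamma_p=5.6, label="starch")
AMINATED_STARCH = SolidSurface(gamma_d=26.1, gamma_p=18.0, label="aminated starch")

SOLID_SCENARIOS = {"starch": STARCH, "aminated_starch": AMINATED_STARCH}

#: (x_w, E' mN/m, E'' mN/m): elasticity drops with nanoparticle loading.
RHEOLOGY_COMPOSITIONS = (
    (0.00, 64.0, 10.0),
    (0.10, 58.0, 10.0),
    (0.21, 52.0, 9.5),
    (0.36, 45.0, 9.0),
)

#: Barrier oscillation frequencies, Hz (20-140 mHz protocol).
RHEOLOGY_FREQUENCIES = (0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14)


def rheology_series(
    frequencies: Sequence[float] = RHEOLOGY_FREQUENCIES,
    compositions: Sequence[tuple] = RHEOLOGY_COMPOSITIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """Oscillation parameter sets for the full composition x frequency grid."""
    out = []
    i = 0
    for x_w, ep, ev in compositions:
        for f in frequencies:
            out.append(
                OscillationModelParams(
                    e_prime=ep,
                    e_loss=ev,
                    frequency=f,
                    noise_sd=noise_sd,
                    seed=seed + i,
                    label=f"xw{x_w:.2f}",
                    x_w=x_w,
                )
            )
            i += 1
    return out
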