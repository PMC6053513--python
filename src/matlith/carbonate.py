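"""Carbonate-system speciation and calcite saturation state.

Given temperature, pH and total dissolved inorganic carbon
(TCO2 = CO2(aq)+H2CO3 + HCO3- + CO3--), partitions TCO2 among the three
species by mass action and computes the calcite saturation state
Omega = [Ca++][CO3--]/Ksp'.  Omega = 1 is equilibrium; Omega > 1 is
supersaturated.

Two named equilibrium-constant sets are provided:

``"freshwater"`` (default)
    Thermodynamic (zero-ionic-strength) constants: first and second
    carbonic-acid dissociation from the Harned & Davis (1943) and
    Harned & Scholes (1941) temperature fits, calcite solubility from the
    Plummer & Busenberg (1982) fit.  Appropriate for dilute spring and
    stream waters; concentrations approximate activities unless a Davies
    correction is requested.

``"seawater"``
    Stoichiometric (apparent) constants on a salinity grid: carbonic-acid
    constants from the Lueker, Dickson & Keeling (2000) refit of Mehrbach,
    calcite solubility from Mucci (1983).  These absorb seawater ion
    pairing into the constants, as the CO2SYS family of calculators does;
    ``salinity`` defaults to 35 for this set.

pH is taken as the meter reading (activity of H+); scale distinctions
(NBS vs total) are below the precision that matters in low-salinity water
and are not modelled.  Concentrations are treated as mol/L, interchangeable
with mol/kg-solution at these dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterChemistry",
    "EquilibriumConstants",
    "Speciation",
    "SaturationState",
    "CONSTANT_SETS",
    "equilibrium_constants",
    "davies_gamma",
    "speciate",
    "omega_calcite",
]

CONSTANT_SETS = ("freshwater", "seawater")


@dataclass(frozen=True)
class WaterChemistry:
    """Field measurements for one station.

    temperature_c in degrees Celsius, ph on the meter scale, tco2_mm and
    calcium_mm in mmol/L.
    """

    temperature_c: float
    ph: float
    tco2_mm: float
    calcium_mm: float = 0.0
    station: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.temperature_c < 100.0:
            raise ValueError(f"temperature {self.temperature_c} C outside (0, 100)")
        if not 0.0 < self.ph < 14.0:
            raise ValueError(f"pH {self.ph} outside (0, 14)")
        if self.tco2_mm <= 0:
            raise ValueError("TCO2 must be positive")
        if self.calcium_mm < 0:
            raise ValueError("calcium must be non-negative")


@dataclass(frozen=True)
class EquilibriumConstants:
    k1: float
    k2: float
    ksp_calcite: float
    constant_set: str
    salinity: float = 0.0


@dataclass(frozen=True)
class Speciation:
    co2_aq_mm: float
    hco3_mm: float
    co3_mm: float
    constants_used: str

    @property
    def tco2_mm(self) -> float:
        return self.co2_aq_mm + self.hco3_mm + self.co3_mm


@dataclass(frozen=True)
class SaturationState:
    omega: float
    ksp_prime: float
    co3_mm: float
    constants_used: str


def _freshwater_constants(t_kelvin: float) -> tuple[float, float, float]:
    # Harned & Davis (1943): log10 K1, pure water, 0-50 C fit
    log_k1 = -3404.71 / t_kelvin + 14.8435 - 0.032786 * t_kelvin
    # Harned & Scholes (1941): log10 K2
    log_k2 = -2902.39 / t_kelvin + 6.4980 - 0.02379 * t_kelvin
    # Plummer & Busenberg (1982): log10 Ksp calcite, 0-90 C
    log_ksp = (
        -171.9065
        - 0.077993 * t_kelvin
        + 2839.319 / t_kelvin
        + 71.595 * np.log10(t_kelvin)
    )
    return 10.0**log_k1, 10.0**log_k2, 10.0**log_ksp


def _seawater_constants(t_kelvin: float, salinity: float) -> tuple[float, float, float]:
    # Lueker et al. (2000), total scale, mol/kg-SW; valid S 19-43, T 2-35 C
    pk1 = (
        3633.86 / t_kelvin
        - 61.2172
        + 9.6777 * np.log(t_kelvin)
        - 0.011555 * salinity
        + 0.0001152 * salinity**2
    )
    pk2 = (
        471.78 / t_kelvin
        + 25.929
        - 3.16967 * np.log(t_kelvin)
        - 0.01781 * salinity
        + 0.0001122 * salinity**2
    )
    # Mucci (1983) stoichiometric calcite Ksp; reduces to Plummer & Busenberg
    # at S = 0
    log_ksp = (
        -171.9065
        - 0.077993 * t_kelvin
        + 2839.319 / t_kelvin
        + 71.595 * np.log10(t_kelvin)
        + (-0.77712 + 0.0028426 * t_kelvin + 178.34 / t_kelvin) * np.sqrt(salinity)
        - 0.07711 * salinity
        + 0.0041249 * salinity**1.5
    )
    return 10.0**-pk1, 10.0**-pk2, 10.0**log_ksp


def equilibrium_constants(
    temperature_c: float,
    constant_set: str = "freshwater",
    salinity: float | None = None,
) -> EquilibriumConstants:
    """Temperature-dependent K1, K2 and calcite Ksp for a named set."""
    if not 0.0 < temperature_c < 100.0:
        raise ValueError(f"temperature {temperature_c} C outside (0, 100)")
    t_kelvin = temperature_c + 273.15
    if constant_set == "freshwater":
        if salinity not in (None, 0, 0.0):
            raise ValueError("the freshwater set has no salinity dependence")
        k1, k2, ksp = _freshwater_constants(t_kelvin)
        salinity = 0.0
    elif constant_set == "seawater":
        salinity = 35.0 if salinity is None else float(salinity)
        if salinity <= 0:
            raise ValueError("the seawater set requires salinity > 0")
        k1, k2, ksp = _seawater_constants(t_kelvin, salinity)
    else:
        raise ValueError(
            f"unknown constant_set {constant_set!r}; choose from {CONSTANT_SETS}"
        )
    return EquilibriumConstants(
        k1=float(k1),
        k2=float(k2),
        ksp_calcite=float(ksp),
        constant_set=constant_set,
        salinity=float(salinity),
    )


def davies_gamma(charge: int, ionic_strength: float, a_coeff: float = 0.509) -> float:
    """Davies-equation single-ion activity coefficient.

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I); adequate for
    I below about 0.5 mol/L.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return 1.0
    sq = np.sqrt(ionic_strength)
    return float(
        10.0 ** (-a_coeff * charge**2 * (sq / (1.0 + sq) - 0.3 * ionic_strength))
    )


def speciate(
    water: WaterChemistry,
    constant_set: str = "freshwater",
    salinity: float | None = None,
    ionic_strength: float = 0.0,
) -> Speciation:
    """Partition TCO2 among CO2(aq), HCO3- and CO3-- at the measured pH.

    With ``ionic_strength`` > 0 (freshwater set only), Davies activity
    coefficients convert the thermodynamic constants to apparent ones so
    the returned values are concentrations; by default concentrations and
    activities are identified.
    """
    consts = equilibrium_constants(water.temperature_c, constant_set, salinity)
    k1, k2 = consts.k1, consts.k2
    if ionic_strength > 0:
        g1 = davies_gamma(1, ionic_strength)
        g2 = davies_gamma(2, ionic_strength)
        k1 = k1 / g1          # [HCO3]/[CO2] = K1' / aH with K1' = K1 * gCO2/gHCO3
        k2 = k2 * g1 / g2     # [CO3]/[HCO3] = K2' / aH with K2' = K2 * gHCO3/gCO3
    h = 10.0 ** (-water.ph)
    denom = h * h + h * k1 + k1 * k2
    return Speciation(
        co2_aq_mm=water.tco2_mm * h * h / denom,
        hco3_mm=water.tco2_mm * h * k1 / denom,
        co3_mm=water.tco2_mm * k1 * k2 / denom,
        constants_used=consts.constant_set,
    )


def omega_calcite(
    water: WaterChemistry,
    constant_set: str = "freshwater",
    salinity: float | None = None,
    ionic_strength: float = 0.0,
) -> SaturationState:
    """Calcite saturation state Omega = [Ca++][CO3--]/Ksp'.

    ``ksp_prime`` is the effective concentration-basis solubility product:
    for the freshwater set with a Davies correction it is
    Ksp / (gamma_Ca * gamma_CO3); for the seawater set it is the Mucci
    stoichiometric product itself.
    """
    if water.calcium_mm <= 0:
        raise ValueError("calcium concentration must be positive to compute Omega")
    consts = equilibrium_constants(water.temperature_c, constant_set, salinity)
    spec = speciate(water, constant_set, salinity, ionic_strength)
    ksp_prime = consts.ksp_calcite
    if ionic_strength > 0 and constant_set == "freshwater":
        g2 = davies_gamma(2, ionic_strength)
        ksp_prime = ksp_prime / (g2 * g2)
    ca = water.calcium_mm * 1e-3
    co3 = spec.co3_mm * 1e-3
    return SaturationState(
        omega=ca * co3 / ksp_prime,
        ksp_prime=ksp_prime,
        co3_mm=spec.co3_mm,
        constants_used=consts.constant_set,
    )
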