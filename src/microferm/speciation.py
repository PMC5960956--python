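"""Headspace/solution speciation of microcosm measurements.

Turns raw observations (headspace mixing ratios at known pressure and
temperature, dissolved concentrations from liquid chromatography, pH)
into total micromoles of each analyte normalized to gram fresh weight
of gut content.  Gases partition between headspace (ideal gas law) and
solution (Bunsen solubility); CO2 additionally carries a bicarbonate
pool from the first carbonic-acid dissociation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import (
    ATM_KPA,
    BUNSEN_SOLUBILITY_22C,
    CARBONIC_ACID_PKA1,
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT,
    MOLAR_VOLUME_STP_ML,
)


class SpeciationError(ValueError):
    pass


@dataclass(frozen=True)
class VialGeometry:
    """Sealed-vial dimensions and the fresh-weight normalization basis."""

    total_ml: float = 27.0
    liquid_ml: float = 10.0
    fresh_weight_g: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.liquid_ml < self.total_ml):
            raise SpeciationError("need 0 < liquid volume < total volume")
        if self.fresh_weight_g <= 0:
            raise SpeciationError("fresh weight must be positive")

    @property
    def headspace_ml(self) -> float:
        return self.total_ml - self.liquid_ml


@dataclass(frozen=True)
class GasObservation:
    time_h: float
    analyte: str
    mixing_ratio: float
    pressure_kpa: float
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_ratio <= 1.0:
            raise SpeciationError(f"mixing ratio out of [0,1]: {self.mixing_ratio}")
        if self.pressure_kpa <= 0 or self.temperature_k <= 0:
            raise SpeciationError("pressure and temperature must be positive")


@dataclass(frozen=True)
class LiquidObservation:
    time_h: float
    analyte: str
    concentration_mm: float
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.concentration_mm < 0:
            raise SpeciationError("concentration must be >= 0")
        if self.ph is not None and not (0.0 < self.ph < 14.0):
            raise SpeciationError(f"pH out of range: {self.ph}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Per-gas solubilities plus carbonate and gas-law constants."""

    solubility: dict[str, float] = field(default_factory=lambda: dict(BUNSEN_SOLUBILITY_22C))
    pka1: float = CARBONIC_ACID_PKA1
    gas_constant: float = GAS_CONSTANT
    reference_temperature_k: float = DEFAULT_TEMPERATURE_K

    def solubility_of(self, gas: str) -> float:
        try:
            return self.solubility[gas]
        except KeyError:
            raise SpeciationError(
                f"no solubility coefficient configured for gas {gas!r}"
            ) from None


DEFAULT_CONSTANTS = PhysicalConstants()


def headspace_amount(obs: GasObservation, geom: VialGeometry) -> float:
    """Micromoles of gas in the headspace from the ideal gas law.

    n = y * P * V_headspace / (R * T).
    """
    # kPa -> Pa (1e3), ml -> m3 (1e-6), mol -> umol (1e6): net factor 1e3.
    pascals = obs.pressure_kpa * 1e3
    cubic_m = geom.headspace_ml * 1e-6
    mol = obs.mixing_ratio * pascals * cubic_m / (obs.temperature_k * GAS_CONSTANT)
    return mol * 1e6


def dissolved_gas_amount(
    obs: GasObservation, geom: VialGeometry, k: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Micromoles of gas dissolved in the liquid phase at equilibrium.

    Bunsen coefficient alpha: ml of gas (STP) absorbed per ml of liquid
    under 1 atm partial pressure.
    """
    alpha = k.solubility_of(obs.analyte)
    partial_atm = obs.mixing_ratio * obs.pressure_kpa / ATM_KPA
    gas_ml_stp = alpha * partial_atm * geom.liquid_ml
    return gas_ml_stp / MOLAR_VOLUME_STP_ML * 1e6


def bicarbonate_amount(
    dissolved_co2_umol: float, ph: float, k: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Micromoles of bicarbonate in equilibrium with dissolved CO2.

    Henderson-Hasselbalch: HCO3- = CO2(aq) * 10^(pH - pKa1).  The second
    dissociation is neglected (valid for pH <= 8).
    """
    if dissolved_co2_umol < 0:
        raise SpeciationError("dissolved CO2 must be >= 0")
    return dissolved_co2_umol * math.pow(10.0, ph - k.pka1)


def total_amount_per_gfw(
    obs: GasObservation | LiquidObservation,
    geom: VialGeometry,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
    ph: float | None = None,
) -> float:
    """Total micromoles of the analyte per gram fresh weight.

    Gases: headspace + dissolved, plus bicarbonate for CO2 (pH required,
    never silently omitted).  Liquid analytes: concentration x liquid
    volume.
    """
    if isinstance(obs, GasObservation):
        total = headspace_amount(obs, geom) + dissolved_gas_amount(obs, geom, k)
        if obs.analyte == "CO2":
            if ph is None:
                raise SpeciationError(
                    "CO2 speciation requires pH for the bicarbonate pool"
                )
            dissolved = dissolved_gas_amount(obs, geom, k)
            total += bicarbonate_amount(dissolved, ph, k)
        return total / geom.fresh_weight_g
    # mM is umol/ml, so concentration x liquid volume is already umol.
    return obs.concentration_mm * geom.liquid_ml / geom.fresh_weight_g


def to_millimolar(amount_umol_per_gfw: float, geom: VialGeometry) -> float:
    """Convert umol/g_FW to mM in the microcosm liquid-equivalent volume.

    With the study geometry (10 ml per 1 g fresh weight) the factor is
    0.1: 100 umol/g_FW corresponds to 10 mM.
    """
    return amount_umol_per_gfw * geom.fresh_weight_g / geom.liquid_ml


def from_millimolar(concentration_mm: float, geom: VialGeometry) -> float:
    """Inverse of :func:`to_millimolar`."""
    return concentration_mm * geom.liquid_ml / geom.fresh_weight_g


MEASUREMENT_COLUMNS = [
    "microcosm_id",
    "treatment",
    "replicate",
    "time_h",
    "analyte",
    "phase",
    "value",
    "unit",
    "pressure_kPa",
    "temperature_K",
    "pH",
]


def speciate_table(
    measurements: pd.DataFrame,
    geom: VialGeometry,
    k: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Speciate a tidy measurement table into per-analyte umol/g_FW.

    Input rows follow the measurement schema (one observation per row,
    ``phase`` in {headspace, liquid}, ``unit`` in {mol_fraction, mM}).
    Returns one row per (treatment, replicate, time_h, analyte) with the
    column ``umol_per_gfw``.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise SpeciationError(f"measurement table lacks columns: {missing}")

    records = []
    for _, row in measurements.iterrows():
        if row["phase"] == "headspace":
            if row["unit"] != "mol_fraction":
                raise SpeciationError(
                    f"headspace rows must be mol_fraction, got {row['unit']!r}"
                )
            obs: GasObservation | LiquidObservation = GasObservation(
                time_h=row["time_h"],
                analyte=row["analyte"],
                mixing_ratio=row["value"],
                pressure_kpa=row["pressure_kPa"],
                temperature_k=row["temperature_K"],
            )
            ph = row["pH"] if pd.notna(row["pH"]) else None
        elif row["phase"] == "liquid":
            if row["unit"] != "mM":
                raise SpeciationError(f"liquid rows must be mM, got {row['unit']!r}")
            obs = LiquidObservation(
                time_h=row["time_h"],
                analyte=row["analyte"],
                concentration_mm=row["value"],
                ph=row["pH"] if pd.notna(row["pH"]) else None,
            )
            ph = None
        else:
            raise SpeciationError(f"unknown phase {row['phase']!r}")
        amount = total_amount_per_gfw(obs, geom, k, ph=ph)
        records.append(
            {
                "treatment": row["treatment"],
                "replicate": row["replicate"],
                "time_h": row["time_h"],
                "analyte": row["analyte"],
                "umol_per_gfw": amount,
            }
        )
    return pd.DataFrame.from_records(records)
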