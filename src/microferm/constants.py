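"""Physical and chemical constants used across the package.

All values live in this single table so that reproducibility-sensitive
numbers (atomic weights, solubilities, dissociation constants) have one
authoritative home.
"""

from __future__ import annotations

# IUPAC 2021 conventional (abridged) standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
}

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.31446

#: Standard atmosphere, kPa.
ATM_KPA = 101.325

#: Molar volume of an ideal gas at 0 degC / 1 atm, ml/mol (Bunsen reference).
MOLAR_VOLUME_STP_ML = 22414.0

#: First dissociation pKa of carbonic acid (freshwater, 25 degC).
CARBONIC_ACID_PKA1 = 6.35

#: Default incubation temperature, K (22 degC, midpoint of the 21-24 degC range).
DEFAULT_TEMPERATURE_K = 295.15

#: Default headspace absolute pressure, kPa (60 kPa N2 overpressure + 1 atm).
DEFAULT_PRESSURE_KPA = 161.325

# Bunsen-style solubility coefficients near 22 degC (ml gas at STP dissolved
# per ml water per atm partial pressure).  CO2 ~0.85 and H2 ~0.017 bracket the
# ~50x solubility contrast between the two gases at lab temperature.
BUNSEN_SOLUBILITY_22C: dict[str, float] = {
    "CO2": 0.85,
    "H2": 0.017,
    "CH4": 0.034,
    "N2": 0.0155,
    "O2": 0.030,
}
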