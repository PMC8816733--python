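"""Packaged reference data: acetylsalicylic acid in ethanol + water.

This module ships the published study dataset the package is exercised on:
shake-flask molar solubilities of acetylsalicylic acid (ASA, aspirin) in
eleven ethanol + water mixtures at 298.15 and 310.15 K, together with the
salicylic acid (hydrolysis product) concentrations measured in the same
saturated solutions, DSC fusion properties, PC-SAFT pure-component
parameters, HPLC calibration lines and published cosolvency-model constants.
"""

from __future__ import annotations

from .data_model import (
    ETHANOL_WATER,
    AbrahamSoluteDescriptors,
    FusionProperties,
    SolubilityDataset,
    SolubilityRecord,
)

__all__ = [
    "aspirin_ethanol_water",
    "ASPIRIN_MOLAR_MASS",
    "SALICYLIC_ACID_MOLAR_MASS",
    "ASPIRIN_LOGP",
    "ASPIRIN_ABRAHAM",
    "ASPIRIN_FUSION",
    "ASPIRIN_FUSION_BY_SAMPLE",
    "SALICYLIC_SATURATION_25C",
    "CRYSTALLINITY_REFERENCE",
]

ASPIRIN_MOLAR_MASS = 180.16  # g/mol
SALICYLIC_ACID_MOLAR_MASS = 138.12  # g/mol
ASPIRIN_LOGP = 1.18  # octanol/water, DrugBank

#: Abraham solvation descriptors (E, S, A, B, V) of acetylsalicylic acid.
ASPIRIN_ABRAHAM = AbrahamSoluteDescriptors(E=0.84, S=1.42, A=0.57, B=0.77, V=1.29)

#: DSC fusion properties of ASA crystals: untreated drug and solids recovered
#: after equilibration with 0, 50 and 100 % ethanol at each temperature.
#: Keys are (sample label, measurement temperature in K); peak melting points
#: in Celsius and specific enthalpies in J/g converted to molar units.
ASPIRIN_FUSION_BY_SAMPLE: dict[tuple[str, float], FusionProperties] = {
    ("untreated", 298.15): FusionProperties.from_specific(145.3, 165.6, ASPIRIN_MOLAR_MASS),
    ("untreated", 310.15): FusionProperties.from_specific(145.3, 165.6, ASPIRIN_MOLAR_MASS),
    ("water", 298.15): FusionProperties.from_specific(142.9, 147.7, ASPIRIN_MOLAR_MASS),
    ("water", 310.15): FusionProperties.from_specific(137.8, 130.7, ASPIRIN_MOLAR_MASS),
    ("50:50", 298.15): FusionProperties.from_specific(141.3, 139.5, ASPIRIN_MOLAR_MASS),
    ("50:50", 310.15): FusionProperties.from_specific(144.4, 161.0, ASPIRIN_MOLAR_MASS),
    ("ethanol", 298.15): FusionProperties.from_specific(143.7, 156.2, ASPIRIN_MOLAR_MASS),
    ("ethanol", 310.15): FusionProperties.from_specific(144.3, 155.4, ASPIRIN_MOLAR_MASS),
}

#: Default fusion properties: the untreated drug (Tm = 418.45 K,
#: dHm = 165.6 J/g * 180.16 g/mol = 29834.5 J/mol).
ASPIRIN_FUSION = ASPIRIN_FUSION_BY_SAMPLE[("untreated", 298.15)]

# Molar solubility of ASA, mol/L: (f1, C at 298.15 K, sd, C at 310.15 K, sd).
_ASA_ROWS = [
    (0.00, 2.46e-2, 0.06e-2, 3.08e-2, 0.00e-2),
    (0.10, 3.47e-2, 0.11e-2, 5.22e-2, 0.01e-2),
    (0.20, 5.92e-2, 0.25e-2, 1.01e-1, 0.00e-1),
    (0.30, 1.28e-1, 0.00e-1, 2.04e-1, 0.04e-1),
    (0.40, 2.71e-1, 0.05e-1, 4.09e-1, 0.03e-1),
    (0.50, 4.31e-1, 0.02e-1, 6.71e-1, 0.08e-1),
    (0.60, 5.46e-1, 0.14e-1, 8.16e-1, 0.92e-1),
    (0.70, 6.82e-1, 0.03e-1, 9.95e-1, 0.16e-1),
    (0.80, 7.77e-1, 0.02e-1, 1.06, 0.19),
    (0.90, 8.68e-1, 0.52e-1, 1.13, 0.08),
    (1.00, 8.26e-1, 0.23e-1, 9.88e-1, 0.02e-1),
]

# Salicylic acid measured in the ASA-saturated solutions, mol/L.
_SA_ROWS = [
    (0.00, 7.26e-4, 0.12e-4, 3.20e-3, 0.13e-3),
    (0.10, 8.78e-4, 0.63e-4, 4.47e-3, 0.25e-3),
    (0.20, 1.04e-3, 0.09e-3, 7.78e-3, 0.60e-3),
    (0.30, 1.95e-3, 0.00e-3, 1.84e-2, 0.00e-2),
    (0.40, 1.86e-3, 0.00e-3, 3.24e-2, 0.00e-2),
    (0.50, 2.98e-3, 0.00e-3, 4.31e-2, 0.00e-2),
    (0.60, 3.16e-3, 0.00e-3, 4.52e-2, 0.00e-2),
    (0.70, 3.67e-3, 0.05e-3, 5.33e-2, 0.00e-2),
    (0.80, 3.28e-3, 0.73e-3, 5.52e-2, 0.44e-2),
    (0.90, 3.73e-3, 0.00e-3, 4.94e-2, 0.01e-2),
    (1.00, 3.38e-3, 0.52e-3, 5.24e-2, 0.01e-2),
]

#: Literature saturation solubility of salicylic acid itself in ethanol +
#: water at 298.15 K, mol/L, on the same f1 grid (reference values used by the
#: undersaturation check).
SALICYLIC_SATURATION_25C = [
    1.37e-2, 1.73e-2, 3.24e-2, 8.09e-2, 2.10e-1, 4.81e-1,
    9.62e-1, 1.38, 1.84, 2.21, 2.11,
]

#: Percent crystallinity of recovered ASA solids (sample -> {T_K: %});
#: reference values only, raw diffractogram areas are not distributed.
CRYSTALLINITY_REFERENCE = {
    "original": {298.15: 44.3, 310.15: 44.3},
    "water": {298.15: 32.3, 310.15: 23.1},
    "ethanol": {298.15: 35.5, 310.15: 40.7},
    "50:50": {298.15: 33.6, 310.15: 42.8},
}


def aspirin_ethanol_water() -> SolubilityDataset:
    """The packaged ASA / ethanol + water study dataset.

    Returns 44 records: molar solubility of acetylsalicylic acid (analyte
    ``primary_solute``) and the co-measured salicylic acid concentration
    (analyte ``degradation_product``) on the f1 grid 0.00-1.00 (step 0.10) at
    298.15 K and 310.15 K.
    """
    records = []
    for f1, c25, sd25, c37, sd37 in _ASA_ROWS:
        records.append(SolubilityRecord(f1, 298.15, c25, sd25, "primary_solute"))
        records.append(SolubilityRecord(f1, 310.15, c37, sd37, "primary_solute"))
    for f1, c25, sd25, c37, sd37 in _SA_ROWS:
        records.append(SolubilityRecord(f1, 298.15, c25, sd25, "degradation_product"))
        records.append(SolubilityRecord(f1, 310.15, c37, sd37, "degradation_product"))
    return SolubilityDataset(
        system=ETHANOL_WATER,
        records=tuple(records),
        solute_name="acetylsalicylic acid",
        solute_molar_mass=ASPIRIN_MOLAR_MASS,
        solute_logP=ASPIRIN_LOGP,
    )
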