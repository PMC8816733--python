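"""Domain types and I/O for solubility data in binary aqueous-cosolvent mixtures.

The central container is :class:`SolubilityDataset`: molar solubilities of one
solute measured over a grid of cosolvent volume fractions ``f1`` (solute-free
basis) at one or more absolute temperatures.  Solvent metadata (densities,
molar masses) lives in :class:`SolventSystem` so that molarity/mole-fraction
conversions are explicit about the densities they use.

All temperatures are stored in Kelvin, concentrations in mol/L, densities in
g/cm^3 and molar masses in g/mol.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, SchemaError, ValidationError

__all__ = [
    "R",
    "CELSIUS_OFFSET",
    "ANALYTES",
    "SolventSystem",
    "SolubilityRecord",
    "SolubilityDataset",
    "FusionProperties",
    "AbrahamSoluteDescriptors",
    "ETHANOL_WATER",
    "load_dataset",
    "write_dataset",
    "molar_to_mole_fraction",
]

#: Molar gas constant, J/(mol K).
R = 8.31446261815324

CELSIUS_OFFSET = 273.15

#: Allowed values of the ``analyte`` column: the solute itself, or a
#: degradation product followed alongside it (e.g. salicylic acid formed by
#: hydrolysis of acetylsalicylic acid).
ANALYTES = ("primary_solute", "degradation_product")

#: Required CSV columns for :func:`load_dataset` / :func:`write_dataset`.
CSV_COLUMNS = ("f1", "T_C", "C_molar", "sd", "analyte")


@dataclass(frozen=True)
class SolventSystem:
    """A binary solvent pair: cosolvent (component 1) + water (component 2).

    Densities are pure-liquid densities per temperature (K -> g/cm^3); they are
    only consulted when converting between molarity and mole fraction or
    between volume and mole fractions of the solvent mixture.
    """

    cosolvent_name: str
    water_name: str
    cosolvent_density: Mapping[float, float]
    water_density: Mapping[float, float]
    cosolvent_molar_mass: float
    water_molar_mass: float

    def __post_init__(self) -> None:
        if self.cosolvent_molar_mass <= 0 or self.water_molar_mass <= 0:
            raise ValidationError("molar masses must be positive")
        for table in (self.cosolvent_density, self.water_density):
            if not table:
                raise ValidationError("density table must not be empty")
            if any(v <= 0 for v in table.values()):
                raise ValidationError("densities must be positive")

    def densities_at(self, T: float) -> tuple[float, float]:
        """Pure-liquid (cosolvent, water) densities at ``T`` in g/cm^3.

        Exact table entries are returned as-is; otherwise the tables are
        linearly interpolated (and clamped at the tabulated extremes).
        """
        out = []
        for table in (self.cosolvent_density, self.water_density):
            if T in table:
                out.append(table[T])
            else:
                temps = np.array(sorted(table))
                out.append(float(np.interp(T, temps, [table[t] for t in temps])))
        return out[0], out[1]


#: Default ethanol + water system.  Pure-liquid densities at 298.15/310.15 K
#: are standard literature values; molar masses are fixed constants.
ETHANOL_WATER = SolventSystem(
    cosolvent_name="ethanol",
    water_name="water",
    cosolvent_density={298.15: 0.78522, 310.15: 0.77641},
    water_density={298.15: 0.99705, 310.15: 0.99333},
    cosolvent_molar_mass=46.07,
    water_molar_mass=18.015,
)


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured point: solvent composition, temperature, molar solubility."""

    f1: float
    T: float
    C: float
    sd: float = 0.0
    analyte: str = "primary_solute"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f1 <= 1.0:
            raise ValidationError(f"f1={self.f1} outside [0, 1]")
        if self.T <= 0:
            raise ValidationError(f"T={self.T} K must be positive")
        if self.C <= 0:
            raise ValidationError(f"C={self.C} mol/L must be positive")
        if self.sd < 0:
            raise ValidationError(f"sd={self.sd} must be non-negative")
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")

    @property
    def f2(self) -> float:
        """Water volume fraction (solute-free basis)."""
        return 1.0 - self.f1


@dataclass(frozen=True)
class FusionProperties:
    """Melting temperature (K) and molar fusion enthalpy (J/mol) of the solute."""

    Tm: float
    dHm: float

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValidationError("Tm must be positive")
        if self.dHm <= 0:
            raise ValidationError("dHm must be positive")

    @classmethod
    def from_specific(cls, Tm_celsius: float, dH_J_per_g: float, molar_mass: float) -> "FusionProperties":
        """Build from a DSC melting point in Celsius and a specific enthalpy in J/g."""
        return cls(Tm=Tm_celsius + CELSIUS_OFFSET, dHm=dH_J_per_g * molar_mass)


@dataclass(frozen=True)
class AbrahamSoluteDescriptors:
    """Abraham solvation descriptors of a solute.

    E: excess molar refraction; S: dipolarity/polarizability; A/B: hydrogen
    bond acidity/basicity; V: McGowan characteristic volume.
    """

    E: float
    S: float
    A: float
    B: float
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValidationError("McGowan volume V must be positive")

    def as_vector(self) -> np.ndarray:
        """The descriptor vector (1, E, S, A, B, V) used by trained models."""
        return np.array([1.0, self.E, self.S, self.A, self.B, self.V])


@dataclass(frozen=True)
class SolubilityDataset:
    """A set of solubility records for one solute in one binary solvent system."""

    system: SolventSystem
    records: tuple[SolubilityRecord, ...]
    solute_name: str = ""
    solute_molar_mass: float = float("nan")
    solute_logP: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        keys = [(r.f1, r.T, r.analyte) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (f1, T, analyte) keys: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def temperatures(self, analyte: str = "primary_solute") -> tuple[float, ...]:
        return tuple(sorted({r.T for r in self.records if r.analyte == analyte}))

    def subset(
        self,
        T: float | None = None,
        analyte: str = "primary_solute",
        f1_values: Sequence[float] | None = None,
    ) -> "SolubilityDataset":
        """Restrict to one analyte and optionally one temperature / f1 subset."""
        recs = [r for r in self.records if r.analyte == analyte]
        if T is not None:
            recs = [r for r in recs if np.isclose(r.T, T)]
        if f1_values is not None:
            recs = [r for r in recs if any(np.isclose(r.f1, f) for f in f1_values)]
        return dataclasses.replace(self, records=tuple(recs))

    def lookup(self, f1: float, T: float, analyte: str = "primary_solute") -> SolubilityRecord:
        for r in self.records:
            if r.analyte == analyte and np.isclose(r.f1, f1) and np.isclose(r.T, T):
                return r
        raise KeyError(f"no record (f1={f1}, T={T}, analyte={analyte})")

    def water_solubility(self, T: float, analyte: str = "primary_solute") -> float:
        """Neat-water anchor C2 = C(f1=0) at temperature ``T``."""
        return self.lookup(0.0, T, analyte).C

    def cosolvent_solubility(self, T: float, analyte: str = "primary_solute") -> float:
        """Neat-cosolvent anchor C1 = C(f1=1) at temperature ``T``."""
        return self.lookup(1.0, T, analyte).C

    def require_anchors(self, analyte: str = "primary_solute") -> None:
        """Check both neat-solvent anchors exist at every temperature."""
        from .exceptions import AnchorMissingError

        for T in self.temperatures(analyte):
            for f1 in (0.0, 1.0):
                try:
                    self.lookup(f1, T, analyte)
                except KeyError:
                    raise AnchorMissingError(
                        f"missing neat-solvent anchor f1={f1} at T={T} K"
                    ) from None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns f1, T_C, C_molar, sd, analyte."""
        return pd.DataFrame(
            {
                "f1": [r.f1 for r in self.records],
                "T_C": [r.T - CELSIUS_OFFSET for r in self.records],
                "C_molar": [r.C for r in self.records],
                "sd": [r.sd for r in self.records],
                "analyte": [r.analyte for r in self.records],
            }
        )


def load_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    system: SolventSystem = ETHANOL_WATER,
    solute_name: str = "",
    solute_molar_mass: float = float("nan"),
    solute_logP: float = float("nan"),
) -> SolubilityDataset:
    """Read a solubility dataset from CSV.

    The expected columns are ``f1, T_C, C_molar, sd, analyte`` (temperature in
    Celsius; converted to Kelvin on load).  ``schema`` optionally maps those
    canonical names to the column names actually present in the file.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ParseError
        For an empty file or a non-numeric cell (the row index is reported).
    ValidationError
        For out-of-range values or duplicate (f1, T, analyte) keys.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    mapping = {canon: (schema or {}).get(canon, canon) for canon in CSV_COLUMNS}
    missing = [col for col in mapping.values() if col not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    records = []
    for idx, row in raw.iterrows():
        numeric = {}
        for canon in ("f1", "T_C", "C_molar", "sd"):
            cell = row[mapping[canon]]
            try:
                numeric[canon] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} in column "
                    f"{mapping[canon]!r}, row {idx}"
                ) from exc
        records.append(
            SolubilityRecord(
                f1=numeric["f1"],
                T=numeric["T_C"] + CELSIUS_OFFSET,
                C=numeric["C_molar"],
                sd=numeric["sd"],
                analyte=str(row[mapping["analyte"]]).strip(),
            )
        )
    return SolubilityDataset(
        system=system,
        records=tuple(records),
        solute_name=solute_name,
        solute_molar_mass=solute_molar_mass,
        solute_logP=solute_logP,
    )


def write_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset to CSV in the canonical schema.

    Floats are written with ``repr`` so that a read/write round trip
    reproduces every numeric field bit-identically.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for r in dataset.records:
            fh.write(
                f"{r.f1!r},{r.T - CELSIUS_OFFSET!r},{r.C!r},{r.sd!r},{r.analyte}\n"
            )


def molar_to_mole_fraction(
    C: float,
    solution_density: float,
    f1: float,
    system: SolventSystem = ETHANOL_WATER,
    solute_molar_mass: float = 180.16,
    T: float = 298.15,
) -> float:
    """Convert a molar solubility to a mole fraction.

    A litre of saturated solution of density ``solution_density`` (g/cm^3)
    contains ``C`` moles of solute; the remaining mass is solvent, split
    between cosolvent and water according to the solute-free volume fraction
    ``f1`` using pure-liquid densities at ``T``.

    Raises :class:`DomainError` if the implied solvent mass is negative.
    """
    if solution_density <= 0:
        raise DomainError("solution density must be positive")
    if not 0.0 <= f1 <= 1.0:
        raise DomainError("f1 outside [0, 1]")
    if C < 0:
        raise DomainError("C must be non-negative")
    if C == 0:
        return 0.0
    total_mass = 1000.0 * solution_density  # g per litre of solution
    solute_mass = C * solute_molar_mass
    solvent_mass = total_mass - solute_mass
    if solvent_mass <= 0:
        raise DomainError(
            f"density {solution_density} g/cm^3 implies non-positive solvent mass"
        )
    rho1, rho2 = system.densities_at(T)
    w1 = f1 * rho1 / (f1 * rho1 + (1.0 - f1) * rho2)
    n1 = solvent_mass * w1 / system.cosolvent_molar_mass
    n2 = solvent_mass * (1.0 - w1) / system.water_molar_mass
    return C / (C + n1 + n2)
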