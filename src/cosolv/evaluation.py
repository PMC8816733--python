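"""Model scoring and profile diagnostics.

The headline statistic is the mean relative deviation percent,

    MRD% = (100 / N) * sum |calculated - observed| / observed,

computed on the linear concentration scale.  Reports carry both the pooled
MRD% over all points and the per-temperature values (whose mean differs from
the pooled value when group sizes differ).

Also here: the solubility-peak locator, the percent-crystallinity index from
diffraction peak areas, and the undersaturation check for a degradation
product measured alongside the solute.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CELSIUS_OFFSET, SolubilityDataset
from .exceptions import AlignmentError, DomainError

__all__ = [
    "mrd_percent",
    "PredictionReport",
    "evaluate_model",
    "evaluate_aligned",
    "solubility_peak",
    "DiffractionPeakAreas",
    "crystallinity_percent",
    "diffractogram_crystallinity",
    "undersaturation_check",
]


def mrd_percent(calculated, observed) -> float:
    """Mean relative deviation percent between two aligned positive vectors."""
    calc = np.asarray(calculated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if calc.shape != obs.shape or calc.ndim != 1 or calc.size == 0:
        raise DomainError("calculated and observed must be equal-length 1-D vectors")
    if np.any(obs <= 0):
        raise DomainError("observed values must be positive")
    return float(100.0 / calc.size * np.sum(np.abs(calc - obs) / obs))


@dataclass(frozen=True)
class PredictionReport:
    """Aligned observed/calculated solubilities with deviation summaries."""

    model: str
    records: pd.DataFrame = field(repr=False)
    mrd_by_temperature: dict[float, float]
    mrd_overall: float
    mrd_mean_of_temperatures: float

    def summary(self) -> dict:
        return {
            "model": self.model,
            "n_points": int(len(self.records)),
            "mrd_overall_percent": round(self.mrd_overall, 1),
            "mrd_mean_of_temperatures_percent": round(self.mrd_mean_of_temperatures, 1),
            "mrd_by_temperature_percent": {
                f"{t - CELSIUS_OFFSET:g}C": round(v, 1)
                for t, v in self.mrd_by_temperature.items()
            },
        }


def evaluate_aligned(
    f1, T, observed, calculated, model: str = ""
) -> PredictionReport:
    """Build a report from already-aligned observation/prediction vectors."""
    f1 = np.asarray(f1, dtype=float)
    T = np.asarray(T, dtype=float)
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if not (f1.shape == T.shape == obs.shape == calc.shape):
        raise AlignmentError("f1, T, observed and calculated must be aligned 1-D vectors")
    records = pd.DataFrame(
        {
            "f1": f1,
            "T": T,
            "observed": obs,
            "calculated": calc,
            "rel_dev": np.abs(calc - obs) / obs,
        }
    )
    by_T = {
        float(t): mrd_percent(g["calculated"], g["observed"])
        for t, g in records.groupby("T")
    }
    return PredictionReport(
        model=model,
        records=records,
        mrd_by_temperature=by_T,
        mrd_overall=mrd_percent(calc, obs),
        mrd_mean_of_temperatures=float(np.mean(list(by_T.values()))),
    )


def evaluate_model(
    dataset: SolubilityDataset,
    predictor: Callable[[float, float], float],
    model: str = "",
    analyte: str = "primary_solute",
) -> PredictionReport:
    """Score a fitted/configured model against a dataset.

    ``predictor`` maps (f1, T) to a calculated solubility on the same
    concentration scale as the dataset.
    """
    recs = dataset.subset(analyte=analyte).records
    if not recs:
        raise DomainError("no records to evaluate")
    f1 = np.array([r.f1 for r in recs])
    T = np.array([r.T for r in recs])
    obs = np.array([r.C for r in recs])
    calc = np.array([float(predictor(r.f1, r.T)) for r in recs])
    return evaluate_aligned(f1, T, obs, calc, model=model)


def solubility_peak(
    dataset: SolubilityDataset, T: float, analyte: str = "primary_solute"
) -> tuple[float, ...]:
    """The f1 value(s) of maximum observed solubility at temperature ``T``.

    Returns all tied maximisers (ties at exact equality of C).
    """
    recs = dataset.subset(T=T, analyte=analyte).records
    if len(recs) < 2:
        raise DomainError(f"need >= 2 records at T={T} K")
    cmax = max(r.C for r in recs)
    return tuple(sorted(r.f1 for r in recs if r.C == cmax))


@dataclass(frozen=True)
class DiffractionPeakAreas:
    """Integrated crystalline-reflection area and total diffractogram area."""

    crystalline_area: float
    total_area: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.crystalline_area <= self.total_area:
            raise DomainError("need 0 <= crystalline_area <= total_area")


def crystallinity_percent(areas: DiffractionPeakAreas) -> float:
    """Percent crystallinity: 100 * crystalline area / total area."""
    if areas.total_area == 0:
        raise DomainError("total area is zero")
    return 100.0 * areas.crystalline_area / areas.total_area


def diffractogram_crystallinity(
    two_theta,
    intensity,
    peak_positions: Sequence[float] = (7.8, 15.6),
    half_width: float = 0.5,
) -> DiffractionPeakAreas:
    """Integrate designated crystalline reflections out of a diffractogram.

    Each crystalline window is ``position +/- half_width`` degrees 2-theta;
    a straight baseline through the window edges (the amorphous halo) is
    subtracted before trapezoidal integration.  The total area integrates the
    whole trace above zero.
    """
    tt = np.asarray(two_theta, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if tt.shape != y.shape or tt.ndim != 1:
        raise DomainError("two_theta and intensity must be aligned 1-D arrays")
    total = float(np.trapezoid(y, tt))
    crystalline = 0.0
    for pos in peak_positions:
        mask = (tt >= pos - half_width) & (tt <= pos + half_width)
        if not np.any(mask):
            raise DomainError(f"window around {pos} deg outside the scan range")
        seg_t, seg_y = tt[mask], y[mask]
        baseline = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_y[0], seg_y[-1]])
        crystalline += float(np.trapezoid(seg_y - baseline, seg_t))
    crystalline = min(max(crystalline, 0.0), total)
    return DiffractionPeakAreas(crystalline_area=crystalline, total_area=total)


def undersaturation_check(measured, saturation_reference, f1=None) -> np.ndarray:
    """Flag where a degradation product stays strictly below its own solubility.

    ``measured`` and ``saturation_reference`` must be aligned (optionally on
    an explicit f1 grid); returns a boolean array, True where measured <
    reference.
    """
    m = np.asarray(measured, dtype=float)
    ref = np.asarray(saturation_reference, dtype=float)
    if m.shape != ref.shape:
        raise AlignmentError("measured and reference series are not aligned")
    if f1 is not None:
        f1 = np.asarray(f1, dtype=float)
        if f1.shape != m.shape:
            raise AlignmentError("f1 grid does not match the series")
    return m < ref
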