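"""HPLC calibration lines and inverse prediction of concentrations.

A calibration line relates detector peak area linearly to analyte
concentration (mg/L).  Saturated samples are diluted before injection, so the
inverse prediction multiplies the back-calculated concentration by the
dilution factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DegenerateDesignError, ExtrapolationWarning, QuantitationError

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "quantify",
    "mg_per_l_to_molar",
    "ASPIRIN_CALIBRATION",
    "SALICYLIC_CALIBRATION",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A straight-line detector response: area = slope * C + intercept.

    ``valid_range`` is the concentration range (mg/L) spanned by the
    calibration standards; predictions outside it warn by default.
    """

    slope: float
    intercept: float
    valid_range: tuple[float, float]
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DegenerateDesignError("calibration slope must be nonzero")
        lo, hi = self.valid_range
        if not lo < hi:
            raise DegenerateDesignError("valid_range low must be below high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valid_range"] = list(self.valid_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            valid_range=tuple(d["valid_range"]),
            analyte=d.get("analyte", ""),
        )


#: Published calibration line for acetylsalicylic acid, 10-1000 mg/L.
ASPIRIN_CALIBRATION = CalibrationCurve(3336.8, 181813.0, (10.0, 1000.0), "acetylsalicylic acid")
#: Published calibration line for salicylic acid, 0.5-20 mg/L.
SALICYLIC_CALIBRATION = CalibrationCurve(39158.0, 14652.0, (0.5, 20.0), "salicylic acid")


def fit_calibration(
    concentrations,
    areas,
    analyte: str = "",
    force_line: bool = False,
) -> CalibrationCurve:
    """Fit an ordinary least-squares line area ~ concentration.

    At least three distinct concentrations are required unless ``force_line``
    is set, in which case exactly two distinct levels are accepted (the line
    through two points).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(areas, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise DegenerateDesignError("concentrations and areas must be 1-D and aligned")
    n_distinct = len(np.unique(c))
    if n_distinct < 2:
        raise DegenerateDesignError("all calibration concentrations are identical")
    if n_distinct < 3 and not force_line:
        raise DegenerateDesignError(
            "need >= 3 distinct concentration levels (or force_line=True with 2)"
        )
    slope, intercept = np.polyfit(c, a, 1)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(c.min()), float(c.max())),
        analyte=analyte,
    )


def quantify(
    area: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    strict: bool = False,
) -> float:
    """Back-calculate a sample concentration (mg/L) from a peak area.

    Returns ``dilution_factor * (area - intercept) / slope``.  The range check
    applies to the injected (undiluted) concentration; out-of-range values
    warn (:class:`ExtrapolationWarning`) or raise when ``strict``.
    """
    if dilution_factor < 1.0:
        raise QuantitationError("dilution factor must be >= 1")
    injected = (area - curve.intercept) / curve.slope
    if injected < 0:
        raise QuantitationError(
            f"area {area} back-calculates to negative concentration {injected:.4g} mg/L"
        )
    lo, hi = curve.valid_range
    tol = 1e-9 * (hi - lo)  # keep exact-boundary points in range despite roundoff
    if not lo - tol <= injected <= hi + tol:
        msg = (
            f"back-calculated concentration {injected:.4g} mg/L outside the "
            f"calibrated range [{lo}, {hi}] mg/L"
        )
        if strict:
            raise QuantitationError(msg)
        if injected > 0:
            warnings.warn(msg, ExtrapolationWarning, stacklevel=2)
    return dilution_factor * injected


def mg_per_l_to_molar(concentration_mg_per_l: float, molar_mass: float) -> float:
    """Convert mg/L to mol/L using the analyte molar mass (g/mol)."""
    if molar_mass <= 0:
        raise QuantitationError("molar mass must be positive")
    return concentration_mg_per_l / 1000.0 / molar_mass
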