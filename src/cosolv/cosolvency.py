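"""Algebraic cosolvency models for solubility in binary solvent mixtures.

Four model families are implemented, all working on the molar concentration
scale of the dataset they are applied to:

* **Log-linear (Yalkowsky)** — ``ln Cm = ln C2 + sigma * f1`` where ``sigma``
  is the solubilization power of the cosolvent, either measured from the two
  neat-solvent solubilities (``sigma = ln(C1/C2)``) or predicted from the
  solute's log P via cosolvent constants M, N (``sigma = M log P + N``).
* **Jouyban-Acree** — a fraction-weighted blend of the neat-solvent
  solubilities plus temperature-scaled Redlich-Kister-type mixing terms::

      ln Cm(T) = f1 ln C1(T) + f2 ln C2(T) + (f1 f2 / T) * sum_i Ji (f1-f2)^i

  The ``Ji`` are obtained by intercept-free linear regression.
* **Trained Jouyban-Acree variants** — published coefficient sets in which
  each power-of-(f1-f2) coefficient is either a constant or a linear
  combination of the solute's Abraham descriptors (1, E, S, A, B, V).
* **Modified Wilson** — a two-parameter local-composition model per
  temperature, fitted by multi-start nonlinear least squares.

All four reproduce the neat-solvent anchors exactly at f1 = 0 and f1 = 1 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data_model import AbrahamSoluteDescriptors, SolubilityDataset
from .exceptions import (
    ConfigurationError,
    DomainError,
    FitError,
    RankDeficiencyError,
)

__all__ = [
    "LogLinearCosolventConstants",
    "ETHANOL_LOGLINEAR",
    "loglinear_sigma",
    "loglinear_sigma_from_logP",
    "loglinear_predict",
    "JouybanAcreeParams",
    "ja_fit",
    "ja_predict",
    "TrainedMixtureCoefficients",
    "ja_trained_predict",
    "JA_ETHANOL_WATER_TWO_TERM",
    "JA_ETHANOL_WATER_GENERAL",
    "JA_ABRAHAM_GENERAL",
    "ModifiedWilsonParams",
    "WILSON_PUBLISHED",
    "wilson_predict",
    "wilson_fit",
]


# ---------------------------------------------------------------------------
# Log-linear (Yalkowsky) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogLinearCosolventConstants:
    """Cosolvent constants of the sigma-vs-logP correlation sigma = M logP + N."""

    M: float
    N: float


#: Literature M, N constants for ethanol as cosolvent.
ETHANOL_LOGLINEAR = LogLinearCosolventConstants(M=2.14, N=0.92)


def loglinear_sigma(C1: float, C2: float) -> float:
    """Solubilization power from the neat-solvent solubilities: ln(C1/C2)."""
    if C1 <= 0 or C2 <= 0:
        raise DomainError("solubilities must be positive")
    return float(np.log(C1 / C2))


def loglinear_sigma_from_logP(
    logP: float, constants: LogLinearCosolventConstants = ETHANOL_LOGLINEAR
) -> float:
    """Predicted solubilization power sigma = M * logP + N."""
    return constants.M * logP + constants.N


def loglinear_predict(C2: float, sigma: float, f1) -> float | np.ndarray:
    """Log-linear solubility ``exp(ln C2 + sigma * f1)``."""
    if C2 <= 0:
        raise DomainError("water solubility C2 must be positive")
    f1 = np.asarray(f1, dtype=float)
    if np.any((f1 < 0) | (f1 > 1)):
        raise DomainError("f1 outside [0, 1]")
    out = np.exp(np.log(C2) + sigma * f1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Jouyban-Acree model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JouybanAcreeParams:
    """Mixing-term coefficients J0..J2 (units of K, since each is divided by T)."""

    J: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.J) <= 3:
            raise ConfigurationError("between 1 and 3 J coefficients required")
        object.__setattr__(self, "J", tuple(float(j) for j in self.J))


def _ja_regressors(f1: np.ndarray, T: np.ndarray, n_terms: int) -> np.ndarray:
    """Design matrix columns f1 f2 (f1-f2)^i / T for i = 0..n_terms-1."""
    f2 = 1.0 - f1
    base = f1 * f2 / T
    return np.column_stack([base * (f1 - f2) ** i for i in range(n_terms)])


def ja_mixing_term(params: JouybanAcreeParams, f1, T) -> np.ndarray:
    """The mixing contribution (f1 f2 / T) sum_i Ji (f1-f2)^i to ln Cm."""
    f1 = np.asarray(f1, dtype=float)
    T = np.asarray(T, dtype=float)
    X = _ja_regressors(np.atleast_1d(f1), np.broadcast_to(np.atleast_1d(T), np.atleast_1d(f1).shape), len(params.J))
    return X @ np.array(params.J)


def ja_fit(
    dataset: SolubilityDataset,
    n_terms: int = 3,
    analyte: str = "primary_solute",
) -> JouybanAcreeParams:
    """Fit the mixing coefficients by intercept-free least squares.

    The response is ``ln Cm - f1 ln C1(T) - f2 ln C2(T)``; neat-solvent rows
    contribute zero rows (they anchor the blend, not the mixing term).

    Raises
    ------
    AnchorMissingError
        If a neat-solvent solubility is missing at any temperature.
    RankDeficiencyError
        If the design matrix has rank < ``n_terms`` (e.g. anchors only).
    """
    if not 1 <= n_terms <= 3:
        raise ConfigurationError("n_terms must be 1, 2 or 3")
    data = dataset.subset(analyte=analyte)
    data.require_anchors(analyte=analyte)
    f1 = np.array([r.f1 for r in data.records])
    T = np.array([r.T for r in data.records])
    lnC = np.log([r.C for r in data.records])
    lnC1 = np.array([np.log(data.cosolvent_solubility(t, analyte)) for t in T])
    lnC2 = np.array([np.log(data.water_solubility(t, analyte)) for t in T])
    y = lnC - f1 * lnC1 - (1.0 - f1) * lnC2
    X = _ja_regressors(f1, T, n_terms)
    rank = np.linalg.matrix_rank(X)
    if rank < n_terms:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {n_terms}; "
            "need interior mixture points spanning the requested terms"
        )
    J, *_ = np.linalg.lstsq(X, y, rcond=None)
    return JouybanAcreeParams(J=tuple(J))


def ja_predict(
    params: JouybanAcreeParams,
    C1T: float,
    C2T: float,
    f1,
    T: float,
) -> float | np.ndarray:
    """Solubility in the mixture from the neat-solvent anchors at the same T."""
    if C1T <= 0 or C2T <= 0:
        raise DomainError("anchor solubilities must be positive")
    if T <= 0:
        raise DomainError("temperature must be positive")
    f1 = np.asarray(f1, dtype=float)
    if np.any((f1 < 0) | (f1 > 1)):
        raise DomainError("f1 outside [0, 1]")
    lnC = (
        f1 * np.log(C1T)
        + (1.0 - f1) * np.log(C2T)
        + ja_mixing_term(params, f1, np.full_like(np.atleast_1d(f1), T)).reshape(f1.shape)
    )
    out = np.exp(lnC)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Trained (pre-published) Jouyban-Acree coefficient sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainedMixtureCoefficients:
    """Published mixing-term coefficients, optionally Abraham-extended.

    ``powers[i]`` holds the coefficient vector of the (f1-f2)^i mixing term:
    either a single constant, or six numbers dotted with (1, E, S, A, B, V).
    """

    powers: tuple[tuple[float, ...], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.powers) <= 3:
            raise ConfigurationError("between 1 and 3 power terms required")
        for vec in self.powers:
            if len(vec) not in (1, 6):
                raise ConfigurationError(
                    "each coefficient vector must have length 1 (constant) or "
                    "6 (constant + five Abraham descriptors)"
                )

    @property
    def needs_descriptors(self) -> bool:
        return any(len(vec) == 6 for vec in self.powers)

    def term_coefficients(
        self, descriptors: AbrahamSoluteDescriptors | None = None
    ) -> JouybanAcreeParams:
        """Collapse to plain Ji values for a given solute."""
        if self.needs_descriptors and descriptors is None:
            raise ConfigurationError(
                f"coefficient set {self.name!r} requires Abraham solute descriptors"
            )
        J = []
        for vec in self.powers:
            if len(vec) == 1:
                J.append(vec[0])
            else:
                J.append(float(np.dot(vec, descriptors.as_vector())))
        return JouybanAcreeParams(J=tuple(J))


#: Two-term coefficient set trained on a minimal ASA subset (both neat-solvent
#: anchors at each temperature plus f1 = 0.3, 0.5, 0.7 at 298.15 K).
JA_ETHANOL_WATER_TWO_TERM = TrainedMixtureCoefficients(
    powers=((1153.087,), (474.742,)), name="ethanol-water-two-term"
)

#: General solute-independent ethanol + water coefficient set.
JA_ETHANOL_WATER_GENERAL = TrainedMixtureCoefficients(
    powers=((1667.856,), (1117.347,), (447.7262,)), name="ethanol-water-general"
)

#: Abraham-extended general model: each mixing coefficient is a linear
#: function of the solute descriptors (1, E, S, A, B, V).
JA_ABRAHAM_GENERAL = TrainedMixtureCoefficients(
    powers=(
        (1286.11, 825.86, 50.69, -812.89, 300.49, -684.22),
        (105.18, -381.77, -740.53, 1104.24, -943.10, 1906.03),
        (-1137.24, -786.06, 1994.90, -83.29, 399.36, -1279.27),
    ),
    name="ethanol-water-abraham",
)


def ja_trained_predict(
    coeffs: TrainedMixtureCoefficients,
    C1T: float,
    C2T: float,
    f1,
    T: float,
    descriptors: AbrahamSoluteDescriptors | None = None,
) -> float | np.ndarray:
    """Predict with a published coefficient set (no fitting).

    Only the two neat-solvent solubilities are taken from experiment; the
    mixing term comes entirely from the trained coefficients (and the solute
    descriptors where the set is Abraham-extended).
    """
    return ja_predict(coeffs.term_coefficients(descriptors), C1T, C2T, f1, T)


# ---------------------------------------------------------------------------
# Modified Wilson model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModifiedWilsonParams:
    """Local-composition interaction constants at one temperature."""

    lambda12: float
    lambda21: float
    T: float

    def __post_init__(self) -> None:
        if self.lambda12 <= 0 or self.lambda21 <= 0:
            raise DomainError("lambda parameters must be positive")


#: Published modified Wilson parameters for ASA in ethanol + water.
WILSON_PUBLISHED = {
    298.15: ModifiedWilsonParams(lambda12=0.394, lambda21=2.537, T=298.15),
    310.15: ModifiedWilsonParams(lambda12=0.294, lambda21=3.405, T=310.15),
}


def wilson_predict(
    params: ModifiedWilsonParams, C1: float, C2: float, f1
) -> float | np.ndarray:
    """Modified Wilson solubility at composition ``f1``.

    Evaluates::

        -ln Cm = 1 - f1 (1 + ln C1) / (f1 + f2 lam12)
                   - f2 (1 + ln C2) / (f1 lam21 + f2)

    with the neat-solvent solubilities on the same concentration scale as the
    returned Cm, then exponentiates.  At f1 = 0 or 1 the result equals the
    corresponding anchor for any lambda.
    """
    if C1 <= 0 or C2 <= 0:
        raise DomainError("anchor solubilities must be positive")
    f1 = np.asarray(f1, dtype=float)
    if np.any((f1 < 0) | (f1 > 1)):
        raise DomainError("f1 outside [0, 1]")
    f2 = 1.0 - f1
    den1 = f1 + f2 * params.lambda12
    den2 = f1 * params.lambda21 + f2
    if np.any(den1 == 0) or np.any(den2 == 0):
        raise DomainError("zero denominator in the Wilson expression")
    neg_ln = 1.0 - f1 * (1.0 + np.log(C1)) / den1 - f2 * (1.0 + np.log(C2)) / den2
    out = np.exp(-neg_ln)
    return float(out) if out.ndim == 0 else out


def wilson_fit(
    dataset: SolubilityDataset,
    T: float,
    analyte: str = "primary_solute",
    starts=None,
) -> ModifiedWilsonParams:
    """Fit lambda12, lambda21 at one temperature by nonlinear least squares.

    Minimizes the sum of squared residuals in ln Cm over all records at ``T``
    from a grid of starting pairs (default 3 x 3 over [0.1, 5]^2), keeping the
    best optimum; ties within 1e-12 are broken by the smaller lambda12.

    Requires both neat-solvent anchors and at least four mixture points.
    """
    data = dataset.subset(T=T, analyte=analyte)
    data.require_anchors(analyte=analyte)
    f1 = np.array([r.f1 for r in data.records])
    lnC = np.log([r.C for r in data.records])
    n_mix = int(np.sum((f1 > 0) & (f1 < 1)))
    if n_mix < 4:
        raise FitError(f"need >= 4 mixture points at T={T} K, got {n_mix}")
    C1 = data.cosolvent_solubility(T, analyte)
    C2 = data.water_solubility(T, analyte)

    def residuals(p):
        pred = wilson_predict(ModifiedWilsonParams(p[0], p[1], T), C1, C2, f1)
        return np.log(pred) - lnC

    if starts is None:
        grid = [0.1, 1.0, 5.0]
        starts = [(a, b) for a in grid for b in grid]
    best = None
    for p0 in starts:
        try:
            res = least_squares(
                residuals, x0=p0, bounds=([1e-10, 1e-10], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if not res.success:
            continue
        if (
            best is None
            or res.cost < best.cost - 1e-12
            or (abs(res.cost - best.cost) <= 1e-12 and res.x[0] < best.x[0])
        ):
            best = res
    if best is None:
        raise FitError("modified Wilson fit did not converge from any start")
    return ModifiedWilsonParams(lambda12=float(best.x[0]), lambda21=float(best.x[1]), T=T)
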