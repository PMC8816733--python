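"""Solid-liquid equilibrium: solubility prediction from fusion data + PC-SAFT.

The mole-fraction solubility of a crystalline solute follows from

    ln x = (dHm / R) (1/Tm - 1/T) - ln gamma(x)

where the first term is the ideal solubility (activity coefficient 1) set by
the fusion enthalpy and melting point, and gamma is the solute's activity
coefficient in the saturated liquid, here computed with PC-SAFT.  Because
gamma depends on x, the equation is solved by damped fixed-point iteration
starting from the ideal solubility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import R, ETHANOL_WATER, FusionProperties, SolventSystem
from .exceptions import ConvergenceError, DomainError
from .pcsaft import MixtureState, PCSAFTComponent, activity_coefficient

__all__ = [
    "SLEProblem",
    "SLEResult",
    "ideal_solubility",
    "solvent_mole_fractions",
    "solve_solubility",
]


def ideal_solubility(fusion: FusionProperties, T: float) -> float:
    """Ideal mole-fraction solubility exp[(dHm/R)(1/Tm - 1/T)].

    Equals 1 at the melting point and decreases with undercooling; warns when
    evaluated above Tm (the solid no longer exists there).
    """
    if T <= 0:
        raise DomainError("temperature must be positive")
    if T > fusion.Tm:
        warnings.warn(
            f"T={T} K above the melting point {fusion.Tm} K; "
            "ideal solubility extrapolated beyond the solid regime",
            stacklevel=2,
        )
    return float(np.exp(fusion.dHm / R * (1.0 / fusion.Tm - 1.0 / T)))


def solvent_mole_fractions(
    f1: float, system: SolventSystem = ETHANOL_WATER, T: float = 298.15
) -> tuple[float, float]:
    """Solute-free (cosolvent, water) mole fractions from the volume fraction.

    Volumes are converted with the pure-liquid densities at ``T``; mixing
    volume changes are neglected (the composition variable f1 is defined on
    the unmixed basis anyway).
    """
    if not 0.0 <= f1 <= 1.0:
        raise DomainError("f1 outside [0, 1]")
    rho1, rho2 = system.densities_at(T)
    n1 = f1 * rho1 / system.cosolvent_molar_mass
    n2 = (1.0 - f1) * rho2 / system.water_molar_mass
    return n1 / (n1 + n2), n2 / (n1 + n2)


@dataclass(frozen=True)
class SLEProblem:
    """One solubility prediction: solute + binary solvent at (f1, T, P)."""

    solute: PCSAFTComponent
    fusion: FusionProperties
    solvents: tuple[PCSAFTComponent, PCSAFTComponent]
    solvent_f1: float
    T: float
    P: float = 1.013
    system: SolventSystem = ETHANOL_WATER

    def __post_init__(self) -> None:
        if not 0.0 <= self.solvent_f1 <= 1.0:
            raise DomainError("solvent_f1 outside [0, 1]")


@dataclass(frozen=True)
class SLEResult:
    """Converged mole-fraction solubility plus the iteration record."""

    x: float
    gamma: float
    x_ideal: float
    converged: bool
    iterations: int
    clipped: bool
    trace: tuple[float, ...] = field(repr=False, default=())


def solve_solubility(
    problem: SLEProblem,
    damping: float = 0.5,
    rtol: float = 1e-8,
    max_iter: int = 200,
) -> SLEResult:
    """Solve ln x = ln x_ideal - ln gamma(x) by damped fixed-point iteration.

    Starting from the ideal solubility (gamma = 1), each step evaluates the
    solute's PC-SAFT activity coefficient at the current composition (the
    solute-free solvent ratio is held fixed and renormalized with the solute)
    and moves x toward x_ideal / gamma with the given damping.  Iterates that
    escape (0, 1) are clipped and flagged.

    Raises :class:`ConvergenceError` (with the iterate trace in the message)
    if the relative change has not fallen below ``rtol`` within ``max_iter``
    iterations.
    """
    if not 0.0 < damping <= 1.0:
        raise DomainError("damping must be in (0, 1]")
    x_id = ideal_solubility(problem.fusion, problem.T)
    s1, s2 = solvent_mole_fractions(problem.solvent_f1, problem.system, problem.T)

    # pure-solute (subcooled liquid) reference fugacity: constant over iterations
    from .pcsaft import _Eos, _number_density, fugacity_coefficients, solve_density

    pure = MixtureState(
        T=problem.T, P=problem.P, x=np.array([1.0]), components=(problem.solute,)
    )
    ln_phi_pure = fugacity_coefficients(pure, "liquid")[0]
    comps = (problem.solute,) + tuple(problem.solvents)
    eta_hint = None

    def gamma_at(x_solute: float) -> float:
        nonlocal eta_hint
        x = np.array([x_solute, (1.0 - x_solute) * s1, (1.0 - x_solute) * s2])
        state = MixtureState(T=problem.T, P=problem.P, x=x, components=comps)
        rho = solve_density(state, "liquid", eta_hint=eta_hint)
        eta_hint = _Eos(state).eta(_number_density(rho), x)
        ln_phi_mix = fugacity_coefficients(state, rho=rho)[0]
        return float(np.exp(ln_phi_mix - ln_phi_pure))

    x = min(x_id, 0.999)
    clipped = False
    trace = [x]
    for it in range(1, max_iter + 1):
        g = gamma_at(x)
        proposal = x_id / g
        if not 0.0 < proposal < 1.0:
            proposal = min(max(proposal, 1e-12), 1.0 - 1e-12)
            clipped = True
            warnings.warn(
                f"SLE iterate escaped (0, 1) at iteration {it}; clipped",
                stacklevel=2,
            )
        x_new = (1.0 - damping) * x + damping * proposal
        trace.append(x_new)
        if abs(x_new - x) <= rtol * abs(x_new):
            return SLEResult(
                x=float(x_new), gamma=float(g), x_ideal=x_id, converged=True,
                iterations=it, clipped=clipped, trace=tuple(trace),
            )
        x = x_new
    raise ConvergenceError(
        f"SLE fixed point did not converge in {max_iter} iterations; "
        f"last iterates {trace[-5:]}"
    )
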