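"""Perturbed-chain SAFT (PC-SAFT) equation of state with 2B association.

The residual Helmholtz energy is built from the standard hard-chain,
dispersion and association contributions,

    a_res = a_hc + a_disp + a_assoc          (all reduced by RT)

using the universal dispersion constants of the original perturbed-chain
formulation.  Association follows the 2B scheme (one donor + one acceptor
site per molecule); cross-association between associating species uses the
Wolbach-Danner combining rules, and segment size/energy cross-terms use
Lorentz-Berthelot mixing with an optional binary correction k_ij.

Derived properties:

* ``compressibility`` — z = 1 + rho * d(a_res)/d(rho), analytic in density.
* ``solve_density`` — molar density at given T, P on a requested branch.
* ``fugacity_coefficients`` — ln phi_k from a_res, z and the constant-volume
  mole-fraction derivatives of a_res.
* ``activity_coefficient`` — gamma_i = phi_i(mixture) / phi_i(pure i).

Internally all state functions are evaluated with the mole-fraction vector
treated as a free (unnormalized) variable so that the composition
derivatives in the fugacity expression are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .data_model import R
from .exceptions import ConvergenceError, DomainError, ValidationError

__all__ = [
    "PCSAFTComponent",
    "MixtureState",
    "ASPIRIN_PCSAFT",
    "ETHANOL_PCSAFT",
    "WATER_PCSAFT",
    "residual_helmholtz",
    "compressibility",
    "pressure",
    "solve_density",
    "fugacity_coefficients",
    "activity_coefficient",
]

N_AV = 6.02214076e23  # 1/mol

#: Maximum physically meaningful hard-sphere packing fraction.
ETA_MAX = 0.7405

# Universal model constants of the dispersion term (a0i/a1i/a2i, b0i/b1i/b2i).
_A = np.array([
    [0.9105631445, -0.3084016918, -0.0906148351],
    [0.6361281449, 0.1860531159, 0.4527842806],
    [2.6861347891, -2.5030047259, 0.5962700728],
    [-26.547362491, 21.419793629, -1.7241829131],
    [97.759208784, -65.255885330, -4.1302112531],
    [-159.59154087, 83.318680481, 13.7766318697],
    [91.297774084, -33.746922930, -8.6728470368],
])
_B = np.array([
    [0.7240946941, -0.5755498075, 0.0976883116],
    [2.2382791861, 0.6995095521, -0.2557574982],
    [-4.0025849485, 3.8925673390, -9.1558561530],
    [-21.003576815, -17.215471648, 20.642075974],
    [26.855641363, 192.67226447, -38.804430052],
    [206.55133841, -161.82646165, 93.626774077],
    [-355.60235612, -165.20769346, -29.666905585],
])


@dataclass(frozen=True)
class PCSAFTComponent:
    """Pure-component PC-SAFT parameters.

    m: segments per chain; segment_diameter in Angstrom; segment energy and
    association energy as eps/k in Kelvin; assoc_volume is the dimensionless
    kappa_AB; scheme "2B" means one donor + one acceptor site.
    """

    name: str
    m: float
    segment_diameter: float
    segment_energy_over_k: float
    assoc_volume: float = 0.0
    assoc_energy_over_k: float = 0.0
    assoc_scheme: str = "none"
    molar_mass: float = float("nan")

    def __post_init__(self) -> None:
        if self.m < 1.0:
            raise ValidationError("segment number m must be >= 1")
        if self.segment_diameter <= 0:
            raise ValidationError("segment diameter must be positive")
        if self.segment_energy_over_k < 0 or self.assoc_energy_over_k < 0:
            raise ValidationError("energy parameters must be non-negative")
        if self.assoc_scheme not in ("none", "2B"):
            raise ValidationError("assoc_scheme must be 'none' or '2B'")

    @property
    def associating(self) -> bool:
        return self.assoc_scheme == "2B" and self.assoc_volume > 0


#: Pure-component parameters used for the aspirin / ethanol / water system.
ASPIRIN_PCSAFT = PCSAFTComponent(
    "acetylsalicylic acid", m=5.5830, segment_diameter=3.8593,
    segment_energy_over_k=256.38, assoc_volume=0.01,
    assoc_energy_over_k=2453.80, assoc_scheme="2B", molar_mass=180.16,
)
ETHANOL_PCSAFT = PCSAFTComponent(
    "ethanol", m=2.3827, segment_diameter=3.1771,
    segment_energy_over_k=198.2, assoc_volume=0.032384,
    assoc_energy_over_k=2653.4, assoc_scheme="2B", molar_mass=46.07,
)
WATER_PCSAFT = PCSAFTComponent(
    "water", m=1.0656, segment_diameter=3.0007,
    segment_energy_over_k=366.51, assoc_volume=0.034868,
    assoc_energy_over_k=2500.7, assoc_scheme="2B", molar_mass=18.015,
)


@dataclass(frozen=True)
class MixtureState:
    """Temperature (K), pressure (bar), composition and components."""

    T: float
    P: float
    x: np.ndarray
    components: tuple[PCSAFTComponent, ...]
    kij: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "components", tuple(self.components))
        n = len(self.components)
        if x.shape != (n,):
            raise ValidationError("x must have one entry per component")
        if np.any(x < 0):
            raise ValidationError("mole fractions must be non-negative")
        if abs(x.sum() - 1.0) > 1e-8:
            raise ValidationError("mole fractions must sum to 1")
        if self.kij is None:
            object.__setattr__(self, "kij", np.zeros((n, n)))
        else:
            k = np.asarray(self.kij, dtype=float)
            if k.shape != (n, n) or not np.allclose(k, k.T) or np.any(np.diag(k) != 0):
                raise ValidationError("kij must be symmetric with zero diagonal")
            object.__setattr__(self, "kij", k)
        if self.T <= 0 or self.P <= 0:
            raise ValidationError("T and P must be positive")


class _Eos:
    """Precomputed T- and composition-independent structure for one mixture."""

    def __init__(self, state: MixtureState):
        comps = state.components
        self.T = state.T
        self.m = np.array([c.m for c in comps])
        sigma = np.array([c.segment_diameter for c in comps])
        eps = np.array([c.segment_energy_over_k for c in comps])
        # temperature-dependent hard-sphere diameters
        self.d = sigma * (1.0 - 0.12 * np.exp(-3.0 * eps / state.T))
        self.sigma_ij = 0.5 * (sigma[:, None] + sigma[None, :])
        self.eps_ij = np.sqrt(eps[:, None] * eps[None, :]) * (1.0 - state.kij)
        self.eps_ij_kT = self.eps_ij / state.T
        # association (2B): one donor + one acceptor per associating molecule.
        kappa = np.array([c.assoc_volume if c.associating else 0.0 for c in comps])
        eps_ab = np.array([c.assoc_energy_over_k if c.associating else 0.0 for c in comps])
        self.assoc = kappa > 0
        # Wolbach-Danner combining rules between associating pairs
        kappa_ij = np.sqrt(kappa[:, None] * kappa[None, :]) * (
            np.sqrt(sigma[:, None] * sigma[None, :]) / self.sigma_ij
        ) ** 3
        eps_ab_ij = 0.5 * (eps_ab[:, None] + eps_ab[None, :])
        active = np.outer(self.assoc, self.assoc)
        # strength prefactor: Delta_ij = g_ij * _delta_pref_ij  (needs g at rho)
        self.delta_pref = np.where(
            active,
            self.sigma_ij ** 3 * kappa_ij * np.expm1(eps_ab_ij / state.T),
            0.0,
        )
        self.any_assoc = bool(np.any(self.assoc))

    # -- packing fractions ---------------------------------------------------
    def zetas(self, rho_n: float, x: np.ndarray) -> np.ndarray:
        """zeta_0..zeta_3 at number density rho_n (A^-3) and composition x."""
        md = x * self.m
        return np.pi / 6.0 * rho_n * np.array(
            [np.sum(md * self.d ** k) for k in range(4)]
        )

    def eta(self, rho_n: float, x: np.ndarray) -> float:
        return float(self.zetas(rho_n, x)[3])

    def rho_from_eta(self, eta: float, x: np.ndarray) -> float:
        """Number density (A^-3) corresponding to packing fraction eta."""
        return eta * 6.0 / np.pi / np.sum(x * self.m * self.d ** 3)

    # -- hard-sphere contact radial distribution function --------------------
    def _g_terms(self, z: np.ndarray):
        dij = self.d[:, None] * self.d[None, :] / (self.d[:, None] + self.d[None, :])
        om = 1.0 - z[3]
        g = 1.0 / om + dij * 3.0 * z[2] / om ** 2 + dij ** 2 * 2.0 * z[2] ** 2 / om ** 3
        # rho * dg/drho (zetas are linear in rho)
        rho_dg = (
            z[3] / om ** 2
            + dij * (3.0 * z[2] / om ** 2 + 6.0 * z[2] * z[3] / om ** 3)
            + dij ** 2 * (4.0 * z[2] ** 2 / om ** 3 + 6.0 * z[2] ** 2 * z[3] / om ** 4)
        )
        return g, rho_dg

    # -- association site fractions ------------------------------------------
    def site_fractions(self, rho_n: float, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Unbonded-site fraction X_i per component (2B: X_A = X_B by symmetry).

        Solved by damped successive substitution (damping 0.5, tolerance
        1e-12), with a bounded least-squares root solve as fallback.
        """
        delta = g * self.delta_pref
        coupling = rho_n * x[None, :] * delta  # [i, j]
        X = np.where(self.assoc, 0.5, 1.0)

        def step(Xv):
            return 1.0 / (1.0 + coupling @ Xv)

        for _ in range(500):
            X_new = 0.5 * X + 0.5 * step(X)
            if np.max(np.abs(X_new - X)) < 1e-12:
                X = X_new
                break
            X = X_new
        else:
            res = least_squares(
                lambda v: v - step(v), x0=X, bounds=(1e-12, 1.0),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            if not res.success:
                raise ConvergenceError("association site-fraction solve failed")
            X = res.x
        return np.where(self.assoc, X, 1.0)

    # -- Helmholtz energy contributions ---------------------------------------
    def a_res(self, rho_n: float, x: np.ndarray) -> float:
        """Reduced residual Helmholtz energy a_res/RT (x may be unnormalized)."""
        if rho_n <= 0:
            return 0.0
        z = self.zetas(rho_n, x)
        if z[3] >= ETA_MAX:
            raise DomainError(f"packing fraction {z[3]:.3f} >= {ETA_MAX}")
        om = 1.0 - z[3]
        # with x treated as a free (unnormalized) variable, the mean segment
        # number is plain sum(x m), per the unconstrained-derivative recipe
        mbar = np.sum(x * self.m)

        # hard sphere (per segment) and hard chain
        a_hs = (
            3.0 * z[1] * z[2] / om
            + z[2] ** 3 / (z[3] * om ** 2)
            + (z[2] ** 3 / z[3] ** 2 - z[0]) * np.log(om)
        ) / z[0]
        g, _ = self._g_terms(z)
        a_hc = mbar * a_hs - np.sum(x * (self.m - 1.0) * np.log(np.diag(g)))

        # dispersion
        eta = z[3]
        mb = mbar
        a_i = _A[:, 0] + (mb - 1.0) / mb * _A[:, 1] + (mb - 1.0) * (mb - 2.0) / mb ** 2 * _A[:, 2]
        b_i = _B[:, 0] + (mb - 1.0) / mb * _B[:, 1] + (mb - 1.0) * (mb - 2.0) / mb ** 2 * _B[:, 2]
        powers = eta ** np.arange(7)
        I1 = np.sum(a_i * powers)
        I2 = np.sum(b_i * powers)
        C1 = 1.0 / (
            1.0
            + mb * (8.0 * eta - 2.0 * eta ** 2) / om ** 4
            + (1.0 - mb)
            * (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3 - 2.0 * eta ** 4)
            / (om * (2.0 - eta)) ** 2
        )
        mm = x[:, None] * x[None, :] * self.m[:, None] * self.m[None, :]
        m2es3 = np.sum(mm * self.eps_ij_kT * self.sigma_ij ** 3)
        m2e2s3 = np.sum(mm * self.eps_ij_kT ** 2 * self.sigma_ij ** 3)
        a_disp = (
            -2.0 * np.pi * rho_n * I1 * m2es3
            - np.pi * rho_n * mbar * C1 * I2 * m2e2s3
        )

        # association (2 sites per associating molecule, X_A = X_B)
        a_assoc = 0.0
        if self.any_assoc:
            X = self.site_fractions(rho_n, x, g)
            a_assoc = np.sum(x * self.assoc * 2.0 * (np.log(X) - X / 2.0 + 0.5))

        return float(a_hc + a_disp + a_assoc)

    def z_res(self, rho_n: float, x: np.ndarray) -> float:
        """Residual compressibility z - 1 = rho d(a_res)/d(rho), analytic."""
        if rho_n <= 0:
            return 0.0
        z = self.zetas(rho_n, x)
        if z[3] >= ETA_MAX:
            raise DomainError(f"packing fraction {z[3]:.3f} >= {ETA_MAX}")
        om = 1.0 - z[3]
        mbar = np.sum(x * self.m)
        eta = z[3]

        z_hs = (
            z[3] / om
            + 3.0 * z[1] * z[2] / (z[0] * om ** 2)
            + (3.0 * z[2] ** 3 - z[3] * z[2] ** 3) / (z[0] * om ** 3)
        )
        g, rho_dg = self._g_terms(z)
        z_hc = mbar * z_hs - np.sum(
            x * (self.m - 1.0) * np.diag(rho_dg) / np.diag(g)
        )

        mb = mbar
        a_i = _A[:, 0] + (mb - 1.0) / mb * _A[:, 1] + (mb - 1.0) * (mb - 2.0) / mb ** 2 * _A[:, 2]
        b_i = _B[:, 0] + (mb - 1.0) / mb * _B[:, 1] + (mb - 1.0) * (mb - 2.0) / mb ** 2 * _B[:, 2]
        idx = np.arange(7)
        powers = eta ** idx
        I2 = np.sum(b_i * powers)
        detaI1 = np.sum(a_i * (idx + 1) * powers)
        detaI2 = np.sum(b_i * (idx + 1) * powers)
        C1 = 1.0 / (
            1.0
            + mb * (8.0 * eta - 2.0 * eta ** 2) / om ** 4
            + (1.0 - mb)
            * (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3 - 2.0 * eta ** 4)
            / (om * (2.0 - eta)) ** 2
        )
        C2 = -C1 ** 2 * (
            mb * (-4.0 * eta ** 2 + 20.0 * eta + 8.0) / om ** 5
            + (1.0 - mb)
            * (2.0 * eta ** 3 + 12.0 * eta ** 2 - 48.0 * eta + 40.0)
            / (om * (2.0 - eta)) ** 3
        )
        mm = x[:, None] * x[None, :] * self.m[:, None] * self.m[None, :]
        m2es3 = np.sum(mm * self.eps_ij_kT * self.sigma_ij ** 3)
        m2e2s3 = np.sum(mm * self.eps_ij_kT ** 2 * self.sigma_ij ** 3)
        z_disp = (
            -2.0 * np.pi * rho_n * detaI1 * m2es3
            - np.pi * rho_n * mbar * (C1 * detaI2 + C2 * eta * I2) * m2e2s3
        )

        z_assoc = 0.0
        if self.any_assoc:
            X = self.site_fractions(rho_n, x, g)
            # d(a_assoc)/d(rho) via the stationarity of the association
            # functional in X: only the explicit rho * Delta dependence counts.
            pair = (
                x[:, None] * x[None, :] * X[:, None] * X[None, :]
                * self.delta_pref * (g + rho_dg)
            )
            z_assoc = -rho_n * np.sum(pair)

        return float(z_hc + z_disp + z_assoc)


def _number_density(rho_molar: float) -> float:
    """mol/m^3 -> molecules per cubic Angstrom."""
    return rho_molar * N_AV * 1e-30


def residual_helmholtz(state: MixtureState, rho: float) -> float:
    """Reduced residual Helmholtz energy a_res/RT at molar density ``rho`` (mol/m^3)."""
    if rho < 0:
        raise DomainError("density must be non-negative")
    return _Eos(state).a_res(_number_density(rho), state.x)


def compressibility(state: MixtureState, rho: float) -> float:
    """Compressibility factor z = 1 + rho d(a_res)/d(rho) at molar density ``rho``."""
    if rho < 0:
        raise DomainError("density must be non-negative")
    return 1.0 + _Eos(state).z_res(_number_density(rho), state.x)


def pressure(state: MixtureState, rho: float) -> float:
    """Pressure in Pa implied by the EOS at molar density ``rho`` (mol/m^3)."""
    return compressibility(state, rho) * rho * R * state.T


def solve_density(
    state: MixtureState, phase: str = "liquid", eta_hint: float | None = None
) -> float:
    """Molar density (mol/m^3) at the state's T, P on the requested branch.

    The pressure isotherm is scanned over packing fractions from near zero to
    the physical maximum; every bracketed, mechanically stable root of
    P_calc(rho) = P is refined by Brent's method, and the highest-density
    root is returned for the liquid branch, the lowest for the vapor branch.
    ``eta_hint`` (a packing fraction near the expected root) enables a fast
    local bracket before falling back to the full scan.
    """
    if phase not in ("liquid", "vapor"):
        raise DomainError("phase must be 'liquid' or 'vapor'")
    eos = _Eos(state)
    x = state.x
    P_target = state.P * 1e5  # bar -> Pa

    def p_of_eta(eta):
        rho_n = eos.rho_from_eta(eta, x)
        rho_molar = rho_n / (N_AV * 1e-30)
        return (1.0 + eos.z_res(rho_n, x)) * rho_molar * R * state.T - P_target

    if eta_hint is not None and 0 < eta_hint < ETA_MAX:
        lo, hi = eta_hint * 0.9, min(eta_hint * 1.1, 0.74)
        try:
            if p_of_eta(lo) < 0 < p_of_eta(hi):
                r = brentq(p_of_eta, lo, hi, xtol=1e-15, rtol=1e-14)
                rho_n = eos.rho_from_eta(r, x)
                return rho_n / (N_AV * 1e-30)
        except (DomainError, ValueError):
            pass

    etas = np.concatenate([
        np.geomspace(1e-12, 1e-2, 40),
        np.linspace(1.2e-2, 0.74, 160),
    ])
    vals = np.array([p_of_eta(e) for e in etas])
    roots = []
    for i in range(len(etas) - 1):
        if np.sign(vals[i]) == 0:
            r = etas[i]
        elif np.sign(vals[i]) != np.sign(vals[i + 1]):
            r = brentq(p_of_eta, etas[i], etas[i + 1], xtol=1e-15, rtol=1e-14)
        else:
            continue
        # keep mechanically stable roots only (dP/drho > 0); the EOS can show
        # spurious unstable crossings at very high packing fractions
        if p_of_eta(min(r * 1.0005, ETA_MAX)) > p_of_eta(r * 0.9995):
            roots.append(r)
    if not roots:
        raise ConvergenceError(
            f"no density root on the {phase} branch for T={state.T} K, "
            f"P={state.P} bar; isotherm scanned over eta in "
            f"[{etas[0]:.1e}, {etas[-1]:.2f}] with P_calc - P in "
            f"[{vals.min():.3e}, {vals.max():.3e}] Pa"
        )
    eta_root = max(roots) if phase == "liquid" else min(roots)
    rho_n = eos.rho_from_eta(eta_root, x)
    return rho_n / (N_AV * 1e-30)


def fugacity_coefficients(
    state: MixtureState, phase: str = "liquid", rho: float | None = None
) -> np.ndarray:
    """ln phi_k for every component at the solved density.

    Uses ln phi_k = a_res + (z - 1) + da_res/dx_k - sum_j x_j da_res/dx_j - ln z
    with the composition derivatives taken at constant temperature and total
    (volume) density, treating the mole fractions as free variables; the
    derivatives are evaluated by central differences.
    """
    if rho is None:
        rho = solve_density(state, phase)
    eos = _Eos(state)
    rho_n = _number_density(rho)
    x = state.x
    a = eos.a_res(rho_n, x)
    z = 1.0 + eos.z_res(rho_n, x)
    if z <= 0:
        raise ConvergenceError("non-positive compressibility at the solved density")
    h = 1e-5
    mu = np.empty_like(x)
    for k in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        mu[k] = (eos.a_res(rho_n, xp) - eos.a_res(rho_n, xm)) / (2.0 * h)
    return a + (z - 1.0) + mu - np.sum(x * mu) - np.log(z)


def activity_coefficient(
    state: MixtureState, i: int, phase: str = "liquid"
) -> float:
    """gamma_i = phi_i(mixture) / phi_i(pure i) at the same T and P.

    The pure-component reference is the (possibly hypothetical, subcooled)
    pure liquid of component i at the state's temperature and pressure.
    """
    ln_phi_mix = fugacity_coefficients(state, phase)[i]
    pure = MixtureState(
        T=state.T, P=state.P, x=np.array([1.0]),
        components=(state.components[i],),
    )
    ln_phi_pure = fugacity_coefficients(pure, phase)[0]
    return float(np.exp(ln_phi_mix - ln_phi_pure))
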