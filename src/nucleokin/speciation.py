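"""Carbonate speciation and calcite supersaturation.

A deliberately small equilibrium model: total carbonate is distributed over
CO2(aq), HCO3- and CO3^2- at a fixed (pH-stat) pH using the first and second
carbonic-acid dissociation constants, activity coefficients come from the
Davies equation, and the ionic strength is converged by fixed-point
iteration.  Calcium is free Ca^2+ unless ion pairs are explicitly enabled.

The supersaturation convention throughout is

    sigma = ln( a_Ca * a_CO3 / K_sp )

with K_sp the calcite solubility product (10^-8.48 at 25 degC).  sigma is
the chemical driving force that the nucleation-rate law consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import DAVIES_A_25C
from .errors import ConvergenceError, DomainError, ValidationError

DEFAULT_PK1 = 6.35
DEFAULT_PK2 = 10.33
DEFAULT_PKW = 14.00
DEFAULT_PKSP_CALCITE = 8.48


@dataclass(frozen=True)
class EquilibriumConstants:
    """Carbonate-system equilibrium constants (as pK values at 25 degC)."""

    pk1: float = DEFAULT_PK1
    pk2: float = DEFAULT_PK2
    pkw: float = DEFAULT_PKW
    pksp: float = DEFAULT_PKSP_CALCITE
    davies_a: float = DAVIES_A_25C

    @property
    def k1(self) -> float:
        return 10.0 ** -self.pk1

    @property
    def k2(self) -> float:
        return 10.0 ** -self.pk2

    @property
    def kw(self) -> float:
        return 10.0 ** -self.pkw

    @property
    def ksp(self) -> float:
        return 10.0 ** -self.pksp


@dataclass(frozen=True)
class SolutionRecipe:
    """Mixed-solution composition for one nucleation experiment.

    Parameters
    ----------
    total_calcium, total_carbonate : float
        Analytical totals, mol/L.
    pH : float
        Fixed by the pH-stat assumption (experiments run at pH 10).
    temperature : float
        degC; accepted range 0-50.
    background_ions : list of (charge, molarity)
        Inert electrolyte (Na+, Cl-, ...) contributing to ionic strength only.
    """

    total_calcium: float
    total_carbonate: float
    pH: float = 10.0
    temperature: float = 22.0
    background_ions: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.total_calcium < 0 or self.total_carbonate < 0:
            raise ValidationError("concentrations must be >= 0")
        if not (0.0 < self.pH < 14.0):
            raise ValidationError(f"pH must be in (0, 14), got {self.pH}")
        if not (0.0 <= self.temperature <= 50.0):
            raise ValidationError(
                f"temperature must be within 0-50 degC, got {self.temperature}"
            )
        for z, c in self.background_ions:
            if c < 0:
                raise ValidationError("background ion molarity must be >= 0")


@dataclass(frozen=True)
class SpeciationResult:
    """Activities, ionic strength and supersaturation for one recipe."""

    activity_ca: float
    activity_co3: float
    ionic_strength: float
    sigma: float
    activity_ratio: float
    iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "activity_ca": self.activity_ca,
            "activity_co3": self.activity_co3,
            "ionic_strength": self.ionic_strength,
            "sigma": self.sigma,
            "activity_ratio": self.activity_ratio,
        }


def davies_log_gamma(charge: int, ionic_strength: float,
                     a_davies: float = DAVIES_A_25C) -> float:
    """log10 of the single-ion activity coefficient from the Davies equation.

    log10(gamma) = -A z^2 ( sqrt(I)/(1+sqrt(I)) - 0.3 I ).  Returns 0 for
    neutral species and at infinite dilution.
    """
    if ionic_strength < 0:
        raise DomainError(f"ionic strength must be >= 0, got {ionic_strength}")
    if abs(charge) > 4:
        raise ValidationError(f"|charge| must be <= 4, got {charge}")
    sqrt_i = math.sqrt(ionic_strength)
    return -a_davies * charge**2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)


def supersaturation(a_ca: float, a_co3: float, k_sp: float) -> float:
    """sigma = ln(a_Ca * a_CO3 / K_sp); negative when undersaturated."""
    if a_ca <= 0 or a_co3 <= 0 or k_sp <= 0:
        raise DomainError("supersaturation requires strictly positive activities and K_sp")
    return math.log(a_ca * a_co3 / k_sp)


def iap_from_sigma(sigma: float, k_sp: float) -> float:
    """Invert the supersaturation convention: IAP = K_sp * exp(sigma)."""
    if k_sp <= 0:
        raise DomainError("K_sp must be > 0")
    return k_sp * math.exp(sigma)


def _carbonate_fractions(a_h: float, g1: float, g2: float,
                         k: EquilibriumConstants) -> tuple[float, float, float]:
    """Concentration fractions (CO2, HCO3-, CO3^2-) of total carbonate.

    Mass action on activities with activity coefficients g1 (|z|=1) and g2
    (|z|=2); CO2(aq) is treated as ideal (gamma = 1).
    """
    r1 = k.k1 / (a_h * g1)          # [HCO3-]/[CO2]
    r2 = k.k2 * g1 / (a_h * g2)     # [CO3--]/[HCO3-]
    denom = 1.0 + r1 + r1 * r2
    return 1.0 / denom, r1 / denom, r1 * r2 / denom


def solve_carbonate_system(
    recipe: SolutionRecipe,
    constants: EquilibriumConstants | None = None,
    *,
    ion_pairs: dict[str, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SpeciationResult:
    """Distribute carbonate at fixed pH and return activities and sigma.

    The ionic strength and the Davies coefficients are mutually converged by
    fixed-point iteration (relative tolerance ``tol``).  Set ``ion_pairs`` to
    ``{"CaCO3": log10_K_assoc, "CaHCO3": log10_K_assoc}`` to include the two
    calcium-carbonate ion pairs (off by default; this is a documented
    simplification relative to full geochemical speciation codes).
    """
    if constants is None:
        constants = EquilibriumConstants()
    if recipe.total_calcium <= 0 or recipe.total_carbonate <= 0:
        raise DomainError(
            "sigma is undefined for zero total calcium or total carbonate"
        )

    a_h = 10.0 ** -recipe.pH
    ca_t = recipe.total_calcium
    ct = recipe.total_carbonate
    k_p_caco3 = 10.0 ** ion_pairs["CaCO3"] if ion_pairs and "CaCO3" in ion_pairs else 0.0
    k_p_cahco3 = 10.0 ** ion_pairs["CaHCO3"] if ion_pairs and "CaHCO3" in ion_pairs else 0.0

    ionic = 0.0
    for iteration in range(1, max_iter + 1):
        g1 = 10.0 ** davies_log_gamma(1, ionic, constants.davies_a)
        g2 = 10.0 ** davies_log_gamma(2, ionic, constants.davies_a)
        f_co2, f_hco3, f_co3 = _carbonate_fractions(a_h, g1, g2, constants)

        if k_p_caco3 == 0.0 and k_p_cahco3 == 0.0:
            c_ca = ca_t
            c_co2, c_hco3, c_co3 = ct * f_co2, ct * f_hco3, ct * f_co3
        else:
            c_ca, c_co2, c_hco3, c_co3 = _solve_with_pairs(
                ca_t, ct, a_h, g1, g2, constants, k_p_caco3, k_p_cahco3
            )

        c_oh = constants.kw / a_h / g1
        c_h = a_h / g1
        new_ionic = 0.5 * (
            4.0 * c_ca + c_hco3 + 4.0 * c_co3 + c_oh + c_h
            + sum(z * z * c for z, c in recipe.background_ions)
        )
        if abs(new_ionic - ionic) <= tol * max(new_ionic, 1e-30):
            ionic = new_ionic
            break
        ionic = new_ionic
    else:
        raise ConvergenceError(
            f"ionic strength did not converge in {max_iter} iterations",
            residual=abs(new_ionic - ionic),
        )

    a_ca = g2 * c_ca
    a_co3 = g2 * c_co3
    sigma = supersaturation(a_ca, a_co3, constants.ksp)
    return SpeciationResult(
        activity_ca=a_ca,
        activity_co3=a_co3,
        ionic_strength=ionic,
        sigma=sigma,
        activity_ratio=a_ca / a_co3,
        iterations=iteration,
    )


def _solve_with_pairs(ca_t, ct, a_h, g1, g2, k, kp_caco3, kp_cahco3):
    """Inner mass-balance solve when CaCO3(0)/CaHCO3(+) pairs are enabled.

    Unknowns: free [Ca2+] and [CO2(aq)] (log-transformed for positivity).
    """
    r1 = k.k1 / (a_h * g1)
    r2 = k.k2 * g1 / (a_h * g2)

    def residual(logx):
        c_ca, c_co2 = np.exp(logx)
        c_hco3 = r1 * c_co2
        c_co3 = r2 * c_hco3
        a_ca = g2 * c_ca
        c_pair0 = kp_caco3 * a_ca * (g2 * c_co3)          # neutral, gamma=1
        c_pair1 = kp_cahco3 * a_ca * (g1 * c_hco3) / g1   # charge +1
        return [
            c_ca + c_pair0 + c_pair1 - ca_t,
            c_co2 + c_hco3 + c_co3 + c_pair0 + c_pair1 - ct,
        ]

    guess = np.log([ca_t * 0.9, ct * 0.1])
    sol = optimize.root(residual, guess, method="hybr", tol=1e-14)
    if not sol.success:
        raise ConvergenceError("ion-pair mass balance failed: " + sol.message)
    c_ca, c_co2 = np.exp(sol.x)
    return c_ca, c_co2, r1 * c_co2, r2 * r1 * c_co2
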