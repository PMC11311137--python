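"""Classical nucleation theory: rate law, linearized fit, and the slope ->
interfacial-free-energy conversion.

The steady-state heterogeneous nucleation rate is

    J0 = A * exp(-dg_c / kB T),      dg_c = F w^2 g^3 / (kB T sigma)^2

with F the nucleus shape factor (16pi/3 for a spherical cap convention used
here), w the molecular volume of the crystallizing phase (6.13e-23 cm^3 per
CaCO3 formula unit in calcite), g = gamma_net the effective interfacial free
energy of the crystal-substrate-solution system (mJ/m^2), and sigma the
supersaturation.  Defining the dimensionless thermodynamic parameter

    B = F w^2 g^3 / (kB T)^3

gives the linear form  ln J0 = ln A - B / sigma^2 : regressing ln J0 on
1/sigma^2 across experiments yields ln A (kinetic prefactor) and B, and
inverting B yields gamma_net.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from .constants import BOLTZMANN, DEFAULT_TEMPERATURE_K
from .errors import DomainError, InsufficientDataError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .characterization import DSProfile

CM3_TO_M3 = 1e-6
MJ_PER_M2_TO_J_PER_M2 = 1e-3


@dataclass(frozen=True)
class CNTConstants:
    """Physical constants parameterizing the CNT expressions.

    molecular_volume is in cm^3 per formula unit (calcite default); h_shape
    is the auxiliary shape factor of the interfacial-energy decomposition,
    kept as documentation-level metadata (default 1, under-specified).
    """

    boltzmann: float = BOLTZMANN
    temperature: float = DEFAULT_TEMPERATURE_K
    shape_factor: float = 16.0 * math.pi / 3.0
    molecular_volume: float = 6.13e-23
    k_sp: float = 10.0 ** -8.48
    h_shape: float = 1.0

    def __post_init__(self):
        for name in ("boltzmann", "temperature", "shape_factor",
                     "molecular_volume", "k_sp", "h_shape"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def kbt(self) -> float:
        return self.boltzmann * self.temperature


@dataclass(frozen=True)
class RatePoint:
    """One (sigma, ln J0) observation entering the linearized CNT fit."""

    sigma: float
    ln_j0: float
    ln_j0_se: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class CNTFit:
    """Fitted (ln A, B) and the derived gamma_net with standard errors."""

    ln_a: float
    ln_a_se: float
    b: float
    b_se: float
    gamma_net: float        # mJ/m^2; nan when the slope is unphysical (B < 0)
    gamma_net_se: float
    n_points: int
    r_squared: float
    b_negative: bool = False


def critical_barrier(gamma: float, sigma: float, c: CNTConstants | None = None) -> float:
    """Free-energy barrier dg_c = F w^2 g^3 / (kB T sigma)^2, in J.

    gamma in mJ/m^2; converted to SI internally.
    """
    if c is None:
        c = CNTConstants()
    if sigma <= 0:
        raise DomainError("sigma must be > 0 (the barrier diverges at equilibrium)")
    if gamma < 0:
        raise DomainError("gamma must be >= 0")
    w = c.molecular_volume * CM3_TO_M3
    g = gamma * MJ_PER_M2_TO_J_PER_M2
    return c.shape_factor * w**2 * g**3 / (c.kbt * sigma) ** 2


def nucleation_rate(ln_a: float, gamma: float, sigma: float,
                    c: CNTConstants | None = None) -> float:
    """J0 = exp(ln A) * exp(-dg_c / kB T), in m^-2 s^-1."""
    if c is None:
        c = CNTConstants()
    return math.exp(ln_a - critical_barrier(gamma, sigma, c) / c.kbt)


def B_from_gamma(gamma: float, c: CNTConstants | None = None) -> float:
    """Dimensionless thermodynamic parameter B = F w^2 g^3 / (kB T)^3."""
    if c is None:
        c = CNTConstants()
    if gamma < 0:
        raise DomainError("gamma must be >= 0")
    w = c.molecular_volume * CM3_TO_M3
    g = gamma * MJ_PER_M2_TO_J_PER_M2
    return c.shape_factor * w**2 * g**3 / c.kbt**3


def gamma_from_B(b: float, c: CNTConstants | None = None,
                 b_se: float = 0.0) -> tuple[float, float]:
    """Invert B for gamma_net (mJ/m^2), with a delta-method standard error.

    gamma = (B (kB T)^3 / (F w^2))^(1/3);  SE_gamma = gamma * SE_B / (3 B).
    """
    if c is None:
        c = CNTConstants()
    if b < 0:
        raise DomainError(f"B must be >= 0, got {b}")
    if b == 0:
        return 0.0, 0.0
    w = c.molecular_volume * CM3_TO_M3
    g = (b * c.kbt**3 / (c.shape_factor * w**2)) ** (1.0 / 3.0)
    gamma = g / MJ_PER_M2_TO_J_PER_M2
    se = gamma * b_se / (3.0 * b) if b_se else 0.0
    return gamma, se


def fit_cnt(points: Sequence[RatePoint], c: CNTConstants | None = None) -> CNTFit:
    """Linearized CNT regression: ln J0 on 1/sigma^2 across supersaturations.

    The slope is -B and the intercept ln A; gamma_net follows from inverting
    B.  A positive slope (B < 0, unphysical) is flagged and gamma_net is
    reported as NaN rather than silently clipped.
    """
    if c is None:
        c = CNTConstants()
    sigmas = np.array([p.sigma for p in points], dtype=float)
    if np.unique(sigmas).size < 2:
        raise InsufficientDataError(
            "CNT fit needs >= 2 points at distinct supersaturations"
        )
    x = 1.0 / sigmas**2
    y = np.array([p.ln_j0 for p in points], dtype=float)
    fit = stats.linregress(x, y)
    b = -fit.slope
    b_se = float(fit.stderr) if fit.stderr is not None else math.nan
    ln_a_se = float(fit.intercept_stderr) if fit.intercept_stderr is not None else math.nan
    if b < 0:
        gamma, gamma_se = math.nan, math.nan
    else:
        gamma, gamma_se = gamma_from_B(b, c, b_se if math.isfinite(b_se) else 0.0)
    return CNTFit(
        ln_a=float(fit.intercept),
        ln_a_se=ln_a_se,
        b=float(b),
        b_se=b_se,
        gamma_net=gamma,
        gamma_net_se=gamma_se,
        n_points=len(points),
        r_squared=float(fit.rvalue**2),
        b_negative=b < 0,
    )


def protonated_fraction(pH: float, pKa: float) -> float:
    """Acid-base speciation fraction of the protonated amine, 1/(1+10^(pH-pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def net_charge_per_monosaccharide(ds: "DSProfile", pH: float,
                                  pKa_amine: float = 6.5) -> float:
    """Mean formal charge per monosaccharide implied by a substitution profile.

    Sulfate (O- and N-linked) and carboxyl substituents each contribute -1
    per DS unit; free amines contribute +1 weighted by their protonated
    fraction at the given pH.  At pH 10 with pKa ~6.5 the amine term is
    ~3e-4 per DS(NH2) unit, i.e. chitosan is essentially uncharged there.
    """
    for name, value in (("ds_oso3", ds.ds_oso3), ("ds_nso3", ds.ds_nso3),
                        ("ds_nh2", ds.ds_nh2), ("ds_coo", ds.ds_coo)):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0")
    negative = ds.ds_oso3 + ds.ds_nso3 + ds.ds_coo
    positive = ds.ds_nh2 * protonated_fraction(pH, pKa_amine)
    return -negative + positive
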