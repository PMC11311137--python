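"""Polymer molecular weight by dilute-solution viscometry and by PGSTE NMR
diffusometry.

Viscometry route: the intrinsic viscosity [eta] is the zero-concentration
intercept of eta_sp/c (Huggins extrapolation), and the viscosity-average
molecular weight follows from the Mark-Houwink power law

    [eta] = kappa * M_v^alpha .

Diffusometry route: the PGSTE signal attenuates with gradient strength g as
the Stejskal-Tanner relation

    I/I0 = exp( -D * gamma^2 g^2 delta^2 (Delta - delta/3) )

whose log-linear fit yields the translational diffusion coefficient D, and a
second Mark-Houwink-type law D = k * M^(-a) converts D to molecular weight.
The exponent is tied to the viscometric one by alpha = 3a - 1 and the
prefactor k is anchored on one material whose M_w is known independently
(size-exclusion chromatography).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import GAUSS_PER_CM_TO_T_PER_M, GYROMAGNETIC_1H
from .errors import DomainError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class DilutionViscositySeries:
    """Specific viscosities eta_sp = eta/eta_solvent - 1 over a dilution row."""

    concentrations: tuple[float, ...]   # g/mL
    specific_viscosities: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        e = np.asarray(self.specific_viscosities, dtype=float)
        if c.size != e.size:
            raise ValidationError("concentrations and viscosities differ in length")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be > 0")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if np.any(e <= 0):
            raise ValidationError("specific viscosities must be > 0")


@dataclass(frozen=True)
class MarkHouwinkParams:
    """kappa (mL/g) and alpha for a polymer-solvent-temperature system."""

    kappa: float
    alpha: float

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if not (0.0 < self.alpha <= 2.0):
            raise ValidationError(f"alpha must be in (0, 2], got {self.alpha}")


@dataclass(frozen=True)
class DiffusionCalibration:
    """Prefactor k and exponent a of the diffusion Mark-Houwink law D=k M^-a."""

    k: float
    a: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValidationError("k must be > 0")
        if not (0.0 < self.a <= 1.5):
            raise ValidationError(f"a must be in (0, 1.5], got {self.a}")


@dataclass(frozen=True)
class PGSTEDecay:
    """One PGSTE attenuation table with its acquisition parameters.

    gradient_strengths in G/cm (as acquired); delta_small is the gradient
    pulse length delta (s), delta_big the diffusion time Delta (s).
    """

    gradient_strengths: tuple[float, ...]
    intensities: tuple[float, ...]
    i0: float
    delta_small: float = 2e-3
    delta_big: float = 25e-3
    gyromagnetic: float = GYROMAGNETIC_1H
    noise_tolerance: float = 0.05

    def __post_init__(self):
        g = np.asarray(self.gradient_strengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if g.size != i.size:
            raise ValidationError("gradients and intensities differ in length")
        if np.any(i <= 0) or self.i0 <= 0:
            raise ValidationError("intensities must be > 0")
        if self.delta_small >= self.delta_big:
            raise ValidationError("gradient pulse length delta must be < diffusion time Delta")
        order = np.argsort(g)
        if np.any(np.diff(i[order]) > self.noise_tolerance * self.i0):
            raise ValidationError(
                "intensities must be non-increasing with gradient strength "
                "(beyond the stated noise tolerance)"
            )

    @property
    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner b factor per gradient step, s/m^2."""
        g_si = np.asarray(self.gradient_strengths, dtype=float) * GAUSS_PER_CM_TO_T_PER_M
        return (self.gyromagnetic**2 * g_si**2 * self.delta_small**2
                * (self.delta_big - self.delta_small / 3.0))


def intrinsic_viscosity(series: DilutionViscositySeries,
                        method: str = "huggins") -> tuple[float, float]:
    """[eta] (mL/g) and its standard error by dilution extrapolation.

    ``huggins`` regresses eta_sp/c on c; ``kraemer`` regresses ln(1+eta_sp)/c
    on c.  Both report the c -> 0 intercept.
    """
    c = np.asarray(series.concentrations, dtype=float)
    e = np.asarray(series.specific_viscosities, dtype=float)
    if c.size < 2:
        raise InsufficientDataError("extrapolation to c=0 needs >= 2 concentrations")
    if method == "huggins":
        y = e / c
    elif method == "kraemer":
        y = np.log1p(e) / c
    else:
        raise ValidationError(f"unknown extrapolation method {method!r}")
    fit = stats.linregress(c, y)
    se = float(fit.intercept_stderr) if fit.intercept_stderr is not None else 0.0
    if not np.isfinite(se):
        se = 0.0
    return float(fit.intercept), se


def mark_houwink_mv(eta: float, params: MarkHouwinkParams) -> float:
    """Viscosity-average molecular weight M_v = ([eta]/kappa)^(1/alpha), Da."""
    if eta <= 0:
        raise DomainError("intrinsic viscosity must be > 0")
    return (eta / params.kappa) ** (1.0 / params.alpha)


def stejskal_tanner_attenuation(d: float, gradient_strengths,
                                delta_small: float = 2e-3,
                                delta_big: float = 25e-3,
                                gyromagnetic: float = GYROMAGNETIC_1H) -> np.ndarray:
    """Forward attenuation I/I0 = exp(-D b(g)) per gradient value (G/cm)."""
    if d < 0:
        raise DomainError("diffusion coefficient must be >= 0")
    if delta_small >= delta_big:
        raise ValidationError("delta must be < Delta")
    g_si = np.asarray(gradient_strengths, dtype=float) * GAUSS_PER_CM_TO_T_PER_M
    b = gyromagnetic**2 * g_si**2 * delta_small**2 * (delta_big - delta_small / 3.0)
    return np.exp(-d * b)


def fit_diffusion(decay: PGSTEDecay) -> tuple[float, float]:
    """D (m^2/s) and its standard error from the log-linear attenuation fit.

    Regresses ln(I/I0) on the b factor; D is minus the slope.
    """
    b = decay.b_values
    if b.size < 2:
        raise InsufficientDataError("diffusion fit needs >= 2 gradient points")
    y = np.log(np.asarray(decay.intensities, dtype=float) / decay.i0)
    fit = stats.linregress(b, y)
    se = float(fit.stderr) if fit.stderr is not None else 0.0
    if not np.isfinite(se):
        se = 0.0
    return float(-fit.slope), se


def mh_exponent_from_alpha(alpha: float) -> float:
    """Convert the viscometric exponent to the diffusional one: a = (alpha+1)/3."""
    if alpha <= -1:
        raise DomainError("alpha must be > -1")
    return (alpha + 1.0) / 3.0


def calibrate_k(d_anchor: float, m_anchor: float, a: float) -> float:
    """Anchor the diffusion prefactor: k = D_anchor * M_anchor^a."""
    if d_anchor <= 0 or m_anchor <= 0 or a <= 0:
        raise DomainError("anchor D, M and exponent a must all be > 0")
    return d_anchor * m_anchor**a


def mw_from_diffusion(d: float, cal: DiffusionCalibration) -> float:
    """Molecular weight M = (k/D)^(1/a), Da."""
    if d <= 0:
        raise DomainError("diffusion coefficient must be > 0")
    return (cal.k / d) ** (1.0 / cal.a)
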