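"""Forward generators for every input the analysis pipeline consumes.

Each generator is the exact statistical inverse of one estimator in the
package: Poisson crystal-appearance counts whose rate obeys the CNT law
across the experimental supersaturation range, Stejskal-Tanner PGSTE
attenuation tables, Huggins dilution-viscosity rows, NMR integral sets
implied by a substitution profile, combustion compositions from formula
masses, and toy particle trajectories (ideal gas, fixed pairs, shell
models, hydrated-ion clusters).  All generators take an explicit integer
seed and are byte-deterministic under it; there is no hidden global RNG
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import cnt
from .characterization import DSProfile, ElementalComposition, NMRIntegrals
from .constants import (
    MASS_ACETYL_INCREMENT,
    MASS_GLUCOSAMINE_MONOMER,
    MASS_C,
    MASS_H,
    MASS_N,
    MASS_O,
    MASS_S,
    MASS_SULFATE_INCREMENT,
)
from .errors import DomainError, ValidationError
from .nucleation_kinetics import CountTimeSeries
from .polymer_mw import DilutionViscositySeries, PGSTEDecay, stejskal_tanner_attenuation
from .trajectory import TrajectoryFrame


@dataclass(frozen=True)
class NucleationScenario:
    """Study conditions for simulated nucleation experiments.

    Defaults reflect the flow-cell experiments the pipeline targets:
    supersaturations spanning the 4.61-5.74 window, a 6.13 mm^2 viewing
    window, 5-hour runs sampled every 5 min with a 10 min burn-in, and a
    CNT parameter pair (gamma_net = 60 mJ/m^2, ln A = 16.5) in the middle
    of the experimentally observed range.
    """

    gamma_net: float = 60.0           # mJ/m^2
    ln_a: float = 16.5
    sigmas: tuple[float, ...] = (4.7, 5.0, 5.3, 5.7)
    window_area: float = 6.13         # mm^2
    duration: float = 300.0           # min
    sample_interval: float = 5.0      # min
    burn_in: float = 10.0             # min
    seed: int = 0
    n_sites: float | None = None      # finite nucleation-site budget (None = off)

    def __post_init__(self):
        if not all(0.0 < s <= 10.0 for s in self.sigmas):
            raise ValidationError("sigmas must lie in (0, 10]")
        if self.duration <= self.burn_in:
            raise ValidationError("duration must exceed burn_in")
        if self.sample_interval <= 0 or self.window_area <= 0:
            raise ValidationError("sample_interval and window_area must be > 0")


def simulate_nucleation_counts(
    scenario: NucleationScenario,
    constants: cnt.CNTConstants | None = None,
) -> list[CountTimeSeries]:
    """One cumulative count series per supersaturation.

    The true rate at each sigma is J0 = exp(ln A - B/sigma^2) with B from
    the scenario's gamma_net; counts accrue as a homogeneous Poisson process
    discretized at the sampling cadence (interval counts, matching how a
    time-lapse camera bins reality).  With a finite ``n_sites`` the process
    thins by the fraction of sites already consumed (site depletion),
    saturating the count record; off by default.
    """
    if constants is None:
        constants = cnt.CNTConstants()
    rng = np.random.default_rng(scenario.seed)
    b = cnt.B_from_gamma(scenario.gamma_net, constants)
    area_m2 = scenario.window_area * 1e-6
    times = np.arange(scenario.sample_interval, scenario.duration + 1e-9,
                      scenario.sample_interval)
    out = []
    for sigma in scenario.sigmas:
        j0 = math.exp(scenario.ln_a - b / sigma**2)
        lam_per_interval = j0 * area_m2 * scenario.sample_interval * 60.0
        if scenario.n_sites is None:
            counts = np.cumsum(rng.poisson(lam_per_interval, size=times.size))
        else:
            counts = np.empty(times.size, dtype=np.int64)
            total = 0
            for i in range(times.size):
                frac_free = max(1.0 - total / scenario.n_sites, 0.0)
                total += rng.poisson(lam_per_interval * frac_free)
                counts[i] = min(total, int(scenario.n_sites))
        out.append(CountTimeSeries(
            times=tuple(times),
            counts=tuple(int(c) for c in counts),
            window_area=scenario.window_area,
            sigma=sigma,
            label=f"synthetic sigma={sigma:g}",
        ))
    return out


def simulate_pgste_decay(
    d: float,
    *,
    delta_small: float = 2e-3,
    delta_big: float = 25e-3,
    n_steps: int = 16,
    noise_sd: float = 0.0,
    target_attenuation: float = 0.9,
    i0: float = 1.0,
    seed: int = 0,
) -> PGSTEDecay:
    """PGSTE table whose gradient grid is auto-scaled so the last step
    attenuates the signal by ``target_attenuation`` (default 90%, matching
    acquisition practice of >= 85% over 16 steps).  Noise is multiplicative
    Gaussian with relative standard deviation ``noise_sd``.
    """
    if d <= 0:
        raise DomainError("diffusion coefficient must be > 0")
    if not (0.0 < target_attenuation < 1.0):
        raise ValidationError("target_attenuation must be in (0, 1)")
    from .constants import GAUSS_PER_CM_TO_T_PER_M, GYROMAGNETIC_1H
    b_factor = GYROMAGNETIC_1H**2 * delta_small**2 * (delta_big - delta_small / 3.0)
    b_needed = -math.log(1.0 - target_attenuation) / d
    g_max_si = math.sqrt(b_needed / b_factor)
    g_max = g_max_si / GAUSS_PER_CM_TO_T_PER_M       # back to G/cm
    gradients = np.linspace(g_max / n_steps, g_max, n_steps)
    signal = i0 * stejskal_tanner_attenuation(
        d, gradients, delta_small=delta_small, delta_big=delta_big
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal * (1.0 + noise_sd * rng.standard_normal(n_steps))
        signal = np.maximum(signal, 1e-12 * i0)
    return PGSTEDecay(
        gradient_strengths=tuple(gradients),
        intensities=tuple(signal),
        i0=i0,
        delta_small=delta_small,
        delta_big=delta_big,
        noise_tolerance=max(0.05, 6.0 * noise_sd),
    )


def simulate_dilution_series(
    intrinsic_viscosity: float,
    huggins_k: float = 0.35,
    concentrations=(2e-4, 4e-4, 6e-4, 8e-4, 1e-3),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionViscositySeries:
    """Huggins-model viscosity row: eta_sp = [eta] c + k_H [eta]^2 c^2."""
    c = np.asarray(concentrations, dtype=float)
    if c.size < 2:
        raise ValidationError("need >= 2 concentrations for an extrapolatable series")
    eta_sp = intrinsic_viscosity * c + huggins_k * intrinsic_viscosity**2 * c**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eta_sp = eta_sp * (1.0 + noise_sd * rng.standard_normal(c.size))
    return DilutionViscositySeries(
        concentrations=tuple(c), specific_viscosities=tuple(eta_sp)
    )


def simulate_nmr_integrals(
    ds: DSProfile,
    scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> NMRIntegrals:
    """Integrals proportional to the proton counts a DS profile implies.

    Backbone envelope: 6 protons (H2-H6) per monosaccharide; acetyl methyl:
    3 protons per acetylated monosaccharide; the three C2-H environments
    split according to the nitrogen-position fractions.
    """
    rng = np.random.default_rng(seed)

    def noisy(x):
        if noise_sd > 0 and x > 0:
            return max(x * (1.0 + noise_sd * rng.standard_normal()), 0.0)
        return x

    return NMRIntegrals(
        i_acetyl_methyl=noisy(3.0 * ds.ds_ac * scale),
        i_backbone=noisy(6.0 * scale),
        n_backbone_protons=6,
        i_c2h_nhac=noisy(ds.ds_ac * scale),
        i_c2h_nhso3=noisy(ds.ds_nso3 * scale),
        i_c2h_nh2=noisy(ds.ds_nh2 * scale),
    )


def simulate_elemental_composition(ds: DSProfile) -> ElementalComposition:
    """Combustion wt% from formula masses of the substituted monosaccharide.

    Average residue mass: anhydroglucosamine (C6H11NO4) plus the acetyl and
    sulfate increments weighted by their DS values.  Used as the forward
    stoichiometry whose S/N mole ratio the elemental DS calculator inverts.
    """
    m = (MASS_GLUCOSAMINE_MONOMER
         + ds.ds_ac * MASS_ACETYL_INCREMENT
         + ds.ds_so3_total * MASS_SULFATE_INCREMENT)
    n_c = 6.0 + 2.0 * ds.ds_ac
    n_h = 11.0 + 2.0 * ds.ds_ac
    n_o = 4.0 + ds.ds_ac + 3.0 * ds.ds_so3_total
    return ElementalComposition(
        wt_c=100.0 * n_c * MASS_C / m,
        wt_h=100.0 * n_h * MASS_H / m,
        wt_n=100.0 * MASS_N / m,
        wt_s=100.0 * ds.ds_so3_total * MASS_S / m,
    )


def simulate_trajectory(kind: str, params: dict | None = None,
                        seed: int = 0) -> list[TrajectoryFrame]:
    """Toy trajectories with known structure for validating the RDF stack.

    kinds
    -----
    ideal_gas : uniform random positions (g(r) = 1 null model)
        params: n (500), box (25.0), n_frames (200), label ("X")
    fixed_pair : two particles at separation d
        params: d (5.0), box (20.0), labels (("A", "B")), n_frames (1)
    two_shell : central particle with neighbours Gaussian-scattered on
        concentric shells
        params: radii ((5.0, 9.0)), occupancies ((6, 3)), width (0.2),
        box (30.0), n_frames (100), center_label ("S"), shell_label ("Ca")
    hydrated_ion : central Ca with n waters on a hydration shell
        params: n_waters (7), shell_radius (2.4), box (20.0), n_frames (50)
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        n = int(params.get("n", 500))
        box = float(params.get("box", 25.0))
        n_frames = int(params.get("n_frames", 200))
        label = params.get("label", "X")
        labels = tuple([label] * n)
        return [
            TrajectoryFrame(rng.uniform(0.0, box, size=(n, 3)), labels,
                            (box, box, box), periodic=True)
            for _ in range(n_frames)
        ]
    if kind == "fixed_pair":
        d = float(params.get("d", 5.0))
        box = float(params.get("box", 20.0))
        labels = tuple(params.get("labels", ("A", "B")))
        n_frames = int(params.get("n_frames", 1))
        pos = np.array([[box / 2 - d / 2, box / 2, box / 2],
                        [box / 2 + d / 2, box / 2, box / 2]])
        return [TrajectoryFrame(pos.copy(), labels, (box, box, box), periodic=True)
                for _ in range(n_frames)]
    if kind == "two_shell":
        radii = tuple(params.get("radii", (5.0, 9.0)))
        occupancies = tuple(params.get("occupancies", (6, 3)))
        width = float(params.get("width", 0.2))
        box = float(params.get("box", 30.0))
        n_frames = int(params.get("n_frames", 100))
        center_label = params.get("center_label", "S")
        shell_label = params.get("shell_label", "Ca")
        if len(radii) != len(occupancies):
            raise ValidationError("radii and occupancies must match in length")
        center = np.full(3, box / 2)
        labels = (center_label,) + (shell_label,) * int(sum(occupancies))
        frames = []
        for _ in range(n_frames):
            pts = [center]
            for radius, occ in zip(radii, occupancies):
                directions = rng.standard_normal((int(occ), 3))
                directions /= np.linalg.norm(directions, axis=1, keepdims=True)
                r = radius + width * rng.standard_normal(int(occ))
                pts.append(center + directions * r[:, None])
            frames.append(TrajectoryFrame(np.vstack(pts), labels,
                                          (box, box, box), periodic=True))
        return frames
    if kind == "hydrated_ion":
        n_waters = int(params.get("n_waters", 7))
        shell_radius = float(params.get("shell_radius", 2.4))
        box = float(params.get("box", 20.0))
        n_frames = int(params.get("n_frames", 50))
        center = np.full(3, box / 2)
        labels = ("Ca",) + ("O_water",) * n_waters
        frames = []
        for _ in range(n_frames):
            directions = rng.standard_normal((n_waters, 3))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            pos = np.vstack([center, center + directions * shell_radius])
            frames.append(TrajectoryFrame(pos, labels, (box, box, box),
                                          periodic=True))
        return frames
    raise ValidationError(f"unknown trajectory kind {kind!r}")
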