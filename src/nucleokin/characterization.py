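"""Degrees of substitution and cross-linking ceilings for chitosan materials.

DS(X) is the average number of substituent X per monosaccharide.  Acetyl
content comes from the ratio of the acetyl methyl integral (3 H) to the
backbone proton envelope; N-sulfation from the relative areas of the three
resolved C2-H environments (NHAc / NHSO3- / NH2); total sulfation from the
S/N mole ratio of combustion elemental analysis (one nitrogen per
glucosamine monosaccharide).  The amine fraction follows by difference from
closure at the nitrogen position: DS(Ac) + DS(NSO3-) + DS(NH2) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    MASS_GLUTARALDEHYDE,
    MASS_GLUCOSAMINE_MONOMER,
    MASS_N,
    MASS_S,
)
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class NMRIntegrals:
    """1H peak integrals needed by the DS calculators.

    i_acetyl_methyl : acetyl CH3 integral (3 protons per acetyl)
    i_backbone : backbone envelope integral (default bookkeeping: the 6
        protons H2-H6; H1 is excluded because it can be obscured by the
        water resonance); n_backbone_protons makes the choice explicit.
    i_c2h_* : the three resolved C2-H environments of N-sulfated materials.
    """

    i_acetyl_methyl: float = 0.0
    i_backbone: float = 0.0
    n_backbone_protons: int = 6
    i_c2h_nhac: float = 0.0
    i_c2h_nhso3: float = 0.0
    i_c2h_nh2: float = 0.0

    def __post_init__(self):
        for name in ("i_acetyl_methyl", "i_backbone", "i_c2h_nhac",
                     "i_c2h_nhso3", "i_c2h_nh2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_backbone_protons not in (6, 7):
            raise ValidationError("n_backbone_protons must be 6 (H2-H6) or 7 (H1-H6)")


@dataclass(frozen=True)
class ElementalComposition:
    """Combustion elemental analysis, mass percent."""

    wt_c: float = 0.0
    wt_h: float = 0.0
    wt_n: float = 0.0
    wt_s: float = 0.0

    def __post_init__(self):
        total = 0.0
        for name in ("wt_c", "wt_h", "wt_n", "wt_s"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
            total += v
        if total > 100.0 + 1e-9:
            raise ValidationError(f"element mass percentages sum to {total} > 100")


@dataclass(frozen=True)
class DSProfile:
    """Per-monosaccharide substitution profile driving charge and mass math.

    The nitrogen position closes: ds_ac + ds_nso3 + ds_nh2 = 1.  O-sulfation
    may exceed 1 (up to 2) only when sulfation of the second hydroxyl (C3-O)
    is allowed.  ds_coo covers carboxymethylated materials.
    """

    ds_ac: float
    ds_oso3: float = 0.0
    ds_nso3: float = 0.0
    ds_nh2: float = 0.0
    ds_coo: float = 0.0
    allow_c3o_sulfation: bool = False

    def __post_init__(self):
        for name in ("ds_ac", "ds_nso3", "ds_nh2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        oso3_cap = 2.0 if self.allow_c3o_sulfation else 1.0
        if not (0.0 <= self.ds_oso3 <= oso3_cap):
            raise ValidationError(
                f"ds_oso3 must be in [0, {oso3_cap}], got {self.ds_oso3}"
            )
        if self.ds_coo < 0:
            raise ValidationError("ds_coo must be >= 0")
        n_total = self.ds_ac + self.ds_nso3 + self.ds_nh2
        if n_total > 1.0 + 1e-9:
            raise ValidationError(
                f"nitrogen-position DS values sum to {n_total} > 1"
            )

    @property
    def ds_so3_total(self) -> float:
        return self.ds_oso3 + self.ds_nso3


@dataclass(frozen=True)
class CrosslinkRecipe:
    """Film-casting recipe for glutaraldehyde cross-linking.

    polymer_mass_fraction is w/v as a fraction (2% -> 0.02 g/mL);
    mass_ratio is polymer:crosslinker by mass (4:1 -> 4.0).
    """

    polymer_mass_fraction: float = 0.02
    mass_ratio: float = 4.0
    crosslinker_molar_mass: float = MASS_GLUTARALDEHYDE
    monomer_molar_mass: float = MASS_GLUCOSAMINE_MONOMER
    reactive_sites_per_monomer: float | None = None

    def __post_init__(self):
        for name in ("polymer_mass_fraction", "mass_ratio",
                     "crosslinker_molar_mass", "monomer_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def ds_acetyl_from_nmr(nmr: NMRIntegrals) -> float:
    """DS(Ac) = (I_CH3 / 3) / (I_backbone / n_backbone_protons)."""
    if nmr.i_backbone <= 0:
        raise DomainError("backbone integral must be > 0")
    return (nmr.i_acetyl_methyl / 3.0) / (nmr.i_backbone / nmr.n_backbone_protons)


def ds_nsulfate_from_nmr(nmr: NMRIntegrals) -> float:
    """DS(NSO3-) from the three resolved C2-H integrals."""
    total = nmr.i_c2h_nhac + nmr.i_c2h_nhso3 + nmr.i_c2h_nh2
    if total <= 0:
        raise DomainError("C2-H integrals are all zero")
    return nmr.i_c2h_nhso3 / total


def ds_sulfate_from_elemental(elem: ElementalComposition) -> float:
    """Total DS(SO3-) as the S/N mole ratio (one N per monosaccharide)."""
    if elem.wt_n <= 0:
        raise DomainError("nitrogen mass percent must be > 0")
    return (elem.wt_s / MASS_S) / (elem.wt_n / MASS_N)


def ds_amine_by_difference(ds_ac: float, ds_nso3: float) -> float:
    """DS(NH2) = 1 - DS(Ac) - DS(NSO3-) from nitrogen-position closure."""
    if ds_ac < 0 or ds_nso3 < 0:
        raise ValidationError("DS inputs must be >= 0")
    if ds_ac + ds_nso3 > 1.0 + 1e-12:
        raise ValidationError(
            f"DS(Ac) + DS(NSO3) = {ds_ac + ds_nso3} exceeds 1: inconsistent inputs"
        )
    return 1.0 - ds_ac - ds_nso3


def max_crosslink_fraction(recipe: CrosslinkRecipe, ds: DSProfile | None = None) -> float:
    """Theoretical ceiling on the cross-linked site fraction, in percent.

    Computed as ``min(100, 100 * 2 * n_crosslinker / n_reactive_sites)``:
    each glutaraldehyde is bifunctional (2 aldehyde ends, so it can cap two
    polymer sites), and the reactive-site count per monomer defaults to the
    free-amine fraction DS(NH2) of the supplied profile (the dominant
    glutaraldehyde target) unless ``recipe.reactive_sites_per_monomer``
    overrides it.  This is an upper bound by construction: dynamic imine
    chemistry, sterics and viscosity keep real films below it, and no claim
    of equality with any particular experimental estimate is made.
    """
    if recipe.reactive_sites_per_monomer is not None:
        sites_per_monomer = recipe.reactive_sites_per_monomer
    elif ds is not None:
        sites_per_monomer = ds.ds_nh2
    else:
        raise ValidationError(
            "provide either recipe.reactive_sites_per_monomer or a DSProfile"
        )
    # per mL of casting solution
    m_polymer = recipe.polymer_mass_fraction
    m_crosslinker = m_polymer / recipe.mass_ratio
    n_crosslinker = m_crosslinker / recipe.crosslinker_molar_mass
    n_sites = (m_polymer / recipe.monomer_molar_mass) * sites_per_monomer
    if n_sites <= 0:
        raise DomainError("reactive-site count is zero")
    if n_crosslinker == 0:
        return 0.0
    return min(100.0, 100.0 * 2.0 * n_crosslinker / n_sites)


def ds_amine_max_xl(ds_nh2: float, max_xl_percent: float) -> float:
    """Residual amine DS after maximal cross-linking: DS(NH2) * maxXL / 100."""
    if not (0.0 <= ds_nh2 <= 1.0):
        raise ValidationError(f"ds_nh2 must be in [0, 1], got {ds_nh2}")
    if not (0.0 <= max_xl_percent <= 100.0):
        raise ValidationError(
            f"max_xl_percent must be in [0, 100], got {max_xl_percent}"
        )
    return ds_nh2 * max_xl_percent / 100.0
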