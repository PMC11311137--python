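# Methods

This note documents the models implemented in `nucleokin`, the assumptions
they make, the defaults they ship with, and the limits of what the test
suite demonstrates.

## Carbonate speciation and supersaturation

`speciation.solve_carbonate_system` distributes total dissolved carbonate
over CO₂(aq), HCO₃⁻ and CO₃²⁻ at a fixed pH (the experiments are
pH-statted at 10) using the carbonic-acid constants pK1 = 6.35,
pK2 = 10.33 and pKw = 14.00 at 25 °C; all constants are overridable
through `EquilibriumConstants`.  Single-ion activity coefficients come
from the Davies equation, log₁₀ γ = −A z² (√I/(1+√I) − 0.3 I), with
A = 0.5092 (25 °C).  The temperature dependence of A between 22 and 25 °C
is sub-percent and is not modelled.  Ionic strength and the activity
coefficients are mutually converged by fixed-point iteration (relative
tolerance 10⁻¹⁰, at most 100 iterations; non-convergence raises with the
residual).

Supersaturation follows the convention σ = ln(a_Ca·a_CO₃/K_sp) with
calcite K_sp = 10⁻⁸·⁴⁸ at 25 °C.  Note σ here is a natural logarithm: a
two-decade ion-activity-product ratio (the amorphous-calcium-carbonate
versus calcite solubility contrast, 10⁻⁶·⁴⁸ vs 10⁻⁸·⁴⁸) corresponds to
σ = 2 ln 10 = 4.61, the lower end of the experimental range.

Calcium–carbonate ion pairs (CaCO₃⁰, CaHCO₃⁺) are **excluded by default**,
a deliberate simplification relative to full geochemical speciation codes;
passing `ion_pairs={"CaCO3": logK, "CaHCO3": logK}` enables them with
user-supplied association constants, solved by an inner mass-balance root
find.  There is no CO₂ degassing, no temperature correction of the
equilibrium constants beyond configuration, and no other complexation.
The Ca/CO₃ activity ratio is reported as a diagnostic (experimental
recipes aim at ≈1) but never enforced.

## Counts → rates

A nucleation experiment yields cumulative crystallite counts in an optical
window (6.13 or 1.53 mm² at the two magnifications), time-stamped in
minutes.  Two assumptions connect counts to nucleation: each crystallite
descends from a single nucleus (so decreasing counts are a validation
error, not data), and crystallites do not interact during the interval
where density grows linearly.

`estimate_J0` converts to SI density (counts / window area, m⁻²; time in
s), discards a configurable burn-in (default 10 min, the initial
high-flow-rate period), selects the **longest contiguous window whose OLS
fit has R² ≥ 0.95** with at least 4 points (ties to the earliest start;
both thresholds configurable — no published criterion exists for "the
linear portion", so the rule is explicit and exhaustively testable), and
reports the OLS slope as J₀.

The slope's standard error deserves a note.  Cumulative counts are a sum
of independent increments, so the regression errors are a random walk and
the textbook iid-residual OLS standard error understates the slope
uncertainty several-fold (measured three-SE coverage ≈25%).  `j0_se` is
therefore a sandwich standard error built from Cov(y_i, y_j) = λ·min(t_i,
t_j) with the increment-variance rate λ estimated by moments from the
observed increments.  It is exactly zero on noise-free data and calibrated
on Poisson data (measured three-SE coverage 99.5% over 200 replicates).
Plain OLS (unweighted) remains the point estimator; an optional
Poisson-weighted (1/count) fit is available but off by default, matching
how such data are usually treated.

## The CNT fit and γ_net

`cnt.fit_cnt` regresses ln J₀ on 1/σ² (unweighted OLS by default;
inverse-variance weights optional).  The intercept is ln A, minus the
slope is B, and

    γ_net = ( B (k_B T)³ / (F ω²) )^(1/3)

with defaults F = 16π/3 (spherical nucleus), ω = 6.13×10⁻²³ cm³ per CaCO₃
formula unit in calcite (polymorph-specific values are configuration, not
code), and T = 295.15 K (22 °C, the experiment temperature; literature
comparisons at 25 °C use the override).  The standard error of γ_net
comes from the delta method, SE_γ = γ·SE_B/(3B), which the tests verify
against a parametric residual bootstrap at n = 6 points.  An unphysical
positive slope (B < 0) is flagged and γ_net reported as NaN — never
clipped.  Reports round γ_net to integer mJ m⁻²; JSON carries full
precision.

The decomposition of γ_net into its three interface contributions,
h·γ_net = γ_cal–soln + γ_cal–PS − γ_PS–soln (h an auxiliary shape factor),
is documented here as an identity only: none of its components is
measurable from the data this package consumes, so no operation computes
it and `CNTConstants.h_shape` (default 1) is metadata.

Net charge per monosaccharide is −(DS(OSO₃⁻) + DS(NSO₃⁻) + DS(COO⁻)) plus
DS(NH₂) weighted by the protonated amine fraction 1/(1+10^(pH−pKa)),
pKa 6.5 by default — at pH 10 chitosan is effectively neutral (≈+3×10⁻⁴
per amine unit).

## Degrees of substitution

- **DS(Ac)** = (I_CH₃/3)/(I_backbone/n): the backbone envelope defaults to
  the six protons H2–H6, because the anomeric H1 resonance can be obscured
  by the water signal; `n_backbone_protons = 7` switches to H1–H6
  bookkeeping if a spectrum resolves it.
- **DS(NSO₃⁻)** is the fractional area of the C₂–H(NHSO₃⁻) environment
  among the three resolved C₂–H peaks.
- **DS(SO₃⁻) (total)** from combustion analysis is the S/N mole ratio with
  M_S = 32.06, M_N = 14.007 (IUPAC 2021), assuming all sulfur is bound
  sulfate and exactly one nitrogen per glucosamine monosaccharide.
- **DS(NH₂)** follows from nitrogen-position closure, 1 − DS(Ac) −
  DS(NSO₃⁻).

The glutaraldehyde cross-linking ceiling is a mole-ratio bound:
min(100, 100·2·n_crosslinker/n_sites), with n values from the casting
recipe (2% w/v polymer, 4:1 polymer:crosslinker by mass as defaults) and
reactive sites per monomer taken from the free-amine DS unless overridden.
This is an upper bound by construction — dynamic imine exchange, sterics
and viscosity keep real films below it — and the functional form is a
package choice: published estimates of this quantity use thermoset-plastic
relations whose exact form is not recoverable, so no equality with any
particular experimental value is asserted anywhere.

## Molecular weight

**Viscometry.** Intrinsic viscosity is the c → 0 intercept of η_sp/c
(Huggins, default) or ln(1+η_sp)/c (Kraemer, optional); the experimental
reports this package targets do not state which extrapolation was used, so
both are provided and the default is the more common one.  M_v then
follows from [η] = κ·M_vᵅ with user-supplied κ and α (for chitosan at the
relevant conditions: κ = 4.44×10⁻⁵ mL/g, α = 1.26; the DS/pH/ionic-
strength regressions that produce such pairs are inputs, not
reimplemented).

**Diffusometry.** The PGSTE attenuation is I/I₀ = exp(−D γ² g² δ² (Δ −
δ/3)) with γ_1H = 26.75×10⁷ rad T⁻¹ s⁻¹; gradients are accepted in G/cm
and converted ×0.01 to T/m.  D is minus the slope of ln(I/I₀) on the b
factor.  Molecular weight uses D = k·M⁻ᵃ with a = (α+1)/3 (= 0.75 for
chitosan's α = 1.26) and k anchored on one material of independently known
M_w (size-exclusion chromatography): k = D_anchor·M_anchorᵃ.  With the
published anchors this gives k = 1.39×10⁻⁷ (O-sulfated, 46 kDa anchor)
and 1.09×10⁻⁷ mL/g-convention (N-sulfated, 37 kDa anchor).  Because the
anchor row re-estimated with a three-significant-figure k can shift by
±1 kDa, the tests assert the anchor rows to that rounding and the
non-anchor rows to the nearest kDa.

## Trajectory metrics

The RDF is a native implementation: per frame, A–B minimum-image distances
in an orthorhombic periodic box are histogrammed (default bin 0.1 Å — the
binning used by common visualization tools is not standardized, so it is
explicit here) and normalized by the ideal-gas shell count 4πr²Δr·ρ_B with
ρ_B = N_B/V (N_B − 1 per reference particle for like pairs; self-pairs
excluded).  r_max may not exceed half the smallest box edge when periodic.
Triclinic boxes are out of scope.  The implementation is cross-checked in
the tests against MDAnalysis' InterRDF on identical coordinates
(agreement to ~10⁻⁶).

Coordination numbers are computed by direct per-frame counting (default)
or by integrating the binned RDF, 4πρ_B Σ g r² Δr; the two agree within
binning tolerance and both are tested.  The most-probable separation is
the global-maximum bin (ties toward smaller r); the first-approach
distance is the smallest bin with g above a noise floor (default 0).
Ion-pairing classification uses the first-peak position with closed upper
bounds: ≤3.2 Å contact, ≤5.6 Å solvent-shared, else solvent-separated.
These cutoffs are heuristics exposed in configuration; physically they
bracket one (~2.8 Å) and two water-layer separations for Ca²⁺–S.

Species are selected purely by label string (e.g. waters are particles
labelled `O_water`); no chemical topology is inferred.

## Synthetic data: what it emulates, and what it does not

Every estimator has a generator that is its exact zero-noise inverse, all
seeded explicitly with no hidden RNG state:

- **Nucleation counts**: homogeneous Poisson interval counts at rate
  J₀(σ)·A_window with J₀ from the CNT law — defaults γ_net = 60 mJ m⁻²,
  ln A = 16.5 (mid-range of the experimentally observed parameters),
  σ ∈ {4.7, 5.0, 5.3, 5.7} spanning the experimental 4.61–5.74 window,
  6.13 mm² window, 300 min sampled every 5 min.  Interval counts (rather
  than event times) match how a time-lapse camera discretizes reality.
  Not emulated: post-nucleation growth, crystallite coalescence, site
  depletion (a saturation model exists as an option but is off by
  default), flow-rate transients.
- **PGSTE decays**: 16 gradient steps auto-scaled to ≈90% final
  attenuation (acquisition practice is ≥85%), multiplicative Gaussian
  noise; δ = 2 ms, Δ = 25 ms defaults.  Not emulated: convection
  artifacts, baseline/phase errors, polydispersity (a single D).
- **Dilution viscosity**: η_sp = [η]c + k_H[η]²c² with k_H = 0.35, a
  typical Huggins constant for flexible polyelectrolytes at moderate
  ionic strength.
- **NMR integrals**: proportional to the proton counts a DS profile
  implies; no peak overlap, baseline or relaxation weighting.
- **Trajectories**: ideal gas (the g = 1 null), fixed pairs, Gaussian
  shell models, and an n-water hydration shell — structural nulls, not
  physical simulations.

Consequently, passing tests demonstrate that the estimators are correct
and calibrated **under their own statistical assumptions**, not that those
assumptions hold for any given instrument or force field.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicates (γ_net recovery, rate-SE coverage),
100 seeds (diffusion-fit bias), 1000 seeds (Poisson moment check), and
ideal-gas trajectories of 500 particles × 200 frames — sizes at which the
asserted tolerances hold with comfortable margins while the whole suite
runs in well under a minute.  Ties in regime detection break toward the
earliest window; ties in the RDF maximum toward smaller r; flat data are
assigned R² = 1 (a zero-slope line fits them exactly).  All fits are
ordinary least squares via `scipy.stats.linregress` unless a weighted
option is requested.

## Known limitations

- The speciation model is deliberately minimal; against a full
  geochemical code it will differ at the percent level through neglected
  ion pairs (unless enabled) and minor species.
- Linear-regime selection is a heuristic; on strongly curved data the
  longest-window rule can include points a human would exclude.  The R²
  threshold and minimum window length are the controls.
- The cross-linking ceiling's reactive-site rule is a modelling choice;
  its absolute values should not be compared across studies that count
  sites differently.
- RDFs require enough frames for their normalization to converge;
  single-frame RDFs are exact only for rigid geometries.
- No image processing: crystal counts are inputs.  No MD engine: only
  post-trajectory analysis is implemented.
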