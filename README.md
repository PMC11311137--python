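# nucleokin

Analysis pipeline for heterogeneous CaCO₃ (calcite) nucleation kinetics on
polysaccharide substrates — from solution chemistry and crystal-count time
series to classical-nucleation-theory (CNT) parameters — together with the
polysaccharide characterization and molecular-simulation structure metrics
that contextualize them.

It is written for researchers who measure crystal nucleation rates on
functionalized biopolymer films (e.g. sulfated or carboxymethylated
chitosans) in flow-cell assays and want a tested, scriptable route from raw
observables to thermodynamic and kinetic parameters.

## The model

The steady-state areal nucleation rate obeys the CNT law

    J₀ = A · exp(−Δg_c / k_B T),       Δg_c = F ω² γ_net³ / (k_B T σ)²

where σ = ln(a_Ca²⁺ · a_CO₃²⁻ / K_sp) is the supersaturation (calcite
K_sp = 10⁻⁸·⁴⁸), F = 16π/3 is the nucleus shape factor, ω = 6.13×10⁻²³ cm³
the molecular volume of calcite, and γ_net (mJ m⁻²) the effective
interfacial free energy of the crystal–substrate–solution system.
Defining B = F ω² γ_net³ / (k_B T)³ gives the linear form

    ln J₀ = ln A − B / σ²

so regressing ln J₀ on 1/σ² across experiments at several supersaturations
yields the kinetic prefactor ln A (intercept) and the thermodynamic
parameter B (−slope), and inverting B gives γ_net.

Around that core the package implements:

- **speciation** — simplified carbonate equilibrium at fixed pH with Davies
  activity coefficients → ion activities, ionic strength, σ.
- **nucleation_kinetics** — cumulative crystal counts in a viewing window →
  areal rate J₀ (m⁻² s⁻¹) with a calibrated standard error, selecting the
  linear regime automatically.
- **cnt** — the rate law, the linearized fit, the B ↔ γ_net conversion
  (delta-method errors), and net charge per monosaccharide.
- **characterization** — degrees of substitution (acetyl, N-/O-sulfate,
  amine) from ¹H-NMR integrals and elemental analysis; glutaraldehyde
  cross-linking ceilings.
- **polymer_mw** — intrinsic viscosity (Huggins/Kraemer extrapolation) and
  Mark–Houwink M_v; PGSTE NMR attenuation (Stejskal–Tanner) → diffusion
  coefficient → molecular weight via an anchored D = k·M⁻ᵃ calibration.
- **trajectory** — native radial distribution functions (periodic
  minimum-image), coordination numbers, most-probable / first-approach
  distances, and contact / solvent-shared / solvent-separated ion-pair
  classification.
- **synthetic** — seeded forward generators for every input (Poisson
  nucleation counts, PGSTE decays, dilution series, NMR integral sets,
  toy trajectories), each the exact statistical inverse of one estimator.
- **io / pipeline / cli** — plain-text readers and writers, a TOML-driven
  end-to-end pipeline with a provenance-carrying JSON report, and the
  `nucleokin` command-line tool.

## Worked example

Simulate four flow-cell experiments at σ ∈ {4.7, 5.0, 5.3, 5.7} with true
γ_net = 60 mJ m⁻² and ln A = 16.5, estimate a rate per experiment, and fit
the CNT line:

```sh
nucleokin simulate nucleation --seed 5 --out sim
for f in sim_sigma*.csv; do nucleokin rate --input $f; done
# collect sigma,j0,j0_se into rates.csv, then:
nucleokin cntfit --rates rates.csv --temp-c 22
```

prints (abridged):

```
sigma,j0,j0_se
4.7,1624.87,133.19
5.0,4441.66,203.61
5.3,11101.79,283.83
5.7,29301.68,654.46

{
  "b": 200.26,  "b_se": 2.47,
  "ln_a": 16.44,  "ln_a_se": 0.095,
  "gamma_net_mJ_per_m2": 59.93,  "gamma_net_se": 0.25,
  "gamma_net_rounded": 60,
  "r_squared": 0.9997
}
```

The per-experiment rates rise steeply with σ as the CNT law demands; the
fitted slope B ≈ 200 inverts to γ_net ≈ 60 mJ m⁻², recovering the
generating parameters within one standard error.  The same computation is
available in Python via `nucleokin.cnt.fit_cnt` on `RatePoint` records, and
the whole chain (many materials, many experiments each, plus the
γ_net-versus-net-charge trend) via `nucleokin run --config pipeline.toml`.

Other one-liners:

```sh
nucleokin speciate --recipe recipe.toml          # activities, I, sigma
nucleokin charact --nmr nmr.toml                 # DS(Ac), DS(NSO3-), DS(NH2)
nucleokin mw --dilution dil.csv --kappa 4.44e-5 --alpha 1.26
nucleokin rdf --traj frames.xyz --a S_sulfate --b Ca --bin 0.1 --out rdf.csv
```

## Documentation

`docs/methods.md` describes the models, assumptions, parameter defaults,
numerical choices, what the synthetic generators do and do not emulate, and
known limitations.
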