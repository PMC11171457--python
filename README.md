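# metadf

Free-energy pipelines for small-molecule adsorption at hydrated oxide
surfaces: metadynamics with on-the-fly thermodynamic integration of
unbiased mean forces, the adsorption-layer free-energy integral, and the
Langmuir/EIS route from charge-transfer resistance to ΔG — implemented as
a fully synthetic, testable reconstruction of a glycine-on-TiO₂ (anatase)
adsorption study, so that every stage of such a determination can be
exercised and validated without an ab initio MD engine.

## Who this is for

People who analyse enhanced-sampling free-energy calculations or
impedance-derived adsorption isotherms and want a desk-scale, fully
controlled test bed: every estimator in the chain runs against an
analytic ground truth, and every synthetic generator emulates a concrete
feature of the real system (two adsorption modes, layered interfacial
water, Langmuir-shaped R_ct responses with replicate noise).

## The science in brief

**Simulation route.** The free-energy surface is spanned by the
surface-separation distance *z* of the ammonium group (Å) and an internal
molecular angle γ. Langevin walkers sample it under a metadynamics bias
V(z, γ, t) (Gaussian hills), while the *unbiased* physical force along
*z* is recorded every step, before the bias correction. The PMF is then
the thermodynamic integral of the bias-reweighted conditional mean force

    A(z) = −∫_{r_c}^{z} ⟨F(z′)⟩ dz′,
    ⟨F⟩(bin) = Σ w_i F_i / Σ w_i,   w_i = exp(+V(x_i, t_i)/k_B T),

referenced to zero in the bulk window before the 1 nm wall. The
adsorption free energy over a layer of thickness δ starting at the solid
onset r_c is the normalized Boltzmann integral

    ΔG = −k_B T · ln[(1/δ) ∫_{r_c}^{r_c+δ} e^{−A(z)/k_B T} dz],

and a two-mode PMF decomposes into the contact mode M1, the
solvent-separated mode M2 and the barrier between them, with the total

    ΔG_total = ΔG_M1 + ΔG_M2 + (barrier height).

**Experimental route.** Coverage from charge-transfer resistance,
Θ = (R_ct − R_ct0)/(R_ct∞ − R_ct0), follows the Langmuir isotherm
Θ = K·C/(1+K·C); raw R_ct replicates are fitted jointly by nonlinear
least squares and ΔG = −R·T·ln(K·C°) with C° = 1 M.

The default synthetic landscape is calibrated so its γ-averaged PMF has
minima of −27 (M1) and −8 kJ/mol (M2) separated by a +5 kJ/mol barrier,
with layered interfacial water near 2.3 / 3.0 / 5.0 Å and an N–H···O
hydrogen-bond distance of ≈1.6 Å in the companion hydration fixtures.

## Worked example

```bash
metadf simulate --out-prefix run           # biased sampling → COLVAR + HILLS
metadf pmf run.colvar --out-prefix run     # forces → PMF → ΔG report
```

With the default configuration (100 000 steps × 4 walkers) the ΔG report
printed by `metadf pmf` reads, abridged:

```json
{
  "dg_layer": -19.4,
  "modes": "double",
  "m1":      {"z": 2.85, "A": -26.19, "dg": -23.5},
  "m2":      {"z": 5.15, "A": -7.87, "dg": -6.1},
  "barrier": {"z": 3.75, "height": 4.98},
  "dg_total_composed": -24.7
}
```

`m1.A`/`m2.A` are the PMF well depths recovered by force integration
(exact values −27 and −8 kJ/mol), `barrier.height` the inter-mode barrier
(exact 5 kJ/mol), `dg` the per-mode layer integrals over each mode's own
layer, and `dg_total_composed` their composition with the barrier. The
experimental route:

```bash
metadf isotherm-sim --out iso.csv          # synthetic two-replicate R_ct table
metadf isotherm iso.csv
# → "K_per_M": 2.76e5, "dg_kJ_mol": -31.06, "ci95_dg": [-31.2, -30.9], ...
```

i.e. an equilibrium constant near 2.7×10⁵ M⁻¹, ΔG ≈ −31 kJ/mol at
298.15 K with a residual-bootstrap confidence interval. Other
subcommands: `adsorb` (ΔG from a PMF TSV), `density` (interfacial water
profile from XYZ), `benchmark` (estimator convergence comparison),
`show-config` (all defaults).

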