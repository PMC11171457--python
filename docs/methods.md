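# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Units throughout: Å, kJ/mol, ps, rad, K;
kB = 0.0083144621 kJ/(mol·K).

## The model landscape

The synthetic free-energy surface U(z, γ) emulates a zwitterionic amino
acid approaching a hydrated oxide slab: *z* is the surface-separation
distance of the anchoring ammonium group, γ an internal molecular angle,
periodic on [−π, π). The functional form is a sum of three Gaussians in
*z* (two wells, one barrier term) multiplied by a C² smoothstep that is
identically zero beyond 8 Å, plus, in 2-D, a non-negative γ-coupling term
c(z)·(1 − cos mγ) whose amplitude is a Gaussian envelope in *z* times the
same switch. The landscape is therefore exactly zero — value and
gradient — throughout the bulk window [z_wall − 2 Å, z_wall], which fixes
the PMF reference without any fitting.

Default geometry: r_c = 2.0, z_M1 = 2.8, z_B = 4.2, z_M2 = 5.2,
z_wall = 10.0 Å ("1 nm" wall); widths 0.35/0.60/0.35 Å; depths
d_M1 = −27, d_M2 = −8, barrier b = +5 kJ/mol; γ-coupling amplitude
3 kJ/mol (envelope centered on the contact well, width 1 Å), first
harmonic. The contact-well span (~1.5 Å) and the well/barrier energetics
mirror the two binding modes of an ammonium group at an anatase-like
interface: direct contact with bridging oxygens (M1) and
solvent-mediated binding through the second water layer (M2).

**Calibration.** The printed well depths and barrier are features of the
*PMF*, not of any fixed-γ slice, so for 2-D landscapes the three Gaussian
amplitudes are calibrated against the γ-Boltzmann-averaged profile
A(z) = −kBT ln ∫ e^(−U/kBT) dγ. Because A is linear in the amplitudes at
fixed z (the γ-entropy term does not depend on them), a damped fixed-point
iteration — solve the 3×3 linear system at the nominal centers against
iteratively corrected targets, re-locate the extrema on a 0.005 Å grid —
converges to |error| < 1e-7 kJ/mol in a few dozen iterations. For
overlapping Gaussians the barrier top does not sit at the nominal z_B
(defaults put it near 3.75 Å); only the extremal *values* are
constrained. 1-D landscapes calibrate the potential itself. The barrier
width default (0.60 Å) is the smallest round value for which the
requested −27/−3/−8 extremal structure is realizable with a smooth single
barrier.

**PMF oracle.** exact_pmf integrates over γ with a periodic trapezoid
rule (128 nodes by default), which is spectrally accurate for these
smooth periodic integrands; doubling the order changes A by < 1e-8.

## Sampler

Underdamped Langevin dynamics with the BAOAB splitting, one force
evaluation per step. Defaults: Δt = 0.002 ps, friction 2 ps⁻¹, masses
50 u (z) and 10 u·Å² (γ), 300 K, 4 walkers. Energies in kJ/mol convert
to u·Å²/ps² via the factor 100. Walls: one-sided harmonics
(500 kJ/mol/Å²) beyond z_wall and below r_c − 0.5 Å. The recorded
physical force F_phys is the landscape force only — bias and wall
excluded — which is what the thermodynamic-integration estimator needs.
Walkers run in lock-step and share one hill history; each deposits a
hill every `stride` steps in walker order. Per-walker noise streams are
spawned from a single seed sequence, making runs bit-for-bit
reproducible; the long-run benchmark kernel instead uses numba's global
PRNG seeded per run (equally deterministic, single stream).

The paper-scale MD details (thermostat, walker count, CV masses) are not
part of the study's printed record; the defaults above were chosen once
for fast decorrelation on the model landscape and are all exposed in the
configuration.

## Bias

Standard metadynamics by default: hills of height w0 = 1 kJ/mol,
σ_z = 0.2 Å, σ_γ = 0.25 rad, stride 100 steps; well-tempered scaling
(height w0·e^(−V/kBΔT), ΔT = (biasfactor−1)·T) available with biasfactor
10. Hill evaluation in the API is exact summation (6σ cutoff per hill,
error < 1e-5 of a unit hill even for 10⁴ stacked hills); an optional
bicubic-spline grid cache (0.01 Å × 0.01 rad) agrees with the exact sum
to ≲1e-6 kJ/mol and is intended for dense repeated evaluation. The
standard-metadynamics PMF estimate is the γ-projection
Â(z) = −kBT ln ⟨e^(+αV/kBT)⟩_γ (α = bf/(bf−1) when well-tempered),
bulk-shifted like every other profile.

## Force-integration estimator

Weights w_i = exp(+V(x_i, t_i)/kBT) use the *instantaneous* bias and are
normalized within each 0.1 Å z-bin, which reweights the biased ensemble
back to the unbiased conditional average at fixed z and reduces exactly
to uniform weighting when no bias is present. Two comparison modes
exist: "uniform" (w ≡ 1) and "final" (weights from the frozen end-of-run
bias). With standard (non-tempered) metadynamics the uniform offset of V
grows in time, so the effective statistics concentrate on roughly the
last kBT/(growth rate) of the run (~10⁴ steps at the defaults); the
per-bin effective sample size (Kish, (Σw)²/Σw²) is reported so this is
visible. Equilibration default: discard the first 10% of each walker's
trace. Integration is trapezoidal on bin centers; interior empty-bin
runs up to 5 bins are linearly interpolated in the force, longer runs
raise a gap error naming the interval; the PMF is shifted so its mean
over [z_wall − 2, z_wall] is zero (profiles that never reached the bulk
are anchored to zero at their covered end and flagged by provenance —
they cannot be bulk-referenced honestly).

## Convergence benchmark and speed-up

One trajectory per seed serves both estimators (paired design). The
long-run kernel keeps the bias on a fine grid (Δz = 0.04 Å, 96 γ nodes)
updated incrementally at each deposition and interpolated bilinearly for
the dynamics, and accumulates the per-bin weighted force sums in-kernel,
so cost per step is independent of the hill count and no trace is
stored; bias-interpolation error (~0.02–0.05 kJ/mol) is far below the
1 kJ/mol tolerance at which the benchmark operates. Both estimators are
snapshotted at checkpoints and scored as RMSE against the analytic PMF
over the adsorption region [r_c, 6.7 Å] (6.7 Å is the bulk onset: the
PMF is flat to < 0.1 kJ/mol beyond it).

Convergence time is "first checkpoint at which RMSE ≤ tolerance and
stays ≤ tolerance for 10 consecutive checkpoints". The default
checkpoint grid is 5k-spaced below 100k steps and 20k-spaced above, so
the sustain window spans ≥ 200k steps in the regime where the standard
estimate converges. This matters: the projection estimate oscillates
slowly around ~1–3 kJ/mol RMSE with excursions on a 10⁵-step scale, and
a short sustain window registers transient dips as convergence; the
force-integration arm, once converged (~10⁴ steps at the defaults),
stays below tolerance for the rest of the run, so the fine early grid
cannot flatter it. The speed-up factor is the median over seeds of
t_standard/t_metadf; a standard arm that never sustains within the
2·10⁶-step budget contributes the censored lower bound
budget/t_metadf — censoring is reported, never silently converted to a
point value. At the defaults the standard arm is censored in every seed
examined, giving a lower bound of ~200.

No claim is made that synthetic simulation steps map to the ab initio
system's picoseconds; the benchmark is a scaled-down methodological
analogue.

## Adsorption integral and mode decomposition

The layer integral is computed by trapezoid on the PMF grid with the
window endpoints interpolated in, after verifying |bulk mean| ≤ 0.01
kJ/mol; the deepest point is factored out of the exponential so T → 0
cannot overflow. The integrand convention (1/δ normalization, bulk
reference) is fixed by two physical requirements: a flat PMF must give
ΔG = 0 and a δ-wide square well of depth W must give −W. Mode
decomposition takes the two lowest local minima (≥ 0.5 kJ/mol
prominence), the maximum between them, and scores each mode over its own
layer — the minimum ± half the distance to the barrier, clipped to the
analysis region; δ = 1.5 Å reproduces the contact-mode layer. The
composition rule ΔG_total = ΔG_M1 + ΔG_M2 + barrier height is the sign
convention consistent with the per-mode arithmetic (−27 − 8 + 5 = −30);
note the layer integral of a narrow −27 kJ/mol well is shallower than
−27 (entropy of the layer), so composed totals from synthetic PMFs sit
above the sum of well depths.

## Isotherm stage

The R_ct model is R(C) = R0 + (R∞ − R0)·KC/(1+KC): the blank R0 is fixed
from measurement (never fitted), R∞ free unless supplied, one shared K
across pooled replicates. Fitting is nonlinear least squares in
(ln K, R∞) with 8 log-spaced K starts (10²–10⁸ M⁻¹); uncertainty by
seeded residual bootstrap (2000 draws, warm-started refits) plus
Jacobian standard errors. ΔG = −R·T·ln(K·C°) with the molar standard
state C° = 1 M — the only convention under which a μM-range isotherm
with K ≈ 2.7×10⁵ M⁻¹ yields ΔG ≈ −31 kJ/mol at 298.15 K. A fitted
R∞ below the largest observed R_ct is flagged, not forbidden. The
synthetic generator draws R_ct as the Langmuir mean times (1 + σ·N(0,1))
at 12 log-spaced concentrations over 1–300 μM, two replicates, σ = 2% —
the experimental design it emulates; R0 = 200 Ω and R∞ = 1200 Ω are
representative scales chosen once (the real values live in supplementary
tables that are not machine-readable here).

## Hydration stage

Distances d are measured along +z from the topmost Ti plane (atoms
within 0.5 Å of the highest Ti), no periodic wrap in z. Density
profiles: 0.1 Å bins, absolute number density (counts / lateral area /
bin width / frames). Layer detection requires peak prominence ≥ 1× the
bulk density (estimated from the outer quarter of the profile), a
minimum 0.5 Å peak separation, and refines positions sub-bin by
parabolic interpolation. H-bond statistics pool, per frame and donor
hydrogen, the minimum H→acceptor distance under a 2.5 Å cutoff. The
generator places Gaussian layers at 2.3/3.0/5.0 Å (widths
0.15/0.20/0.30 Å, occupancies 20/16/14 per 15×15 Å² cell — first layer
~4× bulk density, third ~2.5×, mirroring the measured layering) over a
uniform bulk at 0.0334 Å⁻³, 200 frames by default.

## What the synthetic setting does and does not show

Passing tests demonstrate that the estimators are correct and efficient
*given* their modelling assumptions: a smooth two-CV landscape, ideal
Langevin kinetics, Gaussian replicate noise, Gaussian hydration layers.
They do not probe CV quality, electronic-structure accuracy, hidden slow
degrees of freedom, equivalent-circuit ambiguity in extracting R_ct, or
water orientation/dissociation — all outside scope. The deposited-text
record of the original system contains no numerical PMF curve, so the
landscape is calibrated to the three printed scalar features, not to a
curve shape.
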