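# Methods

`phasekin` quantifies how biomolecular condensates change enzymatic
reactions. A phase-separated sample is treated as two well-mixed
compartments — the dense phase (condensate interior, superscript II) and
the dilute phase (superscript I) — exchanging enzyme, substrate and
product according to partition coefficients, with Michaelis–Menten
kinetics running in each phase. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Phase composition and partitioning

The measurable quantities are the total protein concentration `c_tot`,
the dilute-phase concentration `c_dil` (e.g. from SEC of the
condensate-depleted supernatant) and the dense-phase volume fraction
`phi` (e.g. from confocal z-stacks). The mass balance

    c_tot = phi * c_dense + (1 - phi) * c_dil

is solved for the unmeasured `c_dense`, giving the enzyme partition
coefficient `K_E = c_dense / c_dil`, the recruited fraction
`phi * c_dense / c_tot`, and the dilute-phase dilution factor
`xi = 1 / (K_E * phi + 1 - phi)` (how much condensate formation depletes
the dilute phase at fixed total enzyme). For the reference lipase
condensate (`c_tot` 0.5 µM, `c_dil` 0.036 µM, `phi` 1.7e-4) this yields
`c_dense` ≈ 2.73 mM and ≈ 93 % recruitment. Note that `K_E` recomputed
from these rounded inputs is ≈ 75,800, whereas the headline value of
73,000 was evidently obtained from unrounded intermediates; the package
reports what it computes and does not force agreement. Concentrations
are µM internally (presentation helpers convert); volume fractions are
plain fractions, with "%"-suffixed input accepted by the parsers because
printed tables typically use percent.

## Initial rates and single-phase Michaelis–Menten estimation

Progress curves (signal vs time) are converted to product concentration
through a linear per-condition calibration; out-of-range samples are
flagged, never dropped. The initial rate is the OLS slope of product vs
time restricted to the low-conversion window (default: conversion
≤ 10 % of `S0`, minimum 5 points, free intercept to absorb the
instrument dead time — first reading typically 25 s after mixing).
Because substrate depletes within the window, that slope equals the
instantaneous rate at the window-midpoint substrate concentration, a few
percent below `v(S0)`; `initial_rate` therefore also records the
window-mean substrate (`substrate_effective`), and the pipeline fits
rates against it, which removes the depletion bias (noiseless
end-to-end recovery is then exact to ~1e-4 relative). An opt-in
`extend_to_min` policy takes the first five readings when the
conversion cap leaves fewer (relevant at low `S0` with a 25 s dead
time); the extension is flagged on the result.

`fit_michaelis_menten` is nonlinear least squares of
`v = v_max * S / (K_M + S)` (scipy `curve_fit`), initialized at
`v_max0 = max(v)` and `K_M0` = the interpolated half-saturation point,
bounded positive — reproducible and seed-free. Rates are fitted on
replicate means weighted by 1/SEM² when every level carries ≥ 3
replicates, else unweighted. Standard errors come from the parameter
covariance; 95 % intervals use the Student-t quantile on the residual
degrees of freedom (with 5 substrate levels and 2 parameters that is
t(3) ≈ 3.18, not 1.96 — with so few points the normal quantile
undercovers badly, ~80 % observed vs ~93 % with t). A warning is
attached when `max(S)` < fitted `K_M`: the reference design tops out at
250 µM for solubility reasons, below both systems' `K_M`, so the
constants are extrapolations with strongly correlated uncertainties.

## The two-phase rate-ratio model

The central model. With instantaneous substrate partitioning
(`K_S = [S]_II / [S]_I`) and no mass-transfer limitation, the ratio of
the heterogeneous to the homogeneous initial rate at equal total enzyme
is

    r_het/r_hom = xi*(1 - Phi_D)
                + xi*Phi_D*(kcat_II/kcat_I)*K_E*(KM_I + S) / (KM_eff_II + S)

with `KM_eff_II = KM_II / (gamma_S_II * K_S)`. The first term is the
dilute phase (same chemistry as the homogeneous reference, depleted by
`xi`); the second is the dense phase (enriched `K_E`-fold, its own
constants). The companion product-localization ratio

    dn_dense/dn_dilute = (Phi_D/(1-Phi_D))*(kcat_II/kcat_I)*K_E
                         *(KM_I + S)/(KM_eff_II + S)

is exactly the dense/dilute term ratio of the rate equation (a property
test verifies this identity on random parameter draws). `S` is the
nominal total substrate concentration: with `Phi_D` ~ 1e-4 the
dilute-phase correction is negligible and this matches how rate data
are plotted.

Closure: the default assumes instantaneous phase equilibrium, under
which the substrate activity coefficient in the dense phase is
`gamma_S_II = 1 / K_S`, so `KM_eff_II = KM_II` and the equations are
insensitive to `K_S` itself. No measured `K_S` is available for the
fluorogenic substrate, so the package default (`DEFAULT_K_S = 2`) is an
explicit, user-visible placeholder; users with independent estimates of
`gamma_S_II` and `K_S` can disable the closure and supply both.

Fitting: only `kcat_II` and `KM_eff_II` are free (everything else is
measured independently). Both are log-transformed during optimization —
they span orders of magnitude and must stay positive — and fitted by
Levenberg–Marquardt, weighted 1/SE² when replicate SEs accompany the
ratios. SEs are delta-method back-transforms of the log-scale
covariance; 95 % intervals are computed in log space with the t
quantile. Degenerate designs are flagged rather than hidden: two points
interpolate exactly ("unvalidated"), and `xi * Phi_D * K_E` ≈ 0 means
the data contain no dense-phase information ("non-identifiable").

The reference parameter set (`REFERENCE_PARAMS`: `Phi_D` 1.7e-4, `K_E`
73,000, `kcat_I` 4.3 s⁻¹, `KM_I` 713 µM, `kcat_II` 6.9 s⁻¹, `KM_eff_II`
334 µM) is exactly that — a reference parameterization of the studied
lipase system, not a fit target: the underlying replicate-level rate
data are not tabulated anywhere, so those dense-phase constants cannot
be re-derived from printed numbers. What the tests verify instead is
the inverse problem: the fitter recovers generating constants exactly
from noiseless synthetic ratios and with calibrated (≥ 90 %) CI
coverage at 5 % noise.

Transport diagnostics compare the droplet-traversal time
`tau_diff = d²/D` with the catalytic time `t_react = 1/kcat_II`.
`d²/D` (diameter, not radius) is the convention used here; for
D = 1.015 µm²/s and d = 1 µm it gives 985 ms, against
t_react = 145 ms at `kcat_II` = 6.9 s⁻¹ — same order of magnitude, so
the no-mass-transfer assumption is borderline and the fitted dense-phase
enhancement is, if anything, an underestimate. The ratio is reported
and verdict-labelled but never corrected for.

## Ratiometric pH sensing

Dual-emission pH dyes (SNARF-type; bands near 580 and 640 nm) report pH
through the intensity ratio of their two emission bands. The
calibration model is a single-site Henderson–Hasselbalch sigmoid

    R(pH) = R_acid + (R_base - R_acid) / (1 + 10^(pKa_app - pH))

chosen because it is the standard model for such dyes, strictly
monotone, and analytically invertible (the calibration equation used in
the original assay is not documented, so this is a package decision).
Ratios at or beyond the asymptotes are unresolvable — the dye's dynamic
range is finite, which in practice bites below pH 6 — and are returned
flagged, never silently clipped; in-range inversions outside the
calibrated span (default 6.0–9.0, set from the calibration buffers)
carry an out-of-range flag. Per-phase ratios are computed per replicate
and then averaged (not averaged-intensity ratios), matching how
replicate error bars are constructed; the dense-minus-dilute shift is a
difference of group means with the SEMs added in quadrature. Summaries
round to 0.1 pH, the resolution at which such shifts are reported.

## Cascade simulator (model extension)

The two-enzyme cascade module is explicitly labelled an extension: the
pH-buffering mechanism it encodes was demonstrated experimentally, but
no cascade equations accompany those experiments. The simulator
operationalizes the verbal mechanism — lipase sequestered in the more
basic dense phase, oxidase (optimum pH 6.0) almost entirely dilute — as
mass-action/MM ODEs over total species concentrations (ester CB,
alcohol CAlc, aldehyde CAld):

    dCB/dt   = -(v_lip_dense + v_lip_dil)
    dCAlc/dt = +(v_lip...) - (v_ox_dense + v_ox_dil)
    dCAld/dt = +(v_ox...)

Each phase contributes `phi_weight * kcat_eff * E_phase * S_dil /
(KM + S_dil)`; substrates re-equilibrate instantaneously between phases
(species partition coefficients default to 1 — intermediate
partitioning is unmeasured and user-overridable), the dense-phase
lipase rate law uses `KM_eff_II` on dilute-referenced substrate
(consistent with the rate-ratio closure), and each enzyme's `kcat` is
scaled by its relative pH-activity profile evaluated at its phase's pH
(dense pH defaults to solution pH + the fitted shift, default +0.5).
Oxidase cofactor/oxygen dynamics and product inhibition are out of
scope. Integration is LSODA at rtol 1e-9/atol 1e-10; total moles are
conserved by construction and verified to 1e-6 relative on every
trajectory, and a fixed-step RK4 integrator serves as an independent
oracle for the homogeneous flat-profile limit.

The demonstration parameterization (`ph_buffering_demo_conditions`)
uses the measured enzyme amounts (0.5 µM lipase, 5 nM oxidase, oxidase
partition coefficient 156) and coarse digitizations of the two
pH-activity profiles; the oxidase kinetic constants (kcat 200 s⁻¹,
K_M 50 µM) are order-of-magnitude choices — fast enough that it is not
trivially rate-limiting at its optimum while its pH attenuation still
bites at pH 7.5. Under these conditions the simulated product ordering
reproduces the experimental signature: with condensates the cascade is
faster at solution pH 6.0 than 7.5, without them the ordering reverses.
This is a qualitative ordering check; the parameterization was chosen
for mechanistic plausibility, and no quantitative trajectory comparison
is claimed.

## Synthetic data

Every pipeline input has a generator with known ground truth attached
to its output, so each analysis stage can be scored in closed loop.
Progress curves integrate single-phase MM depletion exactly via the
Lambert-W solution of the integrated rate equation (the log-space
argument avoids overflow at `S0 >> K_M`), map through the calibration
line and sample on the plate-reader grid (every 5 s from 25 s after
mixing). Noise defaults to 5 % multiplicative Gaussian — matching the
roughly proportional scatter of replicate error bars in such data, a
stand-in rather than a measured noise model — 3 % for dye-ratio data;
all draws flow from a single integer seed and identical seeds reproduce
identical bytes. What the generators do **not** emulate: instrument
drift, photobleaching, inner-filter effects, droplet coalescence or
size-dependence, pipetting covariance between replicates. Passing
recovery tests therefore show the estimators are correct for the
assumed observation model, not that real plate-reader data satisfy that
model.

## Problem sizes and defaults

Simulation studies use 200 replicate fits (5 substrate levels x 4
replicates, or 7 calibration pH levels x 3 replicates), enough to
estimate a ~90–95 % coverage proportion to a few percent while keeping
the full suite fast. Substrate grids for localization curves use 101–201
points on 0–1000 µM plus the analytic large-S limit, where the
localization minimum is attained. The pipeline's noiseless mode
(`noise_scale = 0`) is the oracle configuration used by the end-to-end
tests.

## Known limitations

- The initial-rate OLS estimator is depletion-biased toward the
  window-midpoint rate by construction; the effective-substrate
  correction removes the bias from the MM fit but individual quoted
  rates remain window averages.
- The two-phase model assumes the dilute phase behaves identically to
  the homogeneous reference (supported by high-salt and sub-saturation
  controls in the reference system, but an assumption elsewhere).
- Wald/t confidence intervals are first-order; for strongly correlated
  (`v_max`, `K_M`) pairs under extrapolation they remain approximate
  (observed coverage ~93 %, not exactly 95 %).
- The cascade module inherits every rate-ratio assumption and adds
  unmeasured oxidase constants; its outputs are labelled as model
  extension throughout.
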