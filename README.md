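# phasekin

Quantitative analysis of enzymatic reactions in phase-separated
(condensate-containing) systems.

Biomolecular condensates concentrate an enzyme thousands-fold in a tiny
dense phase (volume fraction Φ_D ~ 1e-4) while depleting the dilute
phase, and can also change the enzyme's environment — polarity,
effective pH — inside the droplets. `phasekin` is for experimentalists
and modelers who measure such systems with plate-reader kinetics and
confocal microscopy and want to turn those measurements into per-phase
kinetic constants and predictions: how much of the rate enhancement
comes from the dense phase, where the product is formed, and whether a
pH-shifted dense phase can rescue an enzyme outside its optimal pH
range.

## The model

For Michaelis–Menten reactions running simultaneously in the dilute (I)
and dense (II) phase, with enzyme partition coefficient
K_E = c_dense/c_dil, dense-phase volume fraction Φ_D, and instantaneous
substrate partitioning, the heterogeneous/homogeneous initial-rate
ratio at equal total enzyme is

    r_het/r_hom = ξ(1-Φ_D) + ξ Φ_D (k_cat^II/k_cat^I) K_E ·
                  (K_M^I + [S]) / (K_M*II/(γ_S^II·K_S) + [S]),

    ξ = 1 / (K_E·Φ_D + 1 - Φ_D)

and the dense/dilute product-formation ratio is

    dn_dense/dn_dilute = Φ_D/(1-Φ_D) · (k_cat^II/k_cat^I) · K_E ·
                         (K_M^I + [S]) / (K_M*II/(γ_S^II·K_S) + [S]).

Everything except the two dense-phase constants is measured
independently (mass balance for Φ_D/K_E, a homogeneous MM fit for
k_cat^I/K_M^I); `phasekin` fits k_cat^II and the effective dense-phase
Michaelis group from measured rate ratios, under the
instantaneous-equilibrium closure γ_S^II = 1/K_S by default.

Modules: `partitioning` (mass balance, K_E, ξ), `kinetics` (initial
rates, MM fits), `two_phase` (the rate-ratio model, product
localization, diffusion-vs-reaction diagnostics), `ph_sensing`
(ratiometric dual-emission pH calibration), `cascade` (two-compartment
two-enzyme cascade simulator, an explicitly flagged model extension),
`synthetic` (ground-truth data generators), `io`/`pipeline` (strict CSV
I/O and an end-to-end driver). See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

The scripted analyses live under `analysis/` (each is a thin driver
over the library and writes its tables to `results/`). The first one
computes the phase composition of the reference lipase condensate from
its three measured numbers:

```
$ python analysis/01_phase_composition.py
dense-phase concentration : 2.73 mM (2729 uM)
enzyme partition K_E      : 75,818 (headline value 73,000 reflects unrounded inputs)
protein in dense phase    : 92.8 %
dilute-phase dilution xi  : 0.0720
oxidase (K_p 156) dilute  : 97.4 %
```

Reading: a 0.5 µM protein solution with a dilute phase at 0.036 µM and
a dense-phase volume fraction of 0.017 % must hold ≈ 2.7 mM enzyme
inside the droplets — a partition coefficient around 7e4 — so 93 % of
all enzyme sits in 0.017 % of the volume, and the dilute phase retains
only ξ ≈ 7 % of the homogeneous enzyme concentration. A weakly
recruited client (partition coefficient 156) meanwhile stays 97 %
dilute: the basis for spatially splitting a two-enzyme cascade.

The same pattern continues through `02_enzyme_kinetics.py` (synthetic
progress curves → initial rates → MM constants for both systems),
`03_two_phase_model.py` (rate-ratio fit of the dense-phase constants;
with the reference set it prints a 2.52-fold enhancement at 250 µM
substrate, a ≥ 95 % dense-phase product share, and τ_diff = 985 ms vs
t_react = 145 ms), `04_ph_sensing.py` (calibration fit and the +0.5
dense-phase pH shift) and `05_cascade.py` (the four-condition cascade
ranking showing condensates invert the cascade's pH preference).

In code:

```python
from phasekin.two_phase import REFERENCE_PARAMS, rate_ratio, fraction_product_dense

rate_ratio(REFERENCE_PARAMS, 250.0)              # 2.52
fraction_product_dense(REFERENCE_PARAMS, 250.0)  # 0.970
```

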