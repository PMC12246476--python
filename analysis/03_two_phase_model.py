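#!/usr/bin/env python
"""Two-phase rate-ratio fit, product localization and transport check.

Generates a synthetic r_het/r_hom ratio table at the study's substrate
grid from the reference parameter set, re-fits the two dense-phase
constants (kcat_II and the effective dense-phase K_M under the
gamma*K_S = 1 closure), then evaluates what the fitted model implies:
the fraction of product formed inside the condensates across substrate
concentrations, and the diffusion-vs-reaction timescale comparison for
a 1 µm droplet (D = 1.015 µm²/s measured by FCS).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from phasekin.io import write_table
from phasekin.synthetic import NoiseModel, gen_ratio_dataset
from phasekin.two_phase import (
    REFERENCE_PARAMS,
    fit_dense_phase_constants,
    fraction_product_dense,
    rate_ratio,
    transport_diagnostics,
)

S_LEVELS = [15.6, 31.25, 62.5, 125.0, 250.0]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--noise", type=float, default=0.05)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    truth = REFERENCE_PARAMS
    ratios = gen_ratio_dataset(
        truth, S_LEVELS, n_reps=4,
        noise=NoiseModel(scale=args.noise, seed=args.seed))
    write_table(ratios, args.outdir / "rate_ratios.csv",
                meta={"seed": args.seed})

    fit = fit_dense_phase_constants(
        list(ratios[["S_uM", "ratio", "ratio_se"]].itertuples(
            index=False, name=None)),
        known=truth, kcat_II_0=3.0, KM_eff_II_0=100.0)
    print(f"rate enhancement at 250 uM : {rate_ratio(truth, 250.0):.2f}-fold")
    print(f"kcat_II   = {fit.kcat_II:.2f} +/- {fit.kcat_II_se:.2f} /s "
          f"(truth {truth.kcat_II})")
    print(f"KM_eff_II = {fit.KM_eff_II:.0f} +/- {fit.KM_eff_II_se:.0f} uM "
          f"(truth {truth.KM_eff_II:.0f})")

    S = np.linspace(0.0, 1000.0, 101)
    frac = np.asarray(fraction_product_dense(fit.params, S))
    limit = (truth.phi_D / (1 - truth.phi_D)
             * (fit.kcat_II / truth.kcat_I) * truth.K_E)
    print(f"product formed in dense phase: {100 * frac.min():.1f}-"
          f"{100 * frac.max():.1f} % on the grid; large-S floor "
          f"{100 * limit / (1 + limit):.1f} %")
    write_table(
        pd.DataFrame({"S_uM": S, "fraction_product_dense": frac}),
        args.outdir / "product_localization.csv", meta={"seed": args.seed})

    diag = transport_diagnostics(1.015, 1.0, fit.kcat_II)
    print(f"tau_diff = {1000 * diag.tau_diff:.0f} ms, "
          f"t_react = {1000 * diag.t_react:.0f} ms -> {diag.verdict}")


if __name__ == "__main__":
    main()
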