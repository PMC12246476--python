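"""Ground-truth generators for every pipeline input.

The raw observables of the analysis — plate-reader progress curves,
initial-rate ratio tables, dual-channel pH-dye measurements and phase
compositions — are generated here from known parameters, with explicit
noise models and the generating truth attached to every dataset (in
``DataFrame.attrs`` or ``ProgressCurve.ground_truth``).  Noiseless output
is exactly invertible by the corresponding analysis stage, which makes
these generators the oracles of the test suite.

Progress curves integrate single-phase Michaelis-Menten substrate
depletion in closed form via the Lambert-W solution of the integrated
rate equation:

    S(t) = K_M * W((S0/K_M) * exp((S0 - v_max*t)/K_M))

and the sampling scheme mirrors plate-reader practice: readings every
``interval`` seconds with the first taken ``dead_time`` seconds after
mixing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .kinetics import CalibrationLine, MichaelisMentenParams, ProgressCurve
from .partitioning import PhaseComposition, dense_concentration
from .ph_sensing import SnarfCalibration, snarf_forward
from .two_phase import TwoPhaseParams, rate_ratio

__all__ = [
    "NoiseModel",
    "mm_progress",
    "gen_progress_curves",
    "gen_ratio_dataset",
    "gen_snarf_dataset",
    "gen_snarf_calibration_table",
    "gen_phase_composition",
]


@dataclass(frozen=True)
class NoiseModel:
    """Reproducible measurement noise.

    ``additive_gaussian`` adds scale-unit Gaussian noise; the default
    ``multiplicative_gaussian`` multiplies by (1 + scale*N(0,1)), which
    matches the roughly proportional scatter of replicate error bars in
    plate-reader data.  Identical seeds reproduce identical draws
    bit-for-bit; ``scale=0`` is exactly noiseless.
    """

    kind: str = "multiplicative_gaussian"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.scale == 0:
            return x.copy()
        draw = rng.standard_normal(x.shape)
        if self.kind == "additive_gaussian":
            return x + self.scale * draw
        return x * (1.0 + self.scale * draw)


def mm_progress(
    mm: MichaelisMentenParams, S0: float, t: np.ndarray
) -> np.ndarray:
    """Product concentration P(t) for Michaelis-Menten substrate depletion.

    Closed form via Lambert W: S(t) = K_M * W(z) with
    z = (S0/K_M) * exp((S0 - v_max t)/K_M), P = S0 - S(t).  Exact, so it
    serves as the oracle for initial-rate extraction.
    """
    t = np.asarray(t, dtype=float)
    km, vmax = mm.K_M, mm.v_max
    # log-space argument avoids overflow for S0 >> K_M
    log_z = np.log(S0 / km) + (S0 - vmax * t) / km
    S = km * np.real(lambertw(np.exp(log_z)))
    return S0 - np.clip(S, 0.0, S0)


def gen_progress_curves(
    mm: MichaelisMentenParams,
    S_levels: Sequence[float],
    cal: CalibrationLine,
    n_reps: int = 4,
    noise: NoiseModel | None = None,
    dead_time: float = 25.0,
    interval: float = 5.0,
    n_points: int = 60,
) -> list[ProgressCurve]:
    """Generate raw-signal progress curves on the plate-reader grid.

    Times run t = dead_time + k*interval for k = 0..n_points-1
    (first reading after the mixing dead time, then evenly spaced).
    The generating parameters ride along in ``ground_truth``.
    """
    noise = noise or NoiseModel(scale=0.0)
    rng = noise.rng()
    t = dead_time + interval * np.arange(n_points)
    curves = []
    for S0 in S_levels:
        for rep in range(n_reps):
            P = mm_progress(mm, S0, t)
            sig = noise.apply(cal.intercept + cal.slope * P, rng)
            curves.append(ProgressCurve(
                times=t, signal=sig, substrate_0=S0, enzyme_0=mm.enzyme_0,
                condition_label=cal.condition_label,
                replicate_id=f"S{S0:g}_r{rep + 1}",
                units="au",
                ground_truth={
                    "v_max": mm.v_max, "K_M": mm.K_M, "enzyme_0": mm.enzyme_0,
                    "noise": noise, "dead_time": dead_time,
                    "interval": interval,
                },
            ))
    return curves


def gen_ratio_dataset(
    params: TwoPhaseParams,
    S_levels: Sequence[float],
    n_reps: int = 4,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Replicate-averaged r_het/r_hom ratio table at each substrate level.

    Columns: S_uM, ratio, ratio_se, n.  The generating parameter set is
    attached in ``attrs["ground_truth"]``.
    """
    noise = noise or NoiseModel(scale=0.0)
    rng = noise.rng()
    rows = []
    for S in S_levels:
        true = rate_ratio(params, S)
        reps = noise.apply(np.full(n_reps, true), rng)
        se = float(reps.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan
        rows.append({
            "S_uM": float(S), "ratio": float(reps.mean()),
            "ratio_se": se, "n": n_reps,
        })
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "kcat_II": params.kcat_II, "KM_eff_II": params.KM_eff_II,
        "params": params, "noise": noise,
    }
    return df


def gen_snarf_calibration_table(
    cal: SnarfCalibration,
    ph_levels: Sequence[float] | None = None,
    n_reps: int = 3,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Calibration-buffer table: columns pH, ratio, ratio_se, n.

    Default pH levels follow the standard calibration design: 6.0 to 9.0
    in 0.5-unit steps.
    """
    if ph_levels is None:
        ph_levels = np.arange(6.0, 9.0 + 1e-9, 0.5)
    noise = noise or NoiseModel(scale=0.0)
    rng = noise.rng()
    rows = []
    for p in ph_levels:
        true = snarf_forward(cal, p)
        reps = noise.apply(np.full(n_reps, true), rng)
        se = float(reps.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan
        rows.append({"pH": float(p), "ratio": float(reps.mean()),
                     "ratio_se": se, "n": n_reps})
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {"calibration": cal, "noise": noise}
    return df


def gen_snarf_dataset(
    cal: SnarfCalibration,
    ph_levels: Sequence[float],
    dense_shift: float,
    n_reps: int = 6,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Per-replicate dense/dilute ratio measurements at each solution pH.

    Dilute-phase ratios are generated at the nominal pH, dense-phase
    ratios at pH + dense_shift.  Columns: pH_nominal, phase,
    replicate_id, ratio.  Ground truth (calibration, shift) in attrs.
    """
    noise = noise or NoiseModel(scale=0.0)
    rng = noise.rng()
    rows = []
    for p in ph_levels:
        for phase, ph_true in (("dilute", p), ("dense", p + dense_shift)):
            reps = noise.apply(
                np.full(n_reps, snarf_forward(cal, ph_true)), rng
            )
            for k, r in enumerate(reps):
                rows.append({
                    "pH_nominal": float(p), "phase": phase,
                    "replicate_id": f"{phase}_pH{p:g}_r{k + 1}",
                    "ratio": float(r),
                })
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "calibration": cal, "dense_shift": dense_shift, "noise": noise,
    }
    return df


def gen_phase_composition(
    c_tot: float, K_E: float, phi: float
) -> PhaseComposition:
    """Self-consistent phase composition from (c_tot, K_E, phi).

    Solves the mass balance c_tot = phi*c_dense + (1-phi)*c_dil together
    with c_dense = K_E*c_dil, i.e. c_dil = c_tot / (K_E*phi + 1 - phi).
    """
    if c_tot <= 0 or K_E <= 0:
        raise ValueError("c_tot and K_E must be positive")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    c_dil = c_tot / (K_E * phi + 1.0 - phi)
    if phi == 0.0 or K_E == 1.0:
        return PhaseComposition(
            c_tot=c_tot, c_dil=c_dil, c_dense=K_E * c_dil, phi=phi,
        )
    return PhaseComposition.from_measurements(c_tot, c_dil, phi)
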