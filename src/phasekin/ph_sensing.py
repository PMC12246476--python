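"""Ratiometric dual-emission pH sensing (SNARF-type dyes).

A ratiometric pH dye emits at two bands (here ~580 nm and ~640 nm) whose
intensity ratio depends on the dye's protonation state.  The forward
calibration model is a single-site Henderson-Hasselbalch sigmoid in pH:

    R(pH) = R_acid + (R_base - R_acid) / (1 + 10**(pKa_app - pH))

which is strictly monotone and analytically invertible, so measured
intensity ratios map straight back to apparent pH.  Ratios outside the
open interval (R_acid, R_base) or pH values outside the calibrated range
are flagged (the dye's dynamic range is finite), never silently clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SnarfCalibration",
    "RatioMeasurement",
    "PhEstimate",
    "snarf_forward",
    "fit_snarf_calibration",
    "ratio_to_ph",
    "ph_shift",
]


@dataclass(frozen=True)
class SnarfCalibration:
    """Calibration of a dual-emission ratiometric pH dye.

    R_acid and R_base are the limiting intensity ratios at low and high
    pH; pKa_app the apparent transition midpoint.  ``valid_range`` is the
    pH span covered by the calibration buffers (default 6.0-9.0).
    """

    pKa_app: float
    R_acid: float
    R_base: float
    valid_range: tuple[float, float] = (6.0, 9.0)
    pKa_app_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.R_acid == self.R_base:
            raise ValueError("R_acid and R_base must differ")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be non-empty")


@dataclass(frozen=True)
class RatioMeasurement:
    """One dual-channel intensity measurement of the dye in one phase."""

    I_ch1: float               # 570-590 nm band
    I_ch2: float               # 630-650 nm band
    phase: Literal["dense", "dilute"] = "dilute"
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.I_ch1 <= 0 or self.I_ch2 <= 0:
            raise ValueError("intensities must be positive")

    @property
    def ratio(self) -> float:
        return self.I_ch1 / self.I_ch2


@dataclass(frozen=True)
class PhEstimate:
    """Apparent pH recovered from a ratio, with range/resolvability flags."""

    pH: float
    in_range: bool
    resolvable: bool
    flags: tuple[str, ...] = ()


def snarf_forward(cal: SnarfCalibration, pH: float | np.ndarray):
    """Forward calibration curve: intensity ratio at a given pH."""
    pH = np.asarray(pH, dtype=float)
    out = cal.R_acid + (cal.R_base - cal.R_acid) / (1.0 + 10.0 ** (cal.pKa_app - pH))
    return float(out) if out.ndim == 0 else out


def ratio_to_ph(cal: SnarfCalibration, m: RatioMeasurement | float) -> PhEstimate:
    """Invert the calibration: apparent pH from an intensity ratio.

    The analytic inverse is pH = pKa_app - log10((1-f)/f) with
    f = (R - R_acid)/(R_base - R_acid).  Ratios at or beyond the
    asymptotes are unresolvable and flagged, not raised; in-range values
    outside the calibration span carry an out-of-range flag.
    """
    R = m.ratio if isinstance(m, RatioMeasurement) else float(m)
    f = (R - cal.R_acid) / (cal.R_base - cal.R_acid)
    flags: list[str] = []
    if not 0.0 < f < 1.0:
        side = "acid" if f <= 0.0 else "base"
        return PhEstimate(
            pH=float("-inf") if side == "acid" else float("inf"),
            in_range=False, resolvable=False,
            flags=(f"ratio beyond the {side} asymptote: outside the dye's "
                   "dynamic range",),
        )
    pH = cal.pKa_app - math.log10((1.0 - f) / f)
    lo, hi = cal.valid_range
    in_range = lo <= pH <= hi
    if not in_range:
        flags.append(
            f"apparent pH {pH:.2f} outside calibrated range [{lo}, {hi}]"
        )
    return PhEstimate(pH=pH, in_range=in_range, resolvable=True,
                      flags=tuple(flags))


def fit_snarf_calibration(
    data: Sequence[tuple], valid_range: tuple[float, float] | None = None
) -> SnarfCalibration:
    """Least-squares fit of the three calibration parameters.

    Parameters
    ----------
    data:
        Sequence of ``(pH, ratio)`` or ``(pH, ratio, ratio_se)`` tuples;
        needs >= 4 distinct pH levels spanning more than 1 pH unit.
    valid_range:
        Override for the calibration validity span; defaults to the span
        of the supplied pH levels.
    """
    arr = [tuple(map(float, d)) for d in data]
    pH = np.array([d[0] for d in arr])
    R = np.array([d[1] for d in arr])
    se = np.array([d[2] if len(d) > 2 else np.nan for d in arr])
    levels = np.unique(pH)
    if levels.size < 4:
        raise ValueError(
            f"under-determined: need >= 4 distinct pH levels, got {levels.size}"
        )
    if levels.max() - levels.min() <= 1.0:
        raise ValueError("calibration pH levels must span more than 1 pH unit")

    order = np.argsort(pH)
    means = [R[pH == lv].mean() for lv in levels]
    diffs = np.diff(means)
    monotone = bool(np.all(diffs <= 0) or np.all(diffs >= 0))

    def model(x, pKa, r_acid, r_base):
        return r_acid + (r_base - r_acid) / (1.0 + 10.0 ** (pKa - x))

    p0 = [float(levels.mean()), float(R[order][0]), float(R[order][-1])]
    sigma = se if np.all(np.isfinite(se)) and np.all(se > 0) else None
    try:
        popt, pcov = optimize.curve_fit(
            model, pH, R, p0=p0, sigma=sigma, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"calibration fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    if not monotone:
        import warnings as _warnings

        _warnings.warn(
            "mean calibration ratios are not monotone in pH; fit may be "
            "unreliable", stacklevel=2,
        )
    vr = valid_range or (float(levels.min()), float(levels.max()))
    return SnarfCalibration(
        pKa_app=float(popt[0]), R_acid=float(popt[1]), R_base=float(popt[2]),
        valid_range=vr, pKa_app_se=float(perr[0]),
    )


def ph_shift(
    dense: Sequence[float], dilute: Sequence[float]
) -> tuple[float, float]:
    """Dense-minus-dilute mean apparent pH with propagated SE of the mean.

    Returns ``(shift, se)``; the SE contribution of a single-replicate
    group is zero (no within-group scatter observable).
    """
    d = np.asarray(dense, dtype=float)
    i = np.asarray(dilute, dtype=float)
    if d.size == 0 or i.size == 0:
        raise ValueError("both phases need at least one pH value")

    def sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0

    shift = float(d.mean() - i.mean())
    return shift, math.hypot(sem(d), sem(i))
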