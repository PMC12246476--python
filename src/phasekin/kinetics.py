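"""Initial-rate extraction and single-phase Michaelis-Menten estimation.

Raw kinetic data are plate-reader progress curves: signal (fluorescence or
absorbance) versus time for a fluorogenic/chromogenic substrate.  A linear
calibration converts signal to product concentration; the initial rate is
the ordinary-least-squares slope over the low-conversion window; initial
rates measured over a grid of substrate concentrations are fitted with the
Michaelis-Menten model v = v_max * S / (K_M + S).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ProgressCurve",
    "CalibrationLine",
    "MichaelisMentenParams",
    "RateMeasurement",
    "RateWindow",
    "signal_to_concentration",
    "initial_rate",
    "mm_rate",
    "fit_michaelis_menten",
    "kcat_from_vmax",
]


@dataclass(frozen=True)
class ProgressCurve:
    """One kinetic trace: signal or product concentration versus time.

    ``units`` records whether ``signal`` is a raw instrument signal
    ("au") or has been converted to product concentration ("uM").
    ``flags`` accumulates data-quality annotations (e.g. samples outside
    the calibration validity range) without dropping points.
    """

    times: np.ndarray          # seconds, strictly increasing
    signal: np.ndarray         # au or µM, matching `units`
    substrate_0: float         # µM
    enzyme_0: float            # µM
    condition_label: str = ""
    replicate_id: str = ""
    units: Literal["au", "uM"] = "au"
    flags: tuple[str, ...] = ()
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.size < 5:
            raise ValueError(f"progress curve needs >= 5 samples, got {t.size}")
        if t.size != y.size:
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.substrate_0 <= 0:
            raise ValueError("substrate_0 must be positive")
        if self.enzyme_0 < 0:
            raise ValueError("enzyme_0 must be non-negative")


@dataclass(frozen=True)
class CalibrationLine:
    """Linear product calibration: signal = slope * concentration + intercept."""

    slope: float               # signal per µM
    intercept: float           # signal
    valid_range: tuple[float, float] = (0.0, math.inf)   # µM
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("calibration valid_range must be non-empty")


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Michaelis-Menten parameters for one phase or system.

    k_cat is defined as v_max / enzyme_0 (total enzyme); all standard
    errors are 1-sigma.
    """

    v_max: float               # µM/s
    K_M: float                 # µM
    enzyme_0: float            # µM
    v_max_se: float = float("nan")
    K_M_se: float = float("nan")
    dof: int = 0               # residual degrees of freedom of the fit
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.K_M <= 0:
            raise ValueError("v_max and K_M must be positive")
        if self.enzyme_0 <= 0:
            raise ValueError("enzyme_0 must be positive")

    @property
    def k_cat(self) -> float:
        return self.v_max / self.enzyme_0

    @property
    def k_cat_se(self) -> float:
        return self.v_max_se / self.enzyme_0

    def ci95(self) -> dict[str, tuple[float, float]]:
        """Wald 95% confidence intervals.

        Student-t quantile on the fit's residual degrees of freedom (the
        residual scale is estimated from few points); normal quantile
        when dof is unknown.
        """
        q = stats.t.ppf(0.975, self.dof) if self.dof > 0 else 1.959963984540054
        return {
            "v_max": (self.v_max - q * self.v_max_se, self.v_max + q * self.v_max_se),
            "K_M": (self.K_M - q * self.K_M_se, self.K_M + q * self.K_M_se),
        }


@dataclass(frozen=True)
class RateMeasurement:
    """An initial rate at one substrate concentration."""

    substrate_0: float         # µM
    rate: float                # µM/s
    rate_se: float = float("nan")
    n_replicates: int = 1
    system: Literal["homogeneous", "heterogeneous"] = "homogeneous"
    conversion_fraction: float = float("nan")
    #: window-mean substrate S0 - mean(P): the concentration the OLS slope
    #: actually reflects under depletion; fit against this to de-bias.
    substrate_effective: float = float("nan")
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class RateWindow:
    """Policy for selecting the initial-rate window of a progress curve.

    Default: all points with product conversion <= 10% of substrate_0,
    at least ``min_points`` points.  A free intercept absorbs the
    instrument dead time (typically the first reading ~25 s after
    mixing) and any signal offset.
    """

    max_conversion: float = 0.10
    min_points: int = 5
    #: extend the window to the first `min_points` samples (flagged) when
    #: the conversion cap alone leaves too few; default is to refuse.
    extend_to_min: bool = False


def signal_to_concentration(
    curve: ProgressCurve, cal: CalibrationLine
) -> ProgressCurve:
    """Convert a raw-signal curve to product-concentration units.

    concentration(t) = (signal(t) - intercept) / slope.  Samples falling
    outside the calibration validity range (including negative
    concentrations from sub-baseline signal) are flagged, never dropped.
    """
    if curve.units == "uM":
        raise ValueError("curve is already in concentration units")
    if cal.condition_label and curve.condition_label and (
        cal.condition_label != curve.condition_label
    ):
        raise ValueError(
            f"calibration condition {cal.condition_label!r} does not match "
            f"curve condition {curve.condition_label!r}"
        )
    conc = (curve.signal - cal.intercept) / cal.slope
    flags = list(curve.flags)
    lo, hi = cal.valid_range
    n_out = int(np.sum((conc < lo) | (conc > hi)))
    if n_out:
        flags.append(f"{n_out} samples outside calibration range [{lo}, {hi}]")
    if np.any(conc < 0):
        flags.append("negative concentrations (signal below intercept)")
    return replace(curve, signal=conc, units="uM", flags=tuple(flags))


def initial_rate(
    curve: ProgressCurve, window: RateWindow | None = None
) -> RateMeasurement:
    """Initial rate as the OLS slope of product concentration versus time.

    The regression is restricted to the window's low-conversion points and
    fitted with a free intercept (dead-time tolerant).  The standard error
    comes from the regression; the conversion fraction actually used is
    recorded on the result.
    """
    if curve.units != "uM":
        raise ValueError("initial_rate requires a concentration-unit curve; "
                         "apply signal_to_concentration first")
    window = window or RateWindow()
    conv = curve.signal / curve.substrate_0
    mask = conv <= window.max_conversion
    n_in = int(mask.sum())
    flags = []
    if n_in < window.min_points:
        if not window.extend_to_min:
            raise ValueError(
                f"only {n_in} samples within the {window.max_conversion:.0%} "
                f"conversion window (need >= {window.min_points})"
            )
        mask = np.zeros_like(mask)
        mask[: window.min_points] = True
        flags.append(
            f"window extended beyond the {window.max_conversion:.0%} "
            f"conversion cap to reach {window.min_points} points"
        )
    t = curve.times[mask]
    y = curve.signal[mask]
    res = stats.linregress(t, y)
    if res.slope < 0 and res.stderr > 0 and res.slope < -2.0 * res.stderr:
        flags.append("non-monotone signal: fitted slope < 0 beyond 2 SE")
    return RateMeasurement(
        substrate_0=curve.substrate_0,
        rate=float(res.slope),
        rate_se=float(res.stderr),
        n_replicates=1,
        conversion_fraction=float(conv[mask].max()),
        substrate_effective=float(curve.substrate_0 - y.mean()),
        flags=tuple(flags),
    )


def mm_rate(params: MichaelisMentenParams, S: float | np.ndarray):
    """Michaelis-Menten rate v = v_max * S / (K_M + S), µM/s."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = params.v_max * S / (params.K_M + S)
    return float(out) if out.ndim == 0 else out


def kcat_from_vmax(v_max: float, enzyme_0: float) -> float:
    """Turnover number k_cat = v_max / [E]_0 (per second)."""
    if enzyme_0 <= 0:
        raise ValueError(f"enzyme_0 must be positive, got {enzyme_0}")
    return v_max / enzyme_0


def _km_init(S: np.ndarray, v: np.ndarray, v_max0: float) -> float:
    """K_M start value: S where the rate crosses v_max0/2, by interpolation."""
    order = np.argsort(S)
    S, v = S[order], v[order]
    half = v_max0 / 2.0
    above = np.nonzero(v >= half)[0]
    if above.size == 0:
        return float(S[-1])
    i = above[0]
    if i == 0 or v[i] == v[i - 1]:
        return float(S[i])
    f = (half - v[i - 1]) / (v[i] - v[i - 1])
    return float(S[i - 1] + f * (S[i] - S[i - 1]))


def fit_michaelis_menten(
    data: Sequence[RateMeasurement], enzyme_0: float
) -> MichaelisMentenParams:
    """Nonlinear least-squares Michaelis-Menten fit of initial rates.

    Weighted by 1/SE^2 when every point carries >= 3 replicates with a
    finite positive SE, otherwise unweighted.  Standard errors come from
    the parameter covariance.  When the design never reaches the fitted
    K_M (max S < K_M) the result carries a warning: the constants are
    then extrapolated and strongly correlated.
    """
    S = np.array([d.substrate_0 for d in data], dtype=float)
    v = np.array([d.rate for d in data], dtype=float)
    se = np.array([d.rate_se for d in data], dtype=float)
    nrep = np.array([d.n_replicates for d in data], dtype=int)
    if np.unique(S).size < 3:
        raise ValueError(
            f"need >= 3 distinct substrate concentrations, got {np.unique(S).size}"
        )

    v_max0 = float(v.max())
    km0 = max(_km_init(S, v, v_max0), 1e-6)
    use_weights = bool(np.all(nrep >= 3) and np.all(np.isfinite(se)) and np.all(se > 0))
    sigma = se if use_weights else None

    def model(s, v_max, km):
        return v_max * s / (km + s)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                model, S, v, p0=[v_max0, km0], sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge (start v_max={v_max0}, "
                f"K_M={km0}): {exc}"
            ) from exc
    perr = np.sqrt(np.diag(pcov))
    notes: list[str] = []
    if popt[1] < 1e-3 * S.min():
        notes.append("K_M at lower boundary: rates are saturated at all S")
    if S.max() < popt[1]:
        notes.append(
            "max(S) < fitted K_M: constants extrapolated beyond the measured range"
        )
    km_fit = max(float(popt[1]), 1e-12)
    return MichaelisMentenParams(
        v_max=float(popt[0]), K_M=km_fit, enzyme_0=enzyme_0,
        v_max_se=float(perr[0]), K_M_se=float(perr[1]),
        dof=max(len(S) - 2, 0), warnings=tuple(notes),
    )
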