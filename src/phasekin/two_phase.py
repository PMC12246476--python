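"""Two-phase Michaelis-Menten rate-ratio model and derived diagnostics.

The central model of the package.  For an enzymatic reaction running
simultaneously in the dilute (I) and dense (II) phase of a
condensate-containing sample, with instantaneous substrate partitioning
and no mass-transfer limitation, the ratio of the initial rate of the
heterogeneous system to that of a homogeneous system at the same total
enzyme concentration is

    r_het / r_hom = xi*(1 - Phi_D)
                  + xi*Phi_D*(kcat_II/kcat_I)*K_E
                    * (KM_I + S) / (KM_II/(gamma_S_II*K_S) + S)

where Phi_D is the dense-phase volume fraction, K_E and K_S the enzyme
and substrate partition coefficients, gamma_S_II the substrate activity
coefficient in the dense phase, KM_I / KM_II the apparent Michaelis
constants, and xi = 1/(K_E*Phi_D + 1 - Phi_D) the dilute-phase enzyme
dilution factor.  Under the instantaneous-phase-equilibrium closure
gamma_S_II = 1/K_S, so the fitted group KM_II/(gamma_S_II*K_S) equals the
dense-phase apparent constant itself.

The companion product-localization ratio (moles formed in dense vs
dilute phase) is

    dn_dense/dn_dilute = (Phi_D/(1-Phi_D))*(kcat_II/kcat_I)*K_E
                         * (KM_I + S) / (KM_II/(gamma_S_II*K_S) + S).

Only the two dense-phase constants are free when fitting measured rate
ratios; everything else is measured independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import t as t_dist

from .kinetics import MichaelisMentenParams, mm_rate
from .partitioning import xi as _xi

__all__ = [
    "DEFAULT_K_S",
    "TwoPhaseParams",
    "TwoPhaseFitResult",
    "TransportDiagnostics",
    "REFERENCE_PARAMS",
    "rate_ratio",
    "fit_dense_phase_constants",
    "product_partition_ratio",
    "fraction_product_dense",
    "heterogeneous_rate",
    "transport_diagnostics",
]

# Substrate partition coefficient default.  No measured value for the
# fluorogenic butyrate substrate is available in the package's reference
# parameterization; under the equilibrium closure gamma_S_II*K_S = 1 the
# rate-ratio and product-localization equations are insensitive to it.
DEFAULT_K_S: float = 2.0


@dataclass(frozen=True)
class TwoPhaseParams:
    """Full parameter set of the two-phase rate-ratio model.

    ``use_equilibrium_closure`` asserts gamma_S_II = 1/K_S; the
    constructor enforces the product gamma_S_II*K_S = 1 in that case.
    ``KM_II`` is the dense-phase apparent Michaelis constant; the group
    actually entering the equations is ``KM_eff_II`` =
    KM_II/(gamma_S_II*K_S).
    """

    phi_D: float               # dense-phase volume fraction
    K_E: float                 # enzyme partition coefficient
    kcat_I: float              # /s, dilute phase
    KM_I: float                # µM, apparent, dilute phase
    kcat_II: float             # /s, dense phase
    KM_II: float               # µM, apparent, dense phase
    K_S: float = DEFAULT_K_S   # substrate partition coefficient
    gamma_S_II: float = None   # type: ignore[assignment]
    use_equilibrium_closure: bool = True

    def __post_init__(self) -> None:
        if self.gamma_S_II is None:
            if not self.use_equilibrium_closure:
                raise ValueError(
                    "gamma_S_II must be supplied when the equilibrium closure "
                    "is disabled"
                )
            object.__setattr__(self, "gamma_S_II", 1.0 / self.K_S)
        if self.use_equilibrium_closure and not math.isclose(
            self.gamma_S_II * self.K_S, 1.0, rel_tol=1e-12
        ):
            raise ValueError(
                "equilibrium closure requires gamma_S_II * K_S = 1, got "
                f"{self.gamma_S_II * self.K_S}"
            )
        for name in ("K_E", "kcat_I", "KM_I", "kcat_II", "KM_II", "K_S",
                     "gamma_S_II"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.phi_D < 1.0:
            raise ValueError(f"phi_D must be in [0, 1), got {self.phi_D}")

    @property
    def KM_eff_II(self) -> float:
        """Effective dense-phase Michaelis group KM_II/(gamma_S_II*K_S), µM."""
        return self.KM_II / (self.gamma_S_II * self.K_S)

    @property
    def xi(self) -> float:
        return _xi(self.K_E, self.phi_D)


#: Reference parameter set for the lipase condensate system: measured
#: composition (phi_D, K_E), homogeneous constants (kcat_I, KM_I) and the
#: dense-phase constants inferred from measured rate ratios under the
#: equilibrium closure.
REFERENCE_PARAMS = TwoPhaseParams(
    phi_D=1.7e-4, K_E=73_000.0, kcat_I=4.3, KM_I=713.0,
    kcat_II=6.9, KM_II=334.0,
)


def rate_ratio(params: TwoPhaseParams, S: float | np.ndarray):
    """Heterogeneous/homogeneous initial-rate ratio r_het/r_hom at S (µM)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    x = params.xi
    dilute = x * (1.0 - params.phi_D)
    dense = (
        x * params.phi_D * (params.kcat_II / params.kcat_I) * params.K_E
        * (params.KM_I + S) / (params.KM_eff_II + S)
    )
    out = dilute + dense
    return float(out) if out.ndim == 0 else out


def product_partition_ratio(params: TwoPhaseParams, S: float | np.ndarray):
    """Moles of product formed in dense vs dilute phase, dn_dense/dn_dilute."""
    if params.phi_D >= 1.0:
        raise ValueError("phi_D must be < 1")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = (
        params.phi_D / (1.0 - params.phi_D)
        * (params.kcat_II / params.kcat_I) * params.K_E
        * (params.KM_I + S) / (params.KM_eff_II + S)
    )
    return float(out) if out.ndim == 0 else out


def fraction_product_dense(params: TwoPhaseParams, S: float | np.ndarray):
    """Fraction of product formed inside the condensates, ratio/(1+ratio)."""
    r = np.asarray(product_partition_ratio(params, S), dtype=float)
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def heterogeneous_rate(
    params: TwoPhaseParams,
    S: float | np.ndarray,
    homogeneous: MichaelisMentenParams,
):
    """Reconstruct the heterogeneous rate r_het = rate_ratio * r_hom (µM/s).

    The homogeneous parameters must agree with the dilute-phase constants
    in ``params`` (the model assumes the dilute phase behaves like the
    homogeneous system).
    """
    if not math.isclose(homogeneous.k_cat, params.kcat_I, rel_tol=1e-6):
        raise ValueError(
            f"inconsistent kcat_I: {params.kcat_I} vs homogeneous "
            f"{homogeneous.k_cat}"
        )
    if not math.isclose(homogeneous.K_M, params.KM_I, rel_tol=1e-6):
        raise ValueError(
            f"inconsistent KM_I: {params.KM_I} vs homogeneous {homogeneous.K_M}"
        )
    return rate_ratio(params, S) * mm_rate(homogeneous, S)


@dataclass(frozen=True)
class TwoPhaseFitResult:
    """Result of fitting the two dense-phase constants to rate ratios.

    Standard errors are quoted on the natural scale (delta method from
    the log-scale covariance used during optimization); ``ci95`` uses the
    log-scale intervals, which respect positivity.
    """

    kcat_II: float
    KM_eff_II: float
    kcat_II_se: float
    KM_eff_II_se: float
    log_kcat_II_se: float
    log_KM_eff_II_se: float
    residuals: np.ndarray
    params: TwoPhaseParams
    n_points: int
    flags: tuple[str, ...] = ()

    def ci95(self) -> dict[str, tuple[float, float]]:
        """Log-scale Wald 95% intervals (t quantile on the residual dof)."""
        dof = self.n_points - 2
        q = t_dist.ppf(0.975, dof) if dof > 0 else 1.959963984540054
        return {
            "kcat_II": (
                self.kcat_II * math.exp(-q * self.log_kcat_II_se),
                self.kcat_II * math.exp(q * self.log_kcat_II_se),
            ),
            "KM_eff_II": (
                self.KM_eff_II * math.exp(-q * self.log_KM_eff_II_se),
                self.KM_eff_II * math.exp(q * self.log_KM_eff_II_se),
            ),
        }


def fit_dense_phase_constants(
    ratios: Sequence[tuple],
    known: TwoPhaseParams,
    kcat_II_0: float | None = None,
    KM_eff_II_0: float | None = None,
) -> TwoPhaseFitResult:
    """Fit (kcat_II, KM_eff_II) to measured r_het/r_hom ratios.

    Parameters
    ----------
    ratios:
        Sequence of ``(S_uM, ratio)`` or ``(S_uM, ratio, ratio_se)``
        tuples.  Weighted 1/SE^2 when all SEs are finite and positive,
        else unweighted.
    known:
        Parameter set supplying the fixed quantities (phi_D, K_E, K_S,
        kcat_I, KM_I, closure flag); its dense-phase entries serve as
        start values unless overridden.

    Both free parameters are log-transformed during optimization to
    enforce positivity across their orders of magnitude.
    """
    arr = [tuple(map(float, r)) for r in ratios]
    S = np.array([r[0] for r in arr])
    y = np.array([r[1] for r in arr])
    se = np.array([r[2] if len(r) > 2 else np.nan for r in arr])
    if np.unique(S).size < 2:
        raise ValueError("need >= 2 distinct substrate concentrations")

    flags: list[str] = []
    if np.unique(S).size == 2 and len(arr) == 2:
        flags.append("exact interpolation through 2 points: fit unvalidated")
    # Sensitivity of the ratio to the dense phase scales with xi*phi_D*K_E.
    if known.xi * known.phi_D * known.K_E < 1e-6:
        flags.append(
            "non-identifiable: dense-phase contribution xi*phi_D*K_E ~ 0"
        )

    use_w = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    w = 1.0 / se if use_w else np.ones_like(y)

    def with_free(theta: np.ndarray) -> TwoPhaseParams:
        kcat_II = math.exp(theta[0])
        km_eff = math.exp(theta[1])
        # KM_II is stored so that KM_eff_II equals the fitted group.
        return replace(
            known, kcat_II=kcat_II,
            KM_II=km_eff * known.gamma_S_II * known.K_S,
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        return w * (rate_ratio(with_free(theta), S) - y)

    theta0 = np.log([
        kcat_II_0 if kcat_II_0 is not None else known.kcat_II,
        KM_eff_II_0 if KM_eff_II_0 is not None else known.KM_eff_II,
    ])
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(
            f"two-phase fit did not converge: {sol.message}; last iterate "
            f"(kcat_II, KM_eff_II) = {tuple(np.exp(sol.x))}"
        )
    dof = max(len(y) - 2, 0)
    if dof > 0:
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            log_se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            log_se = np.full(2, np.nan)
            flags.append("singular Jacobian: standard errors unavailable")
    else:
        log_se = np.full(2, np.nan)
    kcat_II, km_eff = np.exp(sol.x)
    fitted = with_free(sol.x)
    return TwoPhaseFitResult(
        kcat_II=float(kcat_II),
        KM_eff_II=float(km_eff),
        kcat_II_se=float(kcat_II * log_se[0]),
        KM_eff_II_se=float(km_eff * log_se[1]),
        log_kcat_II_se=float(log_se[0]),
        log_KM_eff_II_se=float(log_se[1]),
        residuals=rate_ratio(fitted, S) - y,
        params=fitted,
        n_points=len(y),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class TransportDiagnostics:
    """Reaction vs diffusion timescales inside a droplet.

    tau_diff = diameter^2 / D is the characteristic time for a small
    molecule to traverse a condensate; t_react = 1/kcat_II the
    characteristic catalytic time.  Their ratio (a Damkoehler-like
    number) diagnoses, but never corrects for, mass-transfer limitation.
    """

    D: float                   # µm²/s
    droplet_diameter: float    # µm
    tau_diff: float            # s
    t_react: float             # s
    damkohler_like_ratio: float
    verdict: str


def transport_diagnostics(
    D: float, diameter: float, kcat_II: float
) -> TransportDiagnostics:
    """Compute droplet transport diagnostics from D, diameter and kcat_II."""
    if D <= 0 or diameter <= 0 or kcat_II <= 0:
        raise ValueError("D, diameter and kcat_II must all be positive")
    tau_diff = diameter**2 / D
    t_react = 1.0 / kcat_II
    ratio = tau_diff / t_react
    if 0.1 <= ratio <= 10.0:
        verdict = "same order of magnitude"
    elif ratio > 10.0:
        verdict = "diffusion much slower than reaction"
    else:
        verdict = "diffusion much faster than reaction"
    return TransportDiagnostics(
        D=D, droplet_diameter=diameter, tau_diff=tau_diff,
        t_react=t_react, damkohler_like_ratio=ratio, verdict=verdict,
    )
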