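"""Phase-composition mass balance and partition coefficients.

A phase-separated sample is described by the total protein concentration
``c_tot``, the dilute-phase concentration ``c_dil``, the dense-phase
concentration ``c_dense`` and the dense-phase volume fraction ``phi``.
These are linked by the mass balance

    c_tot = phi * c_dense + (1 - phi) * c_dil,

equivalently phi = (c_tot - c_dil) / (c_dense - c_dil).  The enzyme
partition coefficient is K_E = c_dense / c_dil, and the dilute-phase
dilution factor

    xi = 1 / (K_E * phi + 1 - phi)

is the factor by which condensate formation depletes the dilute-phase
enzyme concentration at fixed total enzyme.

Concentrations are in µM throughout; volume fractions are plain fractions
(0.00017, never the percent form 0.017%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhaseComposition",
    "ClientPartition",
    "dense_concentration",
    "volume_fraction",
    "partition_coefficient",
    "fraction_in_dense",
    "xi",
    "client_fraction_dilute",
    "uM_to_mM",
    "mM_to_uM",
]

_REL_TOL = 1e-9


def uM_to_mM(c_uM: float) -> float:
    """Presentation helper: µM -> mM."""
    return c_uM / 1000.0


def mM_to_uM(c_mM: float) -> float:
    """Presentation helper: mM -> µM."""
    return c_mM * 1000.0


def dense_concentration(c_tot: float, c_dil: float, phi: float) -> float:
    """Solve the mass balance for the dense-phase concentration (µM).

    c_dense = c_dil + (c_tot - c_dil) / phi

    Parameters
    ----------
    c_tot, c_dil:
        Total and dilute-phase concentrations, µM.
    phi:
        Dense-phase volume fraction, in (0, 1).
    """
    if not 0.0 < phi < 1.0:
        raise ValueError(f"volume fraction must satisfy 0 < phi < 1, got {phi}")
    if c_dil >= c_tot:
        raise ValueError(
            f"no dense-phase enrichment: c_dil ({c_dil}) >= c_tot ({c_tot})"
        )
    return c_dil + (c_tot - c_dil) / phi


def volume_fraction(c_tot: float, c_dil: float, c_dense: float) -> float:
    """Dense-phase volume fraction from the mass balance.

    phi = (c_tot - c_dil) / (c_dense - c_dil), requiring
    c_dil < c_tot < c_dense (allowing the degenerate equalities which map
    to phi = 0 and phi = 1).
    """
    if c_dil > c_tot:
        raise ValueError(f"ordering violated: c_dil ({c_dil}) > c_tot ({c_tot})")
    if c_tot > c_dense:
        raise ValueError(f"ordering violated: c_tot ({c_tot}) > c_dense ({c_dense})")
    if c_dense == c_dil:
        raise ValueError("degenerate composition: c_dense == c_dil")
    return (c_tot - c_dil) / (c_dense - c_dil)


def partition_coefficient(c_dense: float, c_dil: float) -> float:
    """Partition coefficient K = c_dense / c_dil."""
    if c_dense <= 0:
        raise ValueError(f"c_dense must be positive, got {c_dense}")
    if c_dil <= 0:
        raise ValueError(
            f"unbounded partitioning: c_dil must be positive, got {c_dil}"
        )
    return c_dense / c_dil


def xi(K_E: float, phi: float) -> float:
    """Dilute-phase enzyme dilution factor xi = 1 / (K_E*phi + 1 - phi).

    The ratio of the dilute-phase enzyme concentration in the
    phase-separated system to the concentration of the homogeneous system
    at the same total enzyme.  xi in (0, 1] whenever K_E >= 1.
    """
    if K_E < 0:
        raise ValueError(f"K_E must be non-negative, got {K_E}")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"volume fraction must satisfy 0 <= phi < 1, got {phi}")
    return 1.0 / (K_E * phi + 1.0 - phi)


def client_fraction_dilute(K_p: float, phi: float) -> float:
    """Fraction of a client species residing in the dilute phase.

    (1 - phi) / ((1 - phi) + K_p * phi) for a client with partition
    coefficient K_p.  For a weakly partitioned client in a sample with a
    tiny dense-phase volume fraction this stays near 1 even when K_p is
    in the hundreds.
    """
    if K_p <= 0:
        raise ValueError(f"K_p must be positive, got {K_p}")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"volume fraction must satisfy 0 <= phi < 1, got {phi}")
    return (1.0 - phi) / ((1.0 - phi) + K_p * phi)


@dataclass(frozen=True)
class PhaseComposition:
    """Self-consistent two-phase composition with derived partition quantities.

    Attributes
    ----------
    c_tot, c_dil, c_dense:
        Concentrations in µM.
    phi:
        Dense-phase volume fraction (fraction, not percent).
    K_E:
        Enzyme partition coefficient c_dense / c_dil.
    fraction_dense:
        Fraction of total protein residing in the dense phase,
        phi * c_dense / c_tot.
    """

    c_tot: float
    c_dil: float
    c_dense: float
    phi: float
    K_E: float = field(default=None)  # type: ignore[assignment]
    fraction_dense: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must be in [0, 1), got {self.phi}")
        if not self.c_dil <= self.c_tot <= self.c_dense:
            raise ValueError(
                "ordering violated: require c_dil <= c_tot <= c_dense, got "
                f"({self.c_dil}, {self.c_tot}, {self.c_dense})"
            )
        recon = self.phi * self.c_dense + (1.0 - self.phi) * self.c_dil
        if not math.isclose(recon, self.c_tot, rel_tol=_REL_TOL):
            raise ValueError(
                f"mass balance violated: phi*c_dense + (1-phi)*c_dil = {recon} "
                f"!= c_tot = {self.c_tot}"
            )
        if self.K_E is None:
            object.__setattr__(self, "K_E", self.c_dense / self.c_dil)
        if self.fraction_dense is None:
            object.__setattr__(
                self, "fraction_dense", self.phi * self.c_dense / self.c_tot
            )

    @classmethod
    def from_measurements(
        cls, c_tot: float, c_dil: float, phi: float
    ) -> "PhaseComposition":
        """Build from the measured triple (c_tot, c_dil, phi)."""
        c_dense = dense_concentration(c_tot, c_dil, phi)
        return cls(c_tot=c_tot, c_dil=c_dil, c_dense=c_dense, phi=phi)

    @property
    def xi(self) -> float:
        return xi(self.K_E, self.phi)


@dataclass(frozen=True)
class ClientPartition:
    """A client species partitioned between the phases of a host condensate."""

    K_p: float
    phi: float
    fraction_dilute: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.K_p <= 0:
            raise ValueError(f"K_p must be positive, got {self.K_p}")
        if self.fraction_dilute is None:
            object.__setattr__(
                self, "fraction_dilute", client_fraction_dilute(self.K_p, self.phi)
            )


def fraction_in_dense(comp: PhaseComposition) -> float:
    """Fraction of total protein recruited into the dense phase."""
    return comp.phi * comp.c_dense / comp.c_tot
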