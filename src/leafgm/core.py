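"""Point equations for combined gas exchange + chlorophyll fluorescence.

Implements the fluorescence-derived electron transport rate, the Arrhenius
temperature scaling of Rubisco kinetic parameters, the day-respiration
convention, the variable-J inversion for mesophyll conductance, the
stomatal CO2/H2O conductance conversion and intrinsic water-use efficiency.

All functions accept scalars or numpy arrays and raise :class:`DomainError`
when a hard precondition is violated.  The variable-J inversion never raises
on the physically informative failure modes (electron-transport
inconsistency, negative CO2 drawdown): those records are *flagged* with a
reason code so downstream stages can report rather than silently drop them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

#: Molar gas constant, J K^-1 mol^-1.
R_GAS = 8.314

#: H2O:CO2 diffusivity ratio through stomata (gs -> gsc conversion).
H2O_CO2_DIFFUSIVITY = 1.6


class DomainError(ValueError):
    """An input violated a physical precondition."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One instrument reading of simultaneous gas exchange and fluorescence.

    Units: An umol CO2 m-2 s-1; gs mol H2O m-2 s-1; Ci, Ca umol/mol;
    Tleaf K; PPFD umol m-2 s-1; Fs, Fm_prime arbitrary fluorescence units.
    """

    An: float
    gs: float
    Ci: float
    Ca: float
    Tleaf: float
    PPFD: float
    Fs: float
    Fm_prime: float
    RH: Optional[float] = None
    plant_id: Optional[str] = None
    treatment: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gs <= 0:
            raise DomainError(f"gs must be positive, got {self.gs}")
        if self.Ci < 0:
            raise DomainError(f"Ci must be non-negative, got {self.Ci}")
        if self.Tleaf <= 0:
            raise DomainError(f"Tleaf must be positive Kelvin, got {self.Tleaf}")
        if self.PPFD < 0:
            raise DomainError(f"PPFD must be non-negative, got {self.PPFD}")
        if not (self.Fm_prime >= self.Fs >= 0):
            raise DomainError(
                f"need Fm' >= Fs >= 0, got Fs={self.Fs}, Fm'={self.Fm_prime}"
            )


@dataclass(frozen=True)
class FluorescenceDerived:
    """PSII photochemical efficiency and the electron transport rate."""

    phi_psii: float
    Jf: float
    alpha: float = 0.84
    beta: float = 0.5


@dataclass(frozen=True)
class RespirationParams:
    """Dark respiration and the derived day (light) respiration.

    The day respiration Rd is taken as half the measured dark respiration.
    """

    Rdark: float

    def __post_init__(self) -> None:
        if self.Rdark < 0:
            raise DomainError(f"Rdark must be non-negative, got {self.Rdark}")

    @property
    def Rd(self) -> float:
        return self.Rdark / 2.0


class GmEstimate(NamedTuple):
    """Result of the variable-J inversion for one record."""

    gm: float
    Cc: float
    valid: bool
    reason: Optional[str]


@dataclass(frozen=True)
class ConductanceSet:
    """Conductance chain and water-use efficiency for one observation.

    gsc = gs/1.6 converts the stomatal conductance to a CO2 basis; gt is the
    series (harmonic) combination of gsc and the mesophyll conductance gm.
    """

    gs: float
    gsc: float
    gm: float
    gt: float
    WUEi: float
    Cc: Optional[float] = None
    valid: bool = True


def arrhenius_parameter(c, Ha, Tleaf):
    """Temperature-scaled kinetic parameter ``exp(c - Ha/(R*T))``.

    Parameters
    ----------
    c : float or array
        Dimensionless scaling constant.
    Ha : float or array
        Activation energy in kJ/mol (converted to J/mol internally to match
        R in J K-1 mol-1).
    Tleaf : float or array
        Leaf temperature in Kelvin; must be positive.
    """
    Tleaf = np.asarray(Tleaf, dtype=float)
    Ha = np.asarray(Ha, dtype=float)
    if np.any(Tleaf <= 0):
        raise DomainError("Tleaf must be positive Kelvin")
    if np.any(Ha < 0):
        raise DomainError("activation energy must be non-negative")
    out = np.exp(np.asarray(c, dtype=float) - Ha * 1e3 / (R_GAS * Tleaf))
    return out.item() if out.ndim == 0 else out


def phi_psii(Fs, Fm_prime):
    """Actual PSII photochemical efficiency (Fm' - Fs)/Fm' in [0, 1]."""
    Fs = np.asarray(Fs, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise DomainError("Fm' must be positive")
    if np.any(Fs < 0) or np.any(Fs > Fm_prime):
        raise DomainError("need 0 <= Fs <= Fm' (instrument artifact otherwise)")
    out = (Fm_prime - Fs) / Fm_prime
    return out.item() if out.ndim == 0 else out


def electron_transport_rate(phi, PPFD, alpha: float = 0.84, beta: float = 0.5):
    """Fluorescence-based electron transport rate Jf = phi * PPFD * alpha * beta.

    alpha is the leaf absorptance and beta the fraction of absorbed quanta
    partitioned to PSII; the defaults (0.84, 0.5) are the standard broadleaf
    assumptions.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise DomainError("phi_psii must lie in [0, 1]")
    if np.any(np.asarray(PPFD, dtype=float) < 0):
        raise DomainError("PPFD must be non-negative")
    if alpha < 0 or beta < 0:
        raise DomainError("alpha and beta must be non-negative")
    out = phi * np.asarray(PPFD, dtype=float) * alpha * beta
    return out.item() if np.ndim(out) == 0 else out


def rd_from_dark(Rdark):
    """Day respiration as half the measured dark respiration."""
    Rdark = np.asarray(Rdark, dtype=float)
    if np.any(Rdark < 0):
        raise DomainError("Rdark must be non-negative")
    out = Rdark / 2.0
    return out.item() if out.ndim == 0 else out


# Flag reason codes for the variable-J inversion.
REASON_ETR = "electron-transport inconsistency"
REASON_DRAWDOWN = "negative drawdown"
REASON_GROSS = "non-positive gross assimilation"


def gm_variable_j(An, Ci, gamma_star, Rd, Jf) -> GmEstimate:
    """Mesophyll conductance by the variable-J inversion.

    Equates the fluorescence-based electron transport rate with the rate
    implied by gas exchange to back out the chloroplastic CO2 mole fraction

        Cc = gamma_star * (Jf + 8*(An + Rd)) / (Jf - 4*(An + Rd))

    and then gm = An / (Ci - Cc).

    Failure modes are flagged, not raised: ``Jf <= 4*(An+Rd)`` means the
    fluorescence signal cannot support the observed assimilation (Cc
    diverges), and ``Ci <= Cc`` means a negative CO2 drawdown; both yield
    ``valid=False`` with the reason recorded, mirroring how perturbed inputs
    destabilise the method.
    """
    S = An + Rd  # gross assimilation
    if S <= 0:
        return GmEstimate(np.nan, np.nan, False, REASON_GROSS)
    denom = Jf - 4.0 * S
    if denom <= 0:
        return GmEstimate(np.nan, np.nan, False, REASON_ETR)
    Cc = gamma_star * (Jf + 8.0 * S) / denom
    if Ci <= Cc:
        return GmEstimate(np.nan, Cc, False, REASON_DRAWDOWN)
    return GmEstimate(An / (Ci - Cc), Cc, True, None)


def conductance_summary(record: GasExchangeRecord, gm: float,
                        Cc: Optional[float] = None) -> ConductanceSet:
    """Stomatal/mesophyll/total conductances and WUEi for one record.

    gsc = gs/1.6, 1/gt = 1/gsc + 1/gm, WUEi = An/gs.  ``gm=inf`` is allowed
    (gt collapses to gsc).
    """
    if record.gs <= 0 or gm <= 0:
        raise DomainError("conductances must be positive")
    gsc = record.gs / H2O_CO2_DIFFUSIVITY
    gt = 1.0 / (1.0 / gsc + 1.0 / gm)
    return ConductanceSet(
        gs=record.gs,
        gsc=gsc,
        gm=gm,
        gt=gt,
        WUEi=record.An / record.gs,
        Cc=Cc,
    )


def total_conductance(gsc, gm):
    """Series combination 1/gt = 1/gsc + 1/gm (vectorised)."""
    gsc = np.asarray(gsc, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if np.any(gsc <= 0) or np.any(gm <= 0):
        raise DomainError("conductances must be positive")
    out = 1.0 / (1.0 / gsc + 1.0 / gm)
    return out.item() if out.ndim == 0 else out


def fluorescence_summary(record: GasExchangeRecord, alpha: float = 0.84,
                         beta: float = 0.5) -> FluorescenceDerived:
    """Phi_PSII and Jf for one gas-exchange record."""
    phi = phi_psii(record.Fs, record.Fm_prime)
    return FluorescenceDerived(
        phi_psii=phi,
        Jf=electron_transport_rate(phi, record.PPFD, alpha, beta),
        alpha=alpha,
        beta=beta,
    )
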