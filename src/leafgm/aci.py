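"""FvCB photosynthesis model, A/Ci curve simulation and Vcmax fitting.

The Farquhar–von Caemmerer–Berry (FvCB) model describes C3 net assimilation
as the minimum of a Rubisco-limited rate

    Ac = Vcmax * (Cc - gamma_star) / (Cc + Kc*(1 + O/Ko)) - Rd

and an RuBP-regeneration (electron-transport) limited rate

    Aj = J * (Cc - gamma_star) / (4*Cc + 8*gamma_star) - Rd

evaluated at the chloroplastic CO2 mole fraction Cc.  The curve simulator
solves the supply/demand balance An = gsc*(Ca - Ci) = gm*(Ci - Cc) = FvCB(Cc)
for each sample-CO2 setpoint; the solution is unique because the diffusive
supply is strictly decreasing and the biochemical demand non-decreasing in
Cc.  ``fit_vcmax`` implements the classic A/Ci fitting of the
Rubisco-limited segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .core import H2O_CO2_DIFFUSIVITY, DomainError

#: The measurement protocol's sample-CO2 setpoints, umol/mol.  The repeated
#: 400 setpoints after the low-CO2 descent serve as a recovery/stability check.
DEFAULT_CA_PROTOCOL = (400, 300, 200, 150, 100, 50, 400, 400,
                       600, 800, 1000, 1200, 1400, 1600)

RUBISCO = "rubisco"
RUBP = "rubp"


@dataclass(frozen=True)
class FvCBParams:
    """FvCB model parameters at the measurement leaf temperature.

    Units: Vcmax, Jmax, Rd in umol m-2 s-1; gamma_star, Kc in umol/mol;
    Ko, O in mmol/mol.  Jmax is the light-saturated electron transport
    capacity used by the curve generator.
    """

    Vcmax: float
    Rd: float
    gamma_star: float
    Kc: float
    Ko: float
    O: float = 210.0
    Jmax: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Vcmax", "Rd", "gamma_star", "Kc", "Ko", "O"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.Jmax < 0:
            raise DomainError("Jmax must be non-negative")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), umol/mol."""
        return self.Kc * (1.0 + self.O / self.Ko)


class FitError(RuntimeError):
    """A/Ci fitting failed (too few points or no convergence)."""


def fvcb_assimilation(params: FvCBParams, Cc, J):
    """Net assimilation min(Ac, Aj) - structure at chloroplastic CO2 ``Cc``.

    Returns ``(An, label)`` where label is ``"rubisco"`` or ``"rubp"``
    according to the active limitation (ties go to Rubisco).  Vectorised
    over ``Cc``.
    """
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc <= 0):
        raise DomainError("Cc must be positive")
    drawup = Cc - params.gamma_star
    Ac = params.Vcmax * drawup / (Cc + params.Km) - params.Rd
    Aj = np.asarray(J, dtype=float) * drawup / (4.0 * Cc + 8.0 * params.gamma_star) - params.Rd
    An = np.minimum(Ac, Aj)
    label = np.where(Ac <= Aj, RUBISCO, RUBP)
    if An.ndim == 0:
        return An.item(), label.item()
    return An, label


def dA_dCc(params: FvCBParams, Cc):
    """Sensitivity of Rubisco-limited assimilation to chloroplastic CO2.

    dA/dCc = Vcmax * (gamma_star + Km) / (Cc + Km)^2   [mol m-2 s-1 per
    mol/mol, i.e. the same flux units as An per unit mole fraction].
    Strictly decreasing in Cc and -> 0 as Cc -> inf.
    """
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc <= 0):
        raise DomainError("Cc must be positive")
    out = params.Vcmax * (params.gamma_star + params.Km) / (Cc + params.Km) ** 2
    return out.item() if out.ndim == 0 else out


def _solve_setpoint(params: FvCBParams, gt: float, Ca: float, J: float):
    """Root of supply gt*(Ca - Cc) minus demand FvCB(Cc); returns (An, Cc)."""

    def f(Cc: float) -> float:
        an, _ = fvcb_assimilation(params, Cc, J)
        return gt * (Ca - Cc) - an

    lo = 1e-9
    hi = max(Ca, params.gamma_star) + (params.Rd + 5.0) / gt + 100.0
    flo, fhi = f(lo), f(hi)
    for _ in range(60):
        if fhi < 0:
            break
        hi *= 2.0
        fhi = f(hi)
    if flo < 0 or fhi > 0:
        raise RuntimeError(
            f"supply/demand balance not bracketed at Ca={Ca} "
            f"(f({lo})={flo:.3g}, f({hi})={fhi:.3g})"
        )
    Cc = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    an, _ = fvcb_assimilation(params, Cc, J)
    return an, Cc


def simulate_aci_curve(
    params: FvCBParams,
    gm: float,
    gs: float,
    protocol: Sequence[float] = DEFAULT_CA_PROTOCOL,
    J: Optional[float] = None,
    tleaf_k: float = 298.15,
    plant_id: Optional[str] = None,
    day: Optional[int] = None,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate a noiseless A/Ci response curve over the CO2 protocol.

    For each sample-CO2 setpoint the coupled diffusion/biochemistry system
    An = gsc*(Ca - Ci) = gm*(Ci - Cc) = FvCB(Cc) is solved exactly.  ``gm``
    may be ``inf`` (Cc = Ci).  ``J`` defaults to ``params.Jmax`` (light-
    saturated).  Returns a tidy frame with one row per setpoint and the
    fluorescence-consistent electron transport rate Jf per point.
    """
    if gs <= 0 or gm <= 0:
        raise DomainError("conductances must be positive")
    if J is None:
        J = params.Jmax
    if J <= 0:
        raise DomainError("electron transport J must be positive")
    gsc = gs / H2O_CO2_DIFFUSIVITY
    gt = 1.0 / (1.0 / gsc + 1.0 / gm) if np.isfinite(gm) else gsc
    rows = []
    for Ca in protocol:
        An, Cc = _solve_setpoint(params, gt, float(Ca), J)
        Ci = Ca - An / gsc
        S = An + params.Rd
        if Cc - params.gamma_star > 1e-9 and S > 0:
            Jf = S * (4.0 * Cc + 8.0 * params.gamma_star) / (Cc - params.gamma_star)
        else:
            Jf = np.nan
        rows.append(
            {
                "Ca": float(Ca), "Ci": Ci, "An": An, "Cc": Cc, "Jf": Jf,
                "Tleaf": tleaf_k, "plant_id": plant_id, "day": day,
                "treatment": treatment,
            }
        )
    curve = pd.DataFrame(rows)
    resid = np.abs(gsc * (curve["Ca"] - curve["Ci"]) - gm * (curve["Ci"] - curve["Cc"]))
    if np.isfinite(gm) and resid.max() > 1e-8:
        raise RuntimeError(f"supply residual {resid.max():.3g} exceeds 1e-8")
    return curve


def fit_vcmax(
    curve: pd.DataFrame,
    params_known: FvCBParams,
    ci_cutoff: float = 300.0,
    x_col: str = "Ci",
    fit_rd: bool = False,
    min_points: int = 5,
):
    """Estimate Vcmax from the Rubisco-limited segment of an A/Ci curve.

    Points with ``x_col`` (default the intercellular CO2, i.e. assuming
    infinite mesophyll conductance for the fit) below ``ci_cutoff`` are
    fitted by bounded least squares to the Rubisco-limited branch with
    gamma_star/Kc/Ko fixed from ``params_known``.  Set ``x_col="Cc"`` to fit
    on a chloroplastic-CO2 basis when Cc has been reconstructed from a gm
    estimate.  Returns a :class:`VcmaxFit`.
    """
    sub = curve[np.isfinite(curve[x_col]) & (curve[x_col] < ci_cutoff)]
    if len(sub) < min_points:
        raise FitError(
            f"only {len(sub)} points with {x_col} < {ci_cutoff}; "
            f"need >= {min_points} for the Rubisco-limited fit"
        )
    _check_repeated_400(curve)
    x = sub[x_col].to_numpy(dtype=float)
    y = sub["An"].to_numpy(dtype=float)
    phi = (x - params_known.gamma_star) / (x + params_known.Km)
    v0 = max(4.0 * float(np.max(y)), 1.0)

    if fit_rd:
        def resid(theta):
            return theta[0] * phi - theta[1] - y
        sol = least_squares(resid, x0=[v0, max(params_known.Rd, 0.1)],
                            bounds=([1e-6, 0.0], [1000.0, 20.0]))
        vcmax, rd = sol.x
    else:
        rd = params_known.Rd
        def resid(theta):
            return theta[0] * phi - rd - y
        sol = least_squares(resid, x0=[v0], bounds=([1e-6], [1000.0]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        vcmax = sol.x[0]
    if not sol.success:
        raise FitError(f"Vcmax fit did not converge from Vcmax0={v0}: {sol.message}")
    rss = float(np.sum(sol.fun ** 2))
    return VcmaxFit(Vcmax=float(vcmax), Rd=float(rd), rss=rss,
                    n_points=len(sub), ci_cutoff=ci_cutoff, basis=x_col)


@dataclass(frozen=True)
class VcmaxFit:
    """Result of an A/Ci Rubisco-limited fit."""

    Vcmax: float
    Rd: float
    rss: float
    n_points: int
    ci_cutoff: float
    basis: str


def _check_repeated_400(curve: pd.DataFrame) -> None:
    """Warn if the two repeated 400-setpoint readings disagree by > 10%."""
    if "Ca" not in curve:
        return
    rep = curve[np.isclose(curve["Ca"], 400.0)]["An"].to_numpy()
    if len(rep) >= 3:
        a, b = rep[1], rep[2]  # the back-to-back repeats after the descent
        ref = max(abs(a), abs(b), 1e-12)
        if abs(a - b) / ref > 0.10:
            warnings.warn(
                f"repeated 400 umol/mol setpoints differ by "
                f"{abs(a - b) / ref:.1%} in An; leaf may not have re-stabilised",
                stacklevel=3,
            )


def params_with(params: FvCBParams, **kwargs) -> FvCBParams:
    """Convenience copy-with-updates for FvCBParams."""
    return replace(params, **kwargs)
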