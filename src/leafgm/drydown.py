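"""Seeded generator of a synthetic progressive soil-drydown experiment.

Emulates a greenhouse pot experiment on tomato seedlings: a well-watered
control arm and a drought arm in which irrigation is withheld for a week so
that relative soil water content (RSWC) falls from ~83% to ~37% of field
capacity and soil water potential from -0.40 to -1.44 MPa.  Leaf water
potential holds at its well-watered value until soil water potential passes
an onset (-0.71 MPa) and then declines linearly; shoot-sap ABA stays at a
low baseline until a deeper threshold (-1.01 MPa) and then rises
exponentially in -psi_soil, calibrated so the final drought mean is ~97.9
ng/ml, roughly 300x the control.  Stomatal conductance responds to leaf
water potential from mild stress onward and is further reduced by ABA;
mesophyll conductance holds a plateau until leaf water potential passes
-1.28 MPa — so gs, by construction, departs from the control before gm
does, the ordering the analysis is meant to detect.

Gas-exchange observations are produced by running the FvCB supply/demand
balance forward with the true conductances, back-filling a fluorescence
signal that is exactly consistent with the variable-J identity, and then
applying seeded multiplicative log-normal noise per observable.  Truth
tables (gs_true, gm_true, Vcmax_true, ...) are emitted alongside for
recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import aci as aci_mod
from .aci import DEFAULT_CA_PROTOCOL, FvCBParams, _solve_setpoint
from .config import DEFAULT_CONFIG, PhotoConfig
from .core import H2O_CO2_DIFFUSIVITY


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal coefficient of variation per observable."""

    An: float = 0.02
    gs: float = 0.02
    Ci: float = 0.02
    phi: float = 0.02
    rswc: float = 0.02
    psi_soil: float = 0.03
    psi_leaf: float = 0.03
    aba: float = 0.10

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"noise CV {name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(**{name: 0.0 for name in cls.__dataclass_fields__})


@dataclass(frozen=True)
class DrydownScenario:
    """Configuration of the synthetic drydown experiment.

    Water-status trajectory anchors, the response thresholds of leaf water
    potential / ABA / conductances, the FvCB parameter truth, the noise
    model and replicate counts.  ``identical seed -> identical dataset``.
    """

    # timeline (days after transplanting), inclusive
    day_start: int = 27
    day_end: int = 33
    # drought-arm RSWC endpoints (% of field capacity) and retention anchors
    rswc_start: float = 82.90
    rswc_end: float = 37.27
    psi_soil_at_start: float = -0.40   # MPa at rswc_start
    psi_soil_at_end: float = -1.44     # MPa at rswc_end
    # control arm
    rswc_control: float = 75.13
    psi_soil_control: float = -0.43
    # leaf water potential response
    psi_leaf_ww: float = -0.72
    psi_leaf_onset: float = -0.71      # psi_soil at which psi_leaf starts to fall
    psi_leaf_slope: float = 1.25       # d(psi_leaf)/d(psi_soil) past the onset
    # ABA response (ng/ml)
    aba_baseline: float = 97.86 / 300.0
    aba_psi_threshold: float = -1.01   # psi_soil below which ABA rises
    aba_rate: float = math.log(300.0) / 0.43  # per MPa; hits 97.86 at -1.44
    # stomatal conductance model (mol H2O m-2 s-1)
    gs_ww: float = 0.32
    gs_psi_onset: float = -0.90        # psi_leaf at which gs starts to fall
    gs_hydraulic_slope: float = 1.10   # fractional loss per MPa past onset
    aba_half: float = 50.0             # ng/ml at which the ABA factor halves
    gs_min: float = 0.010
    # mesophyll conductance model (mol CO2 m-2 s-1)
    gm_plateau: float = 0.20
    gm_psi_threshold: float = -1.28    # psi_leaf below which gm declines
    gm_decline_slope: float = 0.53     # mol m-2 s-1 per MPa past threshold
    gm_min: float = 0.010
    # biochemistry truth and measurement conditions
    vcmax: float = 100.0
    jmax: float = 160.0                # light-saturated J at PPFD 1500
    rdark: float = 2.0                 # dark respiration; Rd = rdark/2
    tleaf_k: float = 298.15
    ppfd: float = 1500.0
    ca: float = 400.0
    rh: float = 55.0
    fm_prime: float = 2000.0           # fixed instrument-scale Fm'
    # replication and noise
    n_control: int = 2
    n_drought: int = 6
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    kinetics: PhotoConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if self.day_end < self.day_start:
            raise ValueError("inverted day range")
        if not (0 < self.rswc_end < self.rswc_start <= 100):
            raise ValueError("drought RSWC endpoints must satisfy 0 < end < start <= 100")
        for name in ("psi_soil_at_start", "psi_soil_at_end", "psi_leaf_ww"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative (MPa)")
        if self.aba_baseline <= 0:
            raise ValueError("ABA baseline must be positive")
        lo, hi = self.psi_soil_at_end, self.psi_soil_at_start
        for name in ("psi_leaf_onset", "aba_psi_threshold"):
            if not (lo <= getattr(self, name) <= hi):
                raise ValueError(f"{name} outside the simulated psi_soil range")

    def zero_noise(self) -> "DrydownScenario":
        return replace(self, noise=NoiseModel.zero())

    def with_seed(self, seed: int) -> "DrydownScenario":
        return replace(self, seed=seed)

    @property
    def rd(self) -> float:
        return self.rdark / 2.0

    def fvcb_params(self) -> FvCBParams:
        k = self.kinetics
        return FvCBParams(
            Vcmax=self.vcmax,
            Jmax=self.jmax,
            Rd=self.rd,
            gamma_star=k.gamma_star_at(self.tleaf_k),
            Kc=k.kc_at(self.tleaf_k),
            Ko=k.ko_at(self.tleaf_k),
            O=k.O_mmol_mol,
        )

    # --- deterministic response functions -------------------------------

    def psi_soil_from_rswc(self, rswc: float) -> float:
        """Log-linear water-retention mapping between the two anchors."""
        a = math.log(-self.psi_soil_at_start)
        b = (math.log(-self.psi_soil_at_end) - a) / (self.rswc_end - self.rswc_start)
        return -math.exp(a + b * (rswc - self.rswc_start))

    def psi_leaf_response(self, psi_soil: float) -> float:
        if psi_soil >= self.psi_leaf_onset:
            return self.psi_leaf_ww
        return self.psi_leaf_ww + self.psi_leaf_slope * (psi_soil - self.psi_leaf_onset)

    def aba_response(self, psi_soil: float) -> float:
        if psi_soil >= self.aba_psi_threshold:
            return self.aba_baseline
        return self.aba_baseline * math.exp(
            self.aba_rate * (self.aba_psi_threshold - psi_soil)
        )

    def gs_response(self, psi_leaf: float, aba: float) -> float:
        f_hyd = 1.0
        if psi_leaf < self.gs_psi_onset:
            f_hyd = 1.0 + self.gs_hydraulic_slope * (psi_leaf - self.gs_psi_onset)
        f_aba = (1.0 + self.aba_baseline / self.aba_half) / (1.0 + aba / self.aba_half)
        return max(self.gs_min, self.gs_ww * f_hyd * f_aba)

    def gm_response(self, psi_leaf: float) -> float:
        if psi_leaf >= self.gm_psi_threshold:
            return self.gm_plateau
        return max(
            self.gm_min,
            self.gm_plateau + self.gm_decline_slope * (psi_leaf - self.gm_psi_threshold),
        )


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal factor with coefficient of variation ~cv."""
    if cv == 0.0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, cv, size=size))


def simulate_water_status(scenario: DrydownScenario,
                          seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate the water-status tables for both arms.

    One row per plant x day with RSWC (% field capacity), soil and leaf
    water potential (MPa) and shoot-sap ABA (ng/ml).  The drought-arm RSWC
    declines linearly between the scenario endpoints; all response
    variables follow the scenario's threshold functions evaluated on each
    replicate's (noisy) soil water potential, so replicate scatter
    propagates coherently.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    days = np.arange(scenario.day_start, scenario.day_end + 1)
    span = max(len(days) - 1, 1)
    rows = []
    for i, day in enumerate(days):
        frac = i / span
        rswc_day = scenario.rswc_start + frac * (scenario.rswc_end - scenario.rswc_start)
        for rep in range(scenario.n_drought):
            rswc = rswc_day * _lognoise(rng, scenario.noise.rswc)
            psi_soil = scenario.psi_soil_from_rswc(rswc) * _lognoise(
                rng, scenario.noise.psi_soil)
            psi_leaf = scenario.psi_leaf_response(psi_soil) * _lognoise(
                rng, scenario.noise.psi_leaf)
            aba = scenario.aba_response(psi_soil) * _lognoise(rng, scenario.noise.aba)
            rows.append(("D%d" % (rep + 1), int(day), "drought",
                         rswc, psi_soil, psi_leaf, aba))
        for rep in range(scenario.n_control):
            rswc = scenario.rswc_control * _lognoise(rng, scenario.noise.rswc)
            psi_soil = scenario.psi_soil_control * _lognoise(rng, scenario.noise.psi_soil)
            psi_leaf = scenario.psi_leaf_ww * _lognoise(rng, scenario.noise.psi_leaf)
            aba = scenario.aba_baseline * _lognoise(rng, scenario.noise.aba)
            rows.append(("CK%d" % (rep + 1), int(day), "control",
                         rswc, psi_soil, psi_leaf, aba))
    return pd.DataFrame(
        rows, columns=["plant_id", "day", "treatment",
                       "RSWC", "psi_soil", "psi_leaf", "ABA"]
    )


def simulate_conductances(status_row, scenario: DrydownScenario):
    """True (gs, gm) for one water-status record (deterministic)."""
    psi_leaf = float(status_row["psi_leaf"] if isinstance(status_row, (dict, pd.Series))
                     else status_row.psi_leaf)
    aba = float(status_row["ABA"] if isinstance(status_row, (dict, pd.Series))
                else status_row.ABA)
    return scenario.gs_response(psi_leaf, aba), scenario.gm_response(psi_leaf)


def generate_observations(scenario: DrydownScenario,
                          seed: Optional[int] = None,
                          include_aci: bool = True) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic experiment.

    Returns a dict with keys ``observations`` (spot gas exchange +
    fluorescence at Ca=400), ``water_status``, ``truth`` (per-record true
    gs/gm/Vcmax and noiseless fluxes) and, when ``include_aci``, ``aci``
    (per plant x day A/Ci curves with noise on An).

    The fluorescence back-fill sets Jf to the value exactly consistent with
    the variable-J identity at the true Cc, so the inversion recovers
    gm_true to machine precision on zero-noise data.
    """
    base_seed = scenario.seed if seed is None else seed
    # independent streams so the observation table is identical whether or
    # not A/Ci curves are generated
    obs_stream, aci_stream = np.random.SeedSequence(base_seed).spawn(2)
    rng = np.random.default_rng(obs_stream)
    rng_aci = np.random.default_rng(aci_stream)
    status = simulate_water_status(scenario, seed=base_seed)
    params = scenario.fvcb_params()
    gstar = params.gamma_star
    denom_phi = scenario.ppfd * scenario.kinetics.alpha * scenario.kinetics.beta

    obs_rows, truth_rows, aci_frames = [], [], []
    for row in status.itertuples(index=False):
        gs_true, gm_true = simulate_conductances(row, scenario)
        gsc = gs_true / H2O_CO2_DIFFUSIVITY
        gt = 1.0 / (1.0 / gsc + 1.0 / gm_true)
        an, cc = _solve_setpoint(params, gt, scenario.ca, scenario.jmax)
        ci = scenario.ca - an / gsc
        s = an + params.Rd
        jf = s * (4.0 * cc + 8.0 * gstar) / (cc - gstar)
        phi = jf / denom_phi
        if not (0.0 < phi < 1.0):
            raise RuntimeError(f"fluorescence back-fill out of range: phi={phi}")

        an_obs = an * _lognoise(rng, scenario.noise.An)
        gs_obs = gs_true * _lognoise(rng, scenario.noise.gs)
        ci_obs = ci * _lognoise(rng, scenario.noise.Ci)
        phi_obs = min(phi * _lognoise(rng, scenario.noise.phi), 0.999)
        fs_obs = scenario.fm_prime * (1.0 - phi_obs)

        obs_rows.append({
            "plant_id": row.plant_id, "day": row.day, "treatment": row.treatment,
            "An": an_obs, "gs": gs_obs, "Ci": ci_obs, "Ca": scenario.ca,
            "Tleaf": scenario.tleaf_k, "PPFD": scenario.ppfd,
            "Fs": fs_obs, "Fm_prime": scenario.fm_prime, "RH": scenario.rh,
        })
        truth_rows.append({
            "plant_id": row.plant_id, "day": row.day, "treatment": row.treatment,
            "gs_true": gs_true, "gm_true": gm_true, "Vcmax_true": scenario.vcmax,
            "An_true": an, "Ci_true": ci, "Cc_true": cc, "Jf_true": jf,
            "psi_leaf": row.psi_leaf, "psi_soil": row.psi_soil, "ABA": row.ABA,
        })
        if include_aci:
            curve = aci_mod.simulate_aci_curve(
                params, gm_true, gs_true, protocol=DEFAULT_CA_PROTOCOL,
                J=scenario.jmax, tleaf_k=scenario.tleaf_k,
                plant_id=row.plant_id, day=row.day, treatment=row.treatment,
            )
            curve = curve.drop(columns=["Cc", "Jf"])
            curve["An"] = curve["An"] * _lognoise(rng_aci, scenario.noise.An,
                                                  size=len(curve))
            aci_frames.append(curve)

    out = {
        "observations": pd.DataFrame(obs_rows),
        "water_status": status,
        "truth": pd.DataFrame(truth_rows),
    }
    if include_aci:
        out["aci"] = pd.concat(aci_frames, ignore_index=True)
    return out
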