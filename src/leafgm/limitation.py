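"""Grassi–Magnani partitioning of photosynthetic limitation and the
variable-J sensitivity analysis.

The partition splits the relative limitation of net assimilation into a
stomatal (ls), mesophyll (lm) and biochemical (lb) fraction

    ls = (gt/gsc * dA/dCc) / (gt + dA/dCc)
    lm = (gt/gm  * dA/dCc) / (gt + dA/dCc)
    lb =  gt                / (gt + dA/dCc)

with gt the series combination of gsc and gm; the three fractions sum to
one algebraically.  The sensitivity analysis perturbs each variable-J input
(Rd, gamma_star, Jf, Ci) by -20/-10/+10/+20 % one at a time and re-runs the
inversion, reporting the perturbed-gm distribution and how many records the
perturbation destabilises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError, GmEstimate, gm_variable_j, total_conductance

SENSITIVITY_FACTORS = ("Rd", "gamma_star", "Jf", "Ci")
SENSITIVITY_PERTURBATIONS = (-0.20, -0.10, 0.10, 0.20)

FLAG_NS = "ns"
FLAG_P05 = "P<0.05"
FLAG_P01 = "P<0.01"
FLAG_INSUFFICIENT = "insufficient replication"


@dataclass(frozen=True)
class LimitationPartition:
    """Relative stomatal/mesophyll/biochemical limitation fractions."""

    ls: float
    lm: float
    lb: float
    dAdCc: float
    gt: float
    gsc: float
    gm: float


@dataclass(frozen=True)
class SensitivityResult:
    """One cell of the sensitivity table (factor x perturbation)."""

    factor: str
    perturbation: float
    gm_mean: float
    gm_sd: float
    n_valid: int
    n_invalid: int
    flag: str


def partition_limitations(gsc, gm, dAdCc) -> LimitationPartition:
    """Partition relative photosynthetic limitation into ls, lm, lb.

    All inputs in mol m-2 s-1 (conductances and dA/dCc on the same flux per
    mole-fraction basis).  The fractions are each in (0, 1) for finite
    positive inputs and sum to one exactly up to floating error.
    """
    if gsc <= 0 or gm <= 0 or dAdCc <= 0:
        raise DomainError("gsc, gm and dA/dCc must all be positive")
    gt = total_conductance(gsc, gm)
    denom = gt + dAdCc
    ls = (gt / gsc) * dAdCc / denom
    lm = (gt / gm) * dAdCc / denom
    lb = gt / denom
    return LimitationPartition(ls=ls, lm=lm, lb=lb, dAdCc=dAdCc,
                               gt=gt, gsc=gsc, gm=gm)


def partition_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised partition over a frame with gsc, gm, dAdCc columns."""
    gsc = df["gsc"].to_numpy(dtype=float)
    gm = df["gm"].to_numpy(dtype=float)
    dadcc = df["dAdCc"].to_numpy(dtype=float)
    if np.any(gsc <= 0) or np.any(gm <= 0) or np.any(dadcc <= 0):
        raise DomainError("gsc, gm and dA/dCc must all be positive")
    gt = 1.0 / (1.0 / gsc + 1.0 / gm)
    denom = gt + dadcc
    out = df.copy()
    out["gt"] = gt
    out["ls"] = (gt / gsc) * dadcc / denom
    out["lm"] = (gt / gm) * dadcc / denom
    out["lb"] = gt / denom
    return out


def _perturbed_estimates(records: pd.DataFrame, factor: str,
                         perturbation: float) -> list[GmEstimate]:
    scale = 1.0 + perturbation
    ests = []
    for row in records.itertuples(index=False):
        kwargs = {
            "An": row.An, "Ci": row.Ci, "gamma_star": row.gamma_star,
            "Rd": row.Rd, "Jf": row.Jf,
        }
        if factor is not None:
            kwargs[factor] = kwargs[factor] * scale
        ests.append(gm_variable_j(**kwargs))
    return ests


def gm_sensitivity_table(
    records: pd.DataFrame,
    factors: Sequence[str] = SENSITIVITY_FACTORS,
    perturbations: Sequence[float] = SENSITIVITY_PERTURBATIONS,
) -> pd.DataFrame:
    """Sensitivity of the variable-J gm estimate to input errors.

    ``records`` needs columns An, Ci, gamma_star, Rd, Jf (one row per
    observation with a valid baseline estimate).  Each of the factor x
    perturbation cells scales exactly one input multiplicatively across all
    records, re-runs the inversion, and reports mean +/- sd of the valid
    perturbed estimates, the count of newly invalid records, and a paired
    significance flag against the baseline.
    """
    if len(records) == 0:
        raise DomainError("need at least one record with a valid baseline")
    baseline = _perturbed_estimates(records, None, 0.0)
    base_gm = np.array([e.gm for e in baseline])
    if not np.any([e.valid for e in baseline]):
        raise DomainError("no record yields a valid baseline gm estimate")
    rows = []
    for factor in factors:
        for pert in perturbations:
            ests = _perturbed_estimates(records, factor, pert)
            gm_vals = np.array([e.gm for e in ests])
            valid = np.array([e.valid for e in ests])
            newly_invalid = int(np.sum(~valid & np.array([e.valid for e in baseline])))
            paired = valid & np.isfinite(base_gm)
            flag = compare_sensitivity(gm_vals[paired], base_gm[paired])
            rows.append(
                {
                    "factor": factor,
                    "perturbation_pct": round(pert * 100),
                    "gm_mean": float(np.mean(gm_vals[valid])) if valid.any() else np.nan,
                    "gm_sd": float(np.std(gm_vals[valid], ddof=1)) if valid.sum() > 1 else np.nan,
                    "n_valid": int(valid.sum()),
                    "n_invalid": newly_invalid,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def compare_sensitivity(perturbed: Iterable[float], baseline: Iterable[float],
                        ) -> str:
    """Paired two-sided comparison of perturbed vs baseline gm estimates.

    A paired t-test across records; returns "ns", "P<0.05" or "P<0.01", or
    "insufficient replication" with fewer than two paired values.  A
    degenerate zero-difference sample is "ns".
    """
    perturbed = np.asarray(list(perturbed), dtype=float)
    baseline = np.asarray(list(baseline), dtype=float)
    ok = np.isfinite(perturbed) & np.isfinite(baseline)
    perturbed, baseline = perturbed[ok], baseline[ok]
    if len(perturbed) < 2:
        return FLAG_INSUFFICIENT
    diff = perturbed - baseline
    if np.allclose(diff, 0.0):
        return FLAG_NS
    if np.std(diff, ddof=1) == 0.0:
        # constant nonzero shift: degenerate t -> treat as strongly significant
        return FLAG_P01
    _, p = stats.ttest_rel(perturbed, baseline)
    if np.isnan(p):
        return FLAG_NS
    if p < 0.01:
        return FLAG_P01
    if p < 0.05:
        return FLAG_P05
    return FLAG_NS


#: Default soil-water-potential breakpoints (MPa) for drought-stage binning
#: of limitation summaries: no stress, mild/moderate, severe.
DEFAULT_PSI_SOIL_BINS = (-0.71, -1.15)


def stage_bins(psi_soil, breakpoints: Sequence[float] = DEFAULT_PSI_SOIL_BINS,
               labels: Optional[Sequence[str]] = None):
    """Assign drought-stage labels from soil water potential.

    Potentials above the first breakpoint are unstressed; between the
    breakpoints mild/moderate; at or below the last, severe.
    """
    psi = np.asarray(psi_soil, dtype=float)
    if labels is None:
        labels = ("none", "mild-moderate", "severe")
    hi, lo = breakpoints
    out = np.where(psi > hi, labels[0], np.where(psi > lo, labels[1], labels[2]))
    return out.item() if out.ndim == 0 else out
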