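"""Statistical surface of the drydown analysis.

Pairwise Pearson correlation matrices with significance flags, regression
family selection by r^2 among {linear, exponential, logarithmic}, and
per-day drought-vs-control comparisons with multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FLAG_NS = "ns"
FLAG_P05 = "P<0.05"
FLAG_P01 = "P<0.01"
FLAG_INSUFFICIENT = "insufficient replication"
FLAG_UNDEFINED = "undefined"

FAMILIES = ("linear", "exponential", "logarithmic")

#: Default variable set of the pooled correlation analysis.
DEFAULT_CORR_VARS = ("An", "gs", "gm", "gm_over_gs", "WUEi", "psi_leaf", "ABA")


def _p_flag(p: float) -> str:
    if np.isnan(p):
        return FLAG_UNDEFINED
    if p < 0.01:
        return FLAG_P01
    if p < 0.05:
        return FLAG_P05
    return FLAG_NS


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with significance flags."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame
    n: pd.DataFrame


@dataclass(frozen=True)
class RelationshipFit:
    """Best-by-r^2 regression among candidate families.

    ``coefficients`` are (intercept-like, slope-like) on the family's
    natural parameterisation: linear y=a+bx; exponential y=a*exp(bx);
    logarithmic y=a+b*ln(x).  r^2 is computed on the original y scale for
    comparability across families.
    """

    family: str
    coefficients: tuple[float, float]
    r2: float
    p_value: float
    n: int
    significant: bool

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.coefficients
        if self.family == "linear":
            return a + b * x
        if self.family == "exponential":
            return a * np.exp(b * x)
        return a + b * np.log(x)


def correlation_matrix(table: pd.DataFrame,
                       variables: Sequence[str] = DEFAULT_CORR_VARS,
                       min_n: int = 3) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided P and 0.05/0.01 flags.

    Rows with missing values are dropped pairwise.  A pair with fewer than
    ``min_n`` complete rows, or with a constant column, is flagged
    "undefined" with r = NaN.
    """
    variables = tuple(v for v in variables if v in table.columns)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(table))
    flags = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if len(pair) < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                flags[i, j] = flags[j, i] = FLAG_UNDEFINED
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            flags[i, j] = flags[j, i] = _p_flag(res.pvalue)
    idx = list(variables)
    return CorrelationMatrix(
        variables=variables,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        flags=pd.DataFrame(flags, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def _fit_family(x: np.ndarray, y: np.ndarray, family: str):
    """Least-squares fit of one family; returns (coeffs, r2, p) or None.

    The exponential family is fitted by log-linearisation (ordinary least
    squares on ln y), the logarithmic by OLS on ln x; r^2 is always
    evaluated against y on the original scale.
    """
    if family == "exponential":
        if np.any(y <= 0):
            return None
        res = stats.linregress(x, np.log(y))
        coeffs = (float(np.exp(res.intercept)), float(res.slope))
        yhat = coeffs[0] * np.exp(coeffs[1] * x)
    elif family == "logarithmic":
        if np.any(x <= 0):
            return None
        res = stats.linregress(np.log(x), y)
        coeffs = (float(res.intercept), float(res.slope))
        yhat = coeffs[0] + coeffs[1] * np.log(x)
    else:
        res = stats.linregress(x, y)
        coeffs = (float(res.intercept), float(res.slope))
        yhat = coeffs[0] + coeffs[1] * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return coeffs, r2, float(res.pvalue)


def fit_best_relationship(x, y,
                          candidates: Sequence[str] = FAMILIES) -> RelationshipFit:
    """Fit each admissible candidate family and keep the one with highest r^2.

    Follows the display rule of reporting a regression only when its slope
    is significant at P < 0.05; ``significant=False`` marks fits that would
    not be drawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError(f"need at least 4 points, got {len(x)}")
    bad = {f for f in candidates if f not in FAMILIES}
    if bad:
        raise ValueError(f"unknown families: {sorted(bad)}")
    best = None
    for family in candidates:
        fit = _fit_family(x, y, family)
        if fit is None:
            continue
        coeffs, r2, p = fit
        if best is None or (np.isfinite(r2) and r2 > best[1]):
            best = (family, r2, coeffs, p)
    if best is None:
        raise ValueError("no admissible regression family for these data")
    family, r2, coeffs, p = best
    return RelationshipFit(family=family, coefficients=coeffs,
                           r2=float(np.clip(r2, 0.0, 1.0)), p_value=p,
                           n=len(x), significant=bool(p < 0.05))


def compare_to_control(df: pd.DataFrame, value_col: str,
                       treatment_col: str = "treatment",
                       day_col: str = "day",
                       control_label: str = "control",
                       adjust: bool = True) -> pd.DataFrame:
    """Per-day comparison of the treatment arm against the control arm.

    Welch two-sample t-tests per day with Holm adjustment across days (the
    per-day flags mirror many-to-one Dunnett-style annotation against a
    single control).  Days with fewer than two values in either arm are
    flagged "insufficient replication".  Returns a frame with one row per
    day: means, test statistic, raw and adjusted P, and the flag.
    """
    rows = []
    for day, grp in df.groupby(day_col, sort=True):
        ctrl = grp.loc[grp[treatment_col] == control_label, value_col].dropna()
        trt = grp.loc[grp[treatment_col] != control_label, value_col].dropna()
        row = {
            day_col: day,
            "mean_control": float(ctrl.mean()) if len(ctrl) else np.nan,
            "mean_treatment": float(trt.mean()) if len(trt) else np.nan,
            "n_control": len(ctrl), "n_treatment": len(trt),
        }
        if len(ctrl) < 2 or len(trt) < 2:
            row.update(t=np.nan, p_raw=np.nan, flag=FLAG_INSUFFICIENT)
        elif ctrl.std(ddof=1) == 0 and trt.std(ddof=1) == 0:
            equal = np.isclose(ctrl.mean(), trt.mean())
            row.update(t=np.nan, p_raw=1.0 if equal else 0.0,
                       flag=FLAG_NS if equal else FLAG_P01)
        else:
            t, p = stats.ttest_ind(trt, ctrl, equal_var=False)
            row.update(t=float(t), p_raw=float(p), flag=None)
        rows.append(row)
    out = pd.DataFrame(rows)
    testable = out["flag"].isna() if "flag" in out else pd.Series(False, index=out.index)
    out["p_adj"] = np.nan
    if adjust and testable.any():
        out.loc[testable, "p_adj"] = multipletests(
            out.loc[testable, "p_raw"], method="holm")[1]
    elif testable.any():
        out.loc[testable, "p_adj"] = out.loc[testable, "p_raw"]
    out.loc[testable, "flag"] = out.loc[testable, "p_adj"].map(_p_flag)
    out.attrs["method"] = ("per-day Welch t vs control, Holm-adjusted across days"
                           if adjust else "per-day Welch t vs control")
    return out


def departure_day(df: pd.DataFrame, value_col: str,
                  treatment_col: str = "treatment",
                  day_col: str = "day",
                  control_label: str = "control",
                  ratio: float = 0.9,
                  alpha: float = 0.05,
                  require_significance: bool = True):
    """First day from which the treatment arm has *sustainedly* departed
    below the control.

    The control arm is pooled across days (it is stationary by design),
    giving a stable reference against the small per-day control
    replication.  A day counts as departed when the treatment mean falls
    below ``ratio`` times the pooled control mean and (optionally) a Welch
    test against the pooled control is significant at ``alpha``; the
    departure day is the first day from which *every* subsequent day is
    departed, so single-day noise dips do not register.  Returns None when
    no sustained departure occurs.
    """
    ctrl = df.loc[df[treatment_col] == control_label, value_col].dropna()
    trt = df[df[treatment_col] != control_label]
    days = sorted(trt[day_col].unique())
    if len(ctrl) < 2 or not days:
        return None

    def departed(day) -> bool:
        vals = trt.loc[trt[day_col] == day, value_col].dropna()
        if len(vals) < 2:
            return False
        if vals.mean() >= ratio * ctrl.mean():
            return False
        if not require_significance:
            return True
        if vals.std(ddof=1) == 0 and ctrl.std(ddof=1) == 0:
            return True
        _, p = stats.ttest_ind(vals, ctrl, equal_var=False)
        return bool(p < alpha)

    flags = {d: departed(d) for d in days}
    for i, d in enumerate(days):
        if all(flags[dd] for dd in days[i:]):
            return d
    return None


def derive_analysis_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ratio columns used by the pooled correlation table."""
    out = estimates.copy()
    if "gm" in out and "gs" in out:
        out["gm_over_gs"] = out["gm"] / out["gs"]
    if "An" in out and "gs" in out and "WUEi" not in out:
        out["WUEi"] = out["An"] / out["gs"]
    return out


def correlation_matrix_csv(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Upper-triangle layout (r with flag suffix) for CSV export."""
    k = len(matrix.variables)
    cells = np.full((k, k), "", dtype=object)
    for i in range(k):
        cells[i, i] = "1"
        for j in range(i + 1, k):
            r = matrix.r.iloc[i, j]
            flag = matrix.flags.iloc[i, j]
            star = {"P<0.01": "**", "P<0.05": "*"}.get(flag, "")
            cells[i, j] = f"{r:.3f}{star}" if np.isfinite(r) else "nan"
    return pd.DataFrame(cells, index=matrix.variables, columns=matrix.variables)
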