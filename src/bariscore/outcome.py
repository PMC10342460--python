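"""Risk-score category effects on weight response, and profile comparisons.

The high-vs-low score categories are related to the weight-response
phenotypes by covariate-adjusted linear regression (mean difference with 95%
CI) for continuous outcomes and logistic regression (odds ratio with 95% CI)
for binary codings, always with the high category contrasted against low.
Pre-surgery profiles across categories are compared with Welch's t-test for
continuous variables and a chi-square test for categorical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    BINARY_PHENOTYPES,
    covariate_design,
    phenotype_family,
    _ci_halfwidth,
    _fit,
)
from .errors import EmptyCategoryError, InsufficientDataError, InvalidArgumentError

DEFAULT_OUTCOMES = ("twl_nadir", "twl_6y", "wr_mwl", "ewl6y_gt50", "wr_gt20")


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Proportion as a percentage, rounded half-up to ``decimals`` places.

    This is the routine used for every count/percentage pair printed in the
    cohort summary tables.
    """
    if total <= 0:
        raise InvalidArgumentError("total must be positive")
    if not 0 <= count <= total:
        raise InvalidArgumentError("count must be between 0 and total")
    value = Decimal(count) * Decimal(100) / Decimal(total)
    quant = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))


def fold_restatement(odds_ratio: float, decimals: int = 2) -> float:
    """'x times more likely (to fail)' restatement of an odds ratio below 1.

    The reciprocal of the OR, rounded half-up.
    """
    if odds_ratio <= 0:
        raise InvalidArgumentError("odds ratio must be positive")
    value = Decimal(1) / Decimal(str(odds_ratio))
    quant = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RSEffect:
    phenotype: str
    kind: str  # 'mean_difference' or 'odds_ratio'
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_high: int
    n_low: int

    def __post_init__(self) -> None:
        if math.isfinite(self.estimate) and not (
            self.ci_low <= self.estimate <= self.ci_high
        ):
            raise InvalidArgumentError("CI must contain the point estimate")


def rs_effect_analysis(
    categories: pd.Series,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
) -> list[RSEffect]:
    """Adjusted high-vs-low effects of the score category on each outcome."""
    ids = list(phenotypes.index)
    categories = categories.reindex(ids)
    if covariates is not None:
        covariates = covariates.reindex(ids)
    high = (categories == "high").to_numpy(float)
    known = categories.isin(["high", "low"]).to_numpy()
    if (categories == "high").sum() == 0 or (categories == "low").sum() == 0:
        raise EmptyCategoryError("both score categories must be non-empty")

    if covariates is not None:
        Xc, _ = covariate_design(covariates)
    else:
        Xc = np.empty((len(ids), 0))

    effects: list[RSEffect] = []
    for ph in outcomes:
        family = phenotype_family(ph)
        y = pd.to_numeric(phenotypes[ph], errors="coerce").to_numpy(dtype=float)
        mask = known & np.isfinite(y) & np.all(np.isfinite(Xc), axis=1)
        n_high = int(high[mask].sum())
        n_low = int(mask.sum() - n_high)
        if n_high == 0 or n_low == 0:
            raise EmptyCategoryError(
                f"{ph}: a score category is empty after complete-case filtering"
            )
        X = np.column_stack([np.ones(mask.sum()), high[mask], Xc[mask]])
        fit = _fit(X, y[mask], family)
        est = float(fit.params[1])
        hw = float(_ci_halfwidth(fit, family)[1])
        if family == "linear":
            tstat = est / fit.bse[1]
            p = float(2.0 * stats.t.sf(abs(tstat), fit.df_resid))
            effects.append(
                RSEffect(ph, "mean_difference", est, est - hw, est + hw, p, n_high, n_low)
            )
        else:
            z = est / fit.bse[1]
            p = float(2.0 * stats.norm.sf(abs(z)))
            effects.append(
                RSEffect(
                    ph,
                    "odds_ratio",
                    math.exp(est),
                    math.exp(est - hw),
                    math.exp(est + hw),
                    p,
                    n_high,
                    n_low,
                )
            )
    return effects


# --------------------------------------------------------------------------
# profile comparison
# --------------------------------------------------------------------------
_CONTINUOUS = (("bmi0", "BMI, kg/m2"), ("age", "Age, years"))
_CATEGORICAL = (
    ("female", "Female, n (%)"),
    ("t2d", "T2D, n (%)"),
    ("htn", "HTN, n (%)"),
    ("restrictive", "Restrictive, n (%)"),
    ("mixed", "Mixed, n (%)"),
    ("malabsorptive", "Malabsorptive, n (%)"),
)


def compare_profiles(categories: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pre-surgery profile by score category: one row per variable.

    Continuous variables are summarized as mean (SD) and compared by Welch's
    t-test; categorical ones as n (%) with a chi-square test. Tests that
    need variance report NaN when a category has fewer than two patients.
    """
    categories = categories.reindex(covariates.index)
    low = covariates[(categories == "low").to_numpy()]
    high = covariates[(categories == "high").to_numpy()]
    if len(low) == 0 or len(high) == 0:
        raise EmptyCategoryError("both score categories must be non-empty")

    flags = {
        "female": covariates["sex"] == "female",
        "t2d": covariates["t2d"].astype(bool),
        "htn": covariates["htn"].astype(bool),
        "restrictive": covariates["surgery"] == "restrictive",
        "mixed": covariates["surgery"] == "mixed",
        "malabsorptive": covariates["surgery"] == "malabsorptive",
    }

    rows = []
    for col, label in _CONTINUOUS:
        a = low[col].to_numpy(float)
        b = high[col].to_numpy(float)
        if len(a) >= 2 and len(b) >= 2:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "variable": label,
                "low": f"{a.mean():.2f} ({a.std(ddof=1):.2f})" if len(a) > 1 else f"{a.mean():.2f}",
                "high": f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) > 1 else f"{b.mean():.2f}",
                "p_value": p,
            }
        )
    for col, label in _CATEGORICAL:
        flag = flags[col]
        a = flag[(categories == "low").to_numpy()]
        b = flag[(categories == "high").to_numpy()]
        table = np.array(
            [[int(a.sum()), int(len(a) - a.sum())], [int(b.sum()), int(len(b) - b.sum())]]
        )
        if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "variable": label,
                "low": f"{int(a.sum())} ({percent(int(a.sum()), len(a), 2)})",
                "high": f"{int(b.sum())} ({percent(int(b.sum()), len(b), 2)})",
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(covariates: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Demographic / weight-response summary table (mean +/- SD or n (%))."""
    n = len(covariates)
    rows = [
        ("Age, years", f"{covariates['age'].mean():.2f} ± {covariates['age'].std(ddof=1):.2f}"),
        (
            "Female, n (%)",
            f"{int((covariates['sex'] == 'female').sum())} "
            f"({percent(int((covariates['sex'] == 'female').sum()), n, 0):.0f})",
        ),
        ("BMI, kg/m2", f"{covariates['bmi0'].mean():.2f} ± {covariates['bmi0'].std(ddof=1):.2f}"),
    ]
    for col in ("twl_nadir", "ewl_nadir", "twl_6y", "ewl_6y"):
        v = pd.to_numeric(phenotypes[col], errors="coerce").dropna()
        rows.append((col, f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"))
    for col, dec in (("ewl6y_gt50", 2), ("wr_gt20", 1)):
        flag = phenotypes[col].dropna().astype(bool)
        rows.append(
            (f"{col}, n (%)", f"{int(flag.sum())} ({percent(int(flag.sum()), n, dec)})")
        )
    wr = pd.to_numeric(phenotypes["wr_mwl"], errors="coerce").dropna()
    rows.append(
        (
            "wr_mwl, median (IQR)",
            f"{wr.median():.2f} ({wr.quantile(0.25):.2f}-{wr.quantile(0.75):.2f})",
        )
    )
    return pd.DataFrame(rows, columns=["variable", "value"])
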