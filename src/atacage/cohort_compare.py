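"""Condition-effect testing on clock output.

Given per-sample predicted and chronological ages plus a two-level
condition label, tests whether the prediction discrepancy
(delta = predicted - chronological) differs between conditions: a raw
Welch t-test, and an age-adjusted linear model
``delta ~ 1 + chronological_age + condition`` whose condition coefficient
is the effect in years (clock accuracy commonly varies with age itself —
young donors tend to be overestimated — so the adjusted model is the
fairer comparison).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def make_delta_table(
    predicted: pd.Series, chronological: pd.Series, condition: pd.Series
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "predicted_age": predicted,
            "chronological_age": chronological,
            "condition": condition,
        }
    ).dropna()
    df["delta"] = df["predicted_age"] - df["chronological_age"]
    return df


def _two_levels(table: pd.DataFrame, reference: str | None):
    levels = sorted(table["condition"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    return reference, other


def group_ttest(table: pd.DataFrame, reference: str | None = None) -> dict:
    """Welch two-sample t-test on delta by condition."""
    ref, other = _two_levels(table, reference)
    a = table.loc[table["condition"] == other, "delta"].to_numpy()
    b = table.loc[table["condition"] == ref, "delta"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition level needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: Welch statistic undefined; identical means -> no effect
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t),
        "p_value": float(p),
        "mean_delta": {other: float(a.mean()), ref: float(b.mean())},
        "reference": ref,
    }


def age_adjusted_effect(table: pd.DataFrame, reference: str | None = None) -> dict:
    """Condition effect in years from OLS delta ~ 1 + age + condition.

    Returns the condition coefficient (years added to predicted age), its
    two-sided p, and the 95% confidence interval. Warns when the two
    conditions' age ranges do not overlap (effect confounded with age).
    """
    ref, other = _two_levels(table, reference)
    cond = (table["condition"] == other).astype(float).to_numpy()
    age = table["chronological_age"].to_numpy(dtype=float)
    if age[cond == 1].min() > age[cond == 0].max() or age[cond == 0].min() > age[cond == 1].max():
        warnings.warn("condition levels have non-overlapping age ranges; effect confounded with age",
                      stacklevel=2)
    X = sm.add_constant(np.column_stack([age, cond]))
    fit = sm.OLS(table["delta"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int()[2]
    return {
        "effect_years": float(fit.params[2]),
        "p_value": float(fit.pvalues[2]),
        "ci95": (float(ci[0]), float(ci[1])),
        "age_slope": float(fit.params[1]),
        "reference": ref,
        "n": int(len(table)),
    }
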