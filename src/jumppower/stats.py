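"""Condition-grid statistics: Winsorising, sequential-SS factorial ANOVA
with semi-partial omega-squared effect sizes, and stratified bootstrap
confidence intervals.

The grid of outer-fold validation errors (signal x model x sensor x jump
type x fold) is compared with a fixed-effects factorial ANOVA using
sequential (Type I) sums of squares in the order Model, Jump Type, Sensor,
Signal, Model x Jump Type.  Effect size is semi-partial omega squared,

    omega2_eff = (SS_eff - df_eff * MS_err) / (SS_total + MS_err),

the proportion of total variance attributable to the effect.  Because a
few support-vector models produce extreme validation errors, the error
vector is Winsorised (symmetric replacement of the most extreme
observations by the adjacent order statistic) before fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

EFFECT_ORDER = [
    ("Model", "C(model)"),
    ("Jump Type", "C(jump)"),
    ("Sensor", "C(sensor)"),
    ("Signal", "C(signal)"),
    ("Model x Jump Type", "C(model):C(jump)"),
]


def winsorise(errors: np.ndarray, n_adjust: int = 10) -> np.ndarray:
    """Pull the ``n_adjust // 2`` most extreme values at each end of the
    range to the adjacent unadjusted order statistic.  Length and order
    are preserved; ranks of non-adjusted observations are unchanged."""
    x = np.asarray(errors, dtype=float).copy()
    if x.size < 2 * n_adjust:
        raise ValueError(f"need at least {2 * n_adjust} observations")
    k = n_adjust // 2
    if k == 0:
        return x
    order = np.argsort(x, kind="stable")
    x[order[-k:]] = x[order[-(k + 1)]]
    x[order[:k]] = x[order[k]]
    return x


def anova_omega2(
    df: pd.DataFrame, error_col: str = "error", effects=None
) -> pd.DataFrame:
    """Type I (sequential) factorial ANOVA over the condition grid.

    ``df`` must hold one row per outer-fold error with the factor columns
    named by ``effects`` (default: the full grid order Model, Jump Type,
    Sensor, Signal, Model x Jump Type) forming a balanced factorial
    layout.  Returns one row per effect with df, F, p and semi-partial
    omega squared.
    """
    effects = EFFECT_ORDER if effects is None else effects
    factor_cols = set()
    for _, term in effects:
        for part in term.split(":"):
            factor_cols.add(part[2:-1])  # strip C( )
    missing = (factor_cols | {error_col}) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = df.groupby(sorted(factor_cols)).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced factorial layout (unequal cell counts)")
    formula = f"{error_col} ~ " + " + ".join(term for _, term in effects)
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ms_err = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    ss_total = table["sum_sq"].sum()
    rows = []
    for name, term in effects:
        ss = table.loc[term, "sum_sq"]
        dfe = table.loc[term, "df"]
        rows.append(
            {
                "effect": name,
                "df": int(dfe),
                "F": table.loc[term, "F"],
                "p": table.loc[term, "PR(>F)"],
                "omega2": (ss - dfe * ms_err) / (ss_total + ms_err),
            }
        )
    out = pd.DataFrame(rows).set_index("effect")
    out.attrs["ss_total"] = float(ss_total)
    out.attrs["ms_err"] = float(ms_err)
    return out


def bootstrap_ci(
    statistic,
    df: pd.DataFrame,
    n_boot: int = 1000,
    stratify: str | None = None,
    seed: int = 0,
    percentiles: tuple[float, float] = (5.0, 95.0),
):
    """Stratified bootstrap of an arbitrary statistic of the data frame.

    Rows are resampled with replacement within each stratum; the statistic
    may return a scalar or a 1-d vector.  Returns (median, lower, upper)
    at the requested percentiles (default 5th/95th, a 90% interval).
    """
    rng = np.random.default_rng(seed)
    if stratify is not None:
        groups = [g for _, g in df.groupby(stratify)]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty stratum")
    else:
        groups = [df]
    stats = []
    for _ in range(n_boot):
        parts = [
            g.iloc[rng.integers(0, len(g), size=len(g))] for g in groups
        ]
        stats.append(statistic(pd.concat(parts, ignore_index=True)))
    stats = np.asarray(stats, dtype=float)
    med = np.median(stats, axis=0)
    lo = np.percentile(stats, percentiles[0], axis=0)
    hi = np.percentile(stats, percentiles[1], axis=0)
    return med, lo, hi


def effect_table_with_ci(
    df: pd.DataFrame,
    n_boot: int = 1000,
    n_adjust: int = 10,
    seed: int = 0,
    error_col: str = "error",
) -> pd.DataFrame:
    """Winsorise the errors, fit the factorial ANOVA and bootstrap the
    omega-squared effect sizes stratified by condition cell."""
    data = df.copy()
    data[error_col] = winsorise(data[error_col].to_numpy(), n_adjust)
    base = anova_omega2(data, error_col)
    data["_cell"] = (
        data["model"].astype(str) + "/" + data["jump"].astype(str)
        + "/" + data["sensor"].astype(str) + "/" + data["signal"].astype(str)
    )
    med, lo, hi = bootstrap_ci(
        lambda d: anova_omega2(d, error_col)["omega2"].to_numpy(),
        data, n_boot=n_boot, stratify="_cell", seed=seed,
    )
    base["omega2_median"] = med
    base["omega2_lo"] = lo
    base["omega2_hi"] = hi
    return base
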