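"""Mixed-effects and regression models of the aggregated activity tables.

Four model families:

* Weekly linear mixed model — response is a bear-week summary (hours active
  per day, or mean active/inactive bout length); fixed effects are mean
  civil-daylight hours, sex, season and the sex x season interaction;
  random intercept per bear; REML estimation.
* Period model — response is the arcsine-square-root of the proportion of
  time active per bear x season x daily period; fixed effects are period,
  season, sex and period x season; random intercept per bear.
* Temperature regression — ordinary least squares of the arcsine-transformed
  daily 24-h activity proportion on daily maximum temperature.
* Warm/hot day-night comparison — days are sorted by maximum temperature
  and split into two equal-sized categories (warm/hot); the response is the
  arcsine-transformed proportion active per bear-day in the pooled day and
  night periods; the term of interest is the category x pool interaction.

Coefficient p-values are Wald normal-approximation tests from the REML fit
(the contract is the coefficient table; see docs/methods.md for how this
relates to denominator-degrees-of-freedom corrections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_formats import SEASONS

WEEKLY_RESPONSES = {
    "hours_active": "hours_active_per_day",
    "active_bout": "active_bout_h",
    "inactive_bout": "inactive_bout_h",
}


@dataclass
class ModelFit:
    """A fitted model reduced to its portable contract."""

    name: str
    coefficients: pd.DataFrame  # columns: term, estimate, se, pvalue
    random_effect_var: float | None
    n_obs: int
    n_groups: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> dict[str, float]:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if len(row) != 1:
            raise KeyError(
                f"term {term!r} not in model {self.name}: "
                f"{self.coefficients['term'].tolist()}"
            )
        r = row.iloc[0]
        return {"estimate": float(r["estimate"]), "se": float(r["se"]),
                "pvalue": float(r["pvalue"])}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "random_effect_var": self.random_effect_var,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "warnings": self.warnings,
        }


def arcsine_transform(p, variant: str = "sqrt"):
    """Variance-stabilizing arcsine transform of a proportion.

    ``variant='sqrt'`` (default, the standard ecological usage) returns
    arcsin(sqrt(p)); ``variant='plain'`` returns arcsin(p).  Input must lie
    in [0, 1]; output is in radians.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if variant == "sqrt":
        out = np.arcsin(np.sqrt(arr))
    elif variant == "plain":
        out = np.arcsin(arr)
    else:
        raise ValueError(f"unknown arcsine variant {variant!r}")
    return float(out) if np.isscalar(p) else out


def _order_categories(df: pd.DataFrame) -> pd.DataFrame:
    """Fix reference levels: herb_bulb for season, F for sex, day for period."""
    df = df.copy()
    if "season" in df:
        present = [s for s in SEASONS if s in set(df["season"])]
        df["season"] = pd.Categorical(df["season"], categories=present)
    if "sex" in df:
        df["sex"] = pd.Categorical(df["sex"], categories=["F", "M"])
    if "period" in df:
        from .solar_time import PERIODS
        order = ["day"] + [p for p in PERIODS if p != "day"]
        present = [p for p in order if p in set(df["period"])]
        df["period"] = pd.Categorical(df["period"], categories=present)
    return df


def _mixedlm(name: str, formula: str, data: pd.DataFrame, groups: str) -> ModelFit:
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=data, groups=data[groups])
        fit = model.fit(reml=True)
        for w in caught:
            if issubclass(w.category, (sm.tools.sm_exceptions.ConvergenceWarning, UserWarning)):
                warns.append(str(w.message))
    fe = fit.fe_params
    coefs = pd.DataFrame({
        "term": fe.index,
        "estimate": fe.to_numpy(),
        "se": fit.bse_fe.to_numpy(),
        "pvalue": fit.pvalues[fe.index].to_numpy(),
    })
    return ModelFit(
        name=name,
        coefficients=coefs.reset_index(drop=True),
        random_effect_var=float(np.asarray(fit.cov_re)[0, 0]),
        n_obs=int(fit.nobs),
        n_groups=len(data[groups].unique()),
        converged=bool(fit.converged),
        warnings=warns,
    )


def fit_weekly_lmm(weekly: pd.DataFrame, response: str = "hours_active") -> ModelFit:
    """Weekly LMM: response ~ daylight + sex + season + sex:season, random
    intercept per bear.

    ``response`` is one of ``hours_active``, ``active_bout``,
    ``inactive_bout``.  Reference levels are female and herb-bulb, so the
    ``season[T.berry]`` coefficient is the berry-vs-herb-bulb contrast.
    """
    col = WEEKLY_RESPONSES[response]
    data = _order_categories(weekly.dropna(subset=[col]))
    if data["bear_id"].nunique() < 2 or data["season"].nunique() < 2:
        raise ValueError("weekly LMM needs >= 2 bears and >= 2 seasons")
    one_sex = data["sex"].nunique() < 2
    rhs = "daylight_civil_hours + season" if one_sex else \
        "daylight_civil_hours + sex + season + sex:season"
    return _mixedlm(f"weekly_{response}", f"{col} ~ {rhs}", data, "bear_id")


def fit_period_lmm(period_table: pd.DataFrame, variant: str = "sqrt") -> ModelFit:
    """Period x season LMM on arcsine proportions, random intercept per bear."""
    data = _order_categories(period_table)
    data["asin_p"] = arcsine_transform(data["proportion_active"].to_numpy(), variant)
    one_sex = data["sex"].nunique() < 2 if "sex" in data else True
    rhs = "period + season + period:season" if one_sex else \
        "period + season + sex + period:season"
    return _mixedlm("period_season", f"asin_p ~ {rhs}", data, "bear_id")


def temperature_regression(day_records: pd.DataFrame, variant: str = "sqrt") -> dict[str, float]:
    """OLS of arcsine daily activity proportion on daily maximum temperature.

    ``day_records`` has one row per bear-day with ``tmax_c`` and
    ``proportion_active_24h``.  Returns slope, r-squared and the slope's
    p-value.
    """
    y = arcsine_transform(day_records["proportion_active_24h"].to_numpy(), variant)
    if np.ptp(y) == 0.0:  # constant response: no relationship by definition
        return {"slope": 0.0, "r_squared": 0.0, "p_value": 1.0}
    X = sm.add_constant(day_records["tmax_c"].to_numpy())
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "r_squared": float(fit.rsquared),
        "p_value": float(fit.pvalues[1]),
    }


def split_warm_hot(day_records: pd.DataFrame, on_odd: str = "error") -> pd.DataFrame:
    """Median split of days into equal-sized warm and hot categories.

    Distinct days are sorted by ``tmax_c`` (ties by date) and halved.  An
    odd number of days cannot split equally: ``on_odd='error'`` (default)
    raises; ``on_odd='drop_median'`` drops the middle day.  The category is
    then joined back onto the bear-day records.
    """
    days = (
        day_records[["date", "tmax_c"]].drop_duplicates("date")
        .sort_values(["tmax_c", "date"], kind="stable").reset_index(drop=True)
    )
    n = len(days)
    if n % 2 == 1:
        if on_odd == "drop_median":
            days = days.drop(index=n // 2).reset_index(drop=True)
            n -= 1
        else:
            raise ValueError(
                f"{n} distinct days cannot split into equal warm/hot halves; "
                "pass on_odd='drop_median' to resolve"
            )
    days["category"] = np.where(np.arange(n) < n // 2, "warm", "hot")
    out = day_records.merge(days[["date", "category"]], on="date", how="inner")
    return out


def warm_hot_comparison(pool_records: pd.DataFrame, variant: str = "sqrt") -> ModelFit:
    """Category x day/night-pool LMM for the hot-weather hypothesis.

    ``pool_records`` has one row per bear x day x pooled period with
    ``category`` ('warm'/'hot'), ``pool`` ('day_pooled'/'night_pooled') and
    ``proportion_active``.  The reported term of interest is the
    category:pool interaction.
    """
    data = pool_records.copy()
    data["category"] = pd.Categorical(data["category"], categories=["warm", "hot"])
    data["pool"] = pd.Categorical(data["pool"], categories=["day_pooled", "night_pooled"])
    data["asin_p"] = arcsine_transform(data["proportion_active"].to_numpy(), variant)
    return _mixedlm("warm_hot", "asin_p ~ category * pool", data, "bear_id")


WARM_HOT_INTERACTION = "category[T.hot]:pool[T.night_pooled]"
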