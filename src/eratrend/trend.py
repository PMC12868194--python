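"""Genetic trend: regression of genotype value on year of release.

The realized genetic trend is the slope of

    g_i = gamma + beta * a_i + tau_i

where g_i is the genotype's estimated genetic value (stage-2 prediction on
the yield scale, t/ha), a_i its calendar year of release and tau_i the
deviation from the trend line. beta (t/ha per year; x1000 for kg/ha/yr) is
the headline genetic-gain figure; it is also expressed as a percentage of
the predicted baseline yield:

    %gg(a1)   = beta / (gamma + beta * a1)            * 100
    %gg(mean) = beta / (gamma + beta * (a1 + an) / 2) * 100

i.e. the annual gain relative to the trend's prediction at the first
release year and at the midpoint of the release window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError


@dataclass
class TrendResult:
    """OLS genetic-trend fit with the percentage-gain summaries."""

    gamma: float            # intercept, t/ha
    beta: float             # slope, t/ha per year
    se_gamma: float
    se_beta: float
    r2: float
    residuals: pd.Series    # tau_i, t/ha
    a1: int                 # first release year in the data
    an: int                 # last release year in the data
    n: int
    gg_first: float = np.nan   # % per year at a1
    gg_mean: float = np.nan    # % per year at the midpoint
    beta_ci: tuple[float, float] = (np.nan, np.nan)
    gg_first_range: tuple[float, float] = (np.nan, np.nan)
    gg_mean_range: tuple[float, float] = (np.nan, np.nan)
    ci_level: float = 0.95
    fitted: pd.Series | None = field(default=None, repr=False)

    @property
    def beta_kg_ha_yr(self) -> float:
        return self.beta * 1000.0

    def summary_row(self, label: str = "") -> dict:
        return {
            "label": label,
            "gamma": self.gamma,
            "se_gamma": self.se_gamma,
            "beta_t_ha_yr": self.beta,
            "beta_kg_ha_yr": self.beta_kg_ha_yr,
            "se_beta": self.se_beta,
            "r2": self.r2,
            "a1": self.a1,
            "an": self.an,
            "gg_first_pct": self.gg_first,
            "gg_first_lo": self.gg_first_range[0],
            "gg_first_hi": self.gg_first_range[1],
            "gg_mean_pct": self.gg_mean,
            "gg_mean_lo": self.gg_mean_range[0],
            "gg_mean_hi": self.gg_mean_range[1],
        }


def percent_genetic_gain(gamma: float, beta: float, a1: float, an: float):
    """The two percentage-gain summaries (% per year).

    Raises when a predicted baseline yield (the denominator) is not positive,
    since a percentage of a non-positive yield is meaningless. Both values
    are invariant to a joint rescaling of gamma and beta (t/ha vs kg/ha).
    """
    if a1 > an:
        raise ValueError("a1 must be <= an")
    denom_first = gamma + beta * a1
    denom_mean = gamma + beta * (a1 + an) / 2.0
    if denom_first <= 0 or denom_mean <= 0:
        raise DegenerateDataError(
            f"undefined gain: predicted baseline yield non-positive "
            f"({denom_first:.4g} at a1, {denom_mean:.4g} at midpoint)"
        )
    return 100.0 * beta / denom_first, 100.0 * beta / denom_mean


def fit_genetic_trend(
    values,
    years,
    weights=None,
    a1: int | None = None,
    an: int | None = None,
    ci_level: float = 0.95,
) -> TrendResult:
    """OLS (optionally inverse-variance weighted) fit of value on release year.

    ``values``/``years`` are aligned per-genotype arrays or Series; ``weights``
    (if given) are 1/SE^2-style regression weights on the predictions. a1/an
    default to the earliest/latest release years present.
    """
    values = pd.Series(values).astype(float)
    years_arr = np.asarray(pd.Series(years).astype(float))
    if len(values) < 3:
        raise DegenerateDataError("genetic trend needs >= 3 genotypes")
    if len(np.unique(years_arr)) < 2:
        raise DegenerateDataError("all release years identical: slope inestimable")

    X = sm.add_constant(years_arr)
    model = sm.WLS(values.to_numpy(), X, weights=weights) if weights is not None \
        else sm.OLS(values.to_numpy(), X)
    fit = model.fit()
    gamma, beta = fit.params
    se_gamma, se_beta = fit.bse
    a1 = int(a1 if a1 is not None else years_arr.min())
    an = int(an if an is not None else years_arr.max())

    result = TrendResult(
        gamma=float(gamma),
        beta=float(beta),
        se_gamma=float(se_gamma),
        se_beta=float(se_beta),
        r2=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        residuals=pd.Series(fit.resid, index=values.index, name="tau"),
        a1=a1,
        an=an,
        n=len(values),
        ci_level=ci_level,
        fitted=pd.Series(fit.fittedvalues, index=values.index, name="fitted"),
    )
    try:
        result.gg_first, result.gg_mean = percent_genetic_gain(gamma, beta, a1, an)
    except DegenerateDataError:
        pass  # non-positive baseline: gains stay NaN
    return trend_uncertainty(result, level=ci_level)


def trend_uncertainty(result: TrendResult, level: float = 0.95) -> TrendResult:
    """Wald t-interval for beta; gain ranges by endpoint propagation.

    The %gg ranges scale the two ends of the beta interval by the predicted
    baseline yield at the point estimate (gamma-hat + beta-hat * year):
    gg_endpoint = 100 * beta_endpoint / baseline. Holding the baseline at the
    point estimate keeps the range monotone in beta and bracketing the point
    estimate (re-evaluating the baseline at each endpoint does neither, since
    d gg / d beta changes sign with gamma). Ranges are NaN when the baseline
    itself is non-positive.
    """
    dof = result.n - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof) if dof > 0 else np.nan
    half = tcrit * result.se_beta
    lo, hi = result.beta - half, result.beta + half
    result.beta_ci = (float(lo), float(hi))
    result.ci_level = level

    denom_first = result.gamma + result.beta * result.a1
    denom_mean = result.gamma + result.beta * (result.a1 + result.an) / 2.0
    if denom_first > 0:
        result.gg_first_range = (100.0 * lo / denom_first, 100.0 * hi / denom_first)
    else:
        result.gg_first_range = (np.nan, np.nan)
    if denom_mean > 0:
        result.gg_mean_range = (100.0 * lo / denom_mean, 100.0 * hi / denom_mean)
    else:
        result.gg_mean_range = (np.nan, np.nan)
    return result


def trend_table(result: TrendResult, label: str = "") -> pd.DataFrame:
    """One-row summary table (intercept, slope, gains with ranges)."""
    return pd.DataFrame([result.summary_row(label)])


def genotype_trend_points(values, years) -> pd.DataFrame:
    """Per-genotype (release year, predicted value) table backing trend plots."""
    values = pd.Series(values)
    years = pd.Series(years)
    return pd.DataFrame(
        {"genotype": values.index, "release_year": years.loc[values.index].to_numpy(),
         "predicted_value": values.to_numpy()}
    )
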