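"""Deployment body-mass anomalies by sex and year.

Mass at logger deployment is expressed as an anomaly from the per-sex overall
mean; annual deviations are tested per sex with a Gaussian linear model of the
anomaly on year indicators with the intercept forced to zero, so each year's
coefficient IS that year's mean anomaly, with a two-sided Wald test against 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["mass_anomaly", "fit_year_model"]


def mass_anomaly(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record anomaly (g) and per-sex-per-year percent anomaly.

    anomaly = mass - per-sex overall (pooled-record) mean;
    percent anomaly = 100 (year mean - overall mean) / overall mean.
    A sex with no records is skipped with a warning.
    """
    if (records["mass_g"] <= 0).any():
        raise ValueError("masses must be positive")
    out = records.copy()
    out["anomaly_g"] = np.nan
    rows = []
    for sex in ("F", "M"):
        sub = records[records["sex"] == sex]
        if sub.empty:
            logger.warning("no records for sex %s: skipped", sex)
            continue
        overall = sub["mass_g"].mean()
        out.loc[sub.index, "anomaly_g"] = sub["mass_g"] - overall
        for year, grp in sub.groupby("year"):
            rows.append({
                "sex": sex, "year": int(year), "n": len(grp),
                "mean_anomaly_g": float(grp["mass_g"].mean() - overall),
                "percent_anomaly": float(
                    100.0 * (grp["mass_g"].mean() - overall) / overall),
            })
    summary = pd.DataFrame(rows)
    return out, summary


def fit_year_model(anomalies: pd.DataFrame, sex: str | None = None
                   ) -> pd.DataFrame:
    """Per-year coefficient, SE and p-value from the no-intercept year model.

    With the indicator design each coefficient equals that year's sample mean
    anomaly.  Years with a single record get a flag (their SE rests entirely
    on the pooled residual variance).
    """
    df = anomalies if sex is None else anomalies[anomalies["sex"] == sex]
    years = np.sort(df["year"].unique())
    if years.size < 2:
        raise ValueError("need at least 2 years")
    X = pd.get_dummies(df["year"].astype(int), dtype=float)[list(map(int, years))]
    fit = sm.OLS(df["anomaly_g"].to_numpy(dtype=float), X.to_numpy()).fit()
    n_per = df.groupby("year").size().reindex(years).to_numpy()
    return pd.DataFrame({
        "year": years.astype(int),
        "coef_g": fit.params,
        "se_g": fit.bse,
        "p_value": fit.pvalues,
        "n": n_per,
        "single_record": n_per == 1,
    })
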