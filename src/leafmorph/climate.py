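"""Weather-window covariates and shape ~ climate models.

Daily station series are averaged per site, converted from the archive's
integer-tenths units, and summarized over three windows anchored on each
specimen's collection date:

* GS  — the growing season, the 6 calendar months up to and including the
  collection date;
* YL  — the 365 days before the collection date, whose mean temperature is
  (mean of the hottest calendar month + mean of the coldest calendar
  month) / 2;
* DOC — the collection date itself.

Each window yields average (AT), maximum (MAX), and minimum (MIN)
temperature in deg C and log-transformed precipitation AP = log1p(mean
daily inches).  Shape descriptors (circularity, aspect ratio) are then
regressed on the four covariates of each window, with and without the
climate-region categorical, plus temperature x precipitation interaction
variants, and the nine fits per descriptor are ranked by delta AIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ComparabilityError, CoverageError, ParameterError

__all__ = [
    "WindowSummary",
    "FitResult",
    "aggregate_stations",
    "convert_units",
    "summarize_window",
    "summarize_windows",
    "fit_models",
    "compare_aic",
    "cramers_v",
    "region_tests",
    "trend",
]

WEATHER_VARS = ("TAVG", "TMAX", "TMIN", "PRCP")
WINDOW_MODELS = ("GS", "YL", "DOC")


@dataclass(frozen=True)
class WindowSummary:
    """AT/MAX/MIN/AP covariates for one specimen and one time window."""

    id: str
    model: str  # GS | YL | DOC
    AT: float
    MAX: float
    MIN: float
    AP: float  # log1p of mean daily precipitation (inches)
    coverage: float  # fraction of window days with data


def aggregate_stations(station_series: pd.DataFrame, site: str) -> pd.DataFrame:
    """Average per-station daily series into one site series.

    For each date, each variable is the mean over the stations reporting it
    that day; a date missing from every station stays missing.
    """
    if station_series.empty:
        raise ParameterError("aggregate_stations: empty station table")
    cols = [c for c in WEATHER_VARS if c in station_series.columns]
    out = station_series.groupby("date", as_index=False)[cols].mean()
    out.insert(0, "site", site)
    return out


def convert_units(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert archive integer-tenths units to deg C and inches.

    Daily temperatures arrive as tenths of a degree Celsius and
    precipitation as tenths of an inch; both are divided by 10.  The
    precipitation log transform is applied later, at window-summary time.
    """
    out = raw.copy()
    for col in ("TAVG", "TMAX", "TMIN"):
        if col in out.columns:
            out[col] = out[col] / 10.0
    if "PRCP" in out.columns:
        out["PRCP"] = out["PRCP"] / 10.0
    return out


def _window_bounds(collection_date: pd.Timestamp, model: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    end = pd.Timestamp(collection_date)
    if model == "GS":
        start = end - pd.DateOffset(months=6)
    elif model == "YL":
        start = end - pd.Timedelta(days=365)
    elif model == "DOC":
        start = end
    else:
        raise ParameterError(f"unknown window model {model!r}; expected GS, YL or DOC")
    return start, end


def summarize_window(
    daily: pd.DataFrame,
    collection_date: Any,
    model: str,
    min_coverage: float = 0.5,
    specimen_id: str = "",
) -> WindowSummary:
    """Summarize one site's daily series over one window.

    ``daily`` must hold a single site's rows (columns date, TAVG, TMAX,
    TMIN, PRCP, already in deg C / inches).  Missing days are skipped; if
    the fraction of covered window days falls below ``min_coverage`` the
    summaries are returned as NaN with a warning.
    """
    end_date = pd.Timestamp(collection_date)
    start, end = _window_bounds(end_date, model)
    dates = pd.to_datetime(daily["date"])
    if end_date < dates.min() or end_date > dates.max():
        raise CoverageError(
            f"specimen {specimen_id!r}: collection date {end_date.date()} outside "
            f"the daily series ({dates.min().date()}..{dates.max().date()})"
        )
    mask = (dates >= start) & (dates <= end)
    win = daily.loc[mask].copy()
    win_dates = dates[mask]
    n_days = (end - start).days + 1
    covered = int(win["TAVG"].notna().sum())
    coverage = covered / n_days
    if coverage < min_coverage:
        warnings.warn(
            f"specimen {specimen_id!r}: {model} window coverage {coverage:.2f} below "
            f"{min_coverage}; summaries set to NaN",
            stacklevel=2,
        )
        return WindowSummary(specimen_id, model, np.nan, np.nan, np.nan, np.nan, coverage)
    if model == "YL":
        by_month = win["TAVG"].groupby(
            [win_dates.dt.year.values, win_dates.dt.month.values]
        ).mean()
        at = float((by_month.max() + by_month.min()) / 2.0)
    else:
        at = float(win["TAVG"].mean())
    return WindowSummary(
        id=specimen_id,
        model=model,
        AT=at,
        MAX=float(win["TMAX"].mean()),
        MIN=float(win["TMIN"].mean()),
        AP=float(np.log1p(win["PRCP"].mean())),
        coverage=coverage,
    )


def summarize_windows(
    weather: pd.DataFrame,
    specimens: pd.DataFrame,
    models: tuple[str, ...] = WINDOW_MODELS,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Wide per-specimen covariate table: AT_GS, MAX_GS, ..., AP_DOC.

    ``weather`` holds per-site daily rows (site, date, TAVG, TMAX, TMIN,
    PRCP); ``specimens`` must carry id and collection_date, with the site
    keyed by specimen id.
    """
    by_site = dict(tuple(weather.groupby("site")))
    rows = []
    for rec in specimens.itertuples(index=False):
        sid = rec.id
        if sid not in by_site:
            raise CoverageError(f"specimen {sid!r}: no weather series for its site")
        daily = by_site[sid]
        row: dict[str, Any] = {"id": sid}
        for model in models:
            ws = summarize_window(
                daily, rec.collection_date, model, min_coverage=min_coverage, specimen_id=sid
            )
            row.update(
                {
                    f"AT_{model}": ws.AT,
                    f"MAX_{model}": ws.MAX,
                    f"MIN_{model}": ws.MIN,
                    f"AP_{model}": ws.AP,
                    f"coverage_{model}": ws.coverage,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """One fitted shape ~ climate OLS model.

    ``aic`` counts every estimated parameter including the residual
    variance: AIC = 2k - 2 logLik with k = (mean parameters) + 1.
    """

    name: str
    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    llf: float
    aic: float
    rsquared: float
    delta_aic: float | None = None
    sm_result: Any = field(default=None, repr=False, compare=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.sm_result.conf_int(alpha=alpha)


def _model_formulas(response: str, window: str, with_region: bool, interaction: bool) -> str:
    terms = [f"AT_{window}", f"MAX_{window}", f"MIN_{window}", f"AP_{window}"]
    if with_region:
        terms.append("C(region)")
    if interaction:
        terms.append(f"AT_{window}:AP_{window}")
    return f"{response} ~ " + " + ".join(terms)


def _fit_one(name: str, formula: str, data: pd.DataFrame, response: str) -> FitResult:
    model = smf.ols(formula, data=data)
    k_mean = model.exog.shape[1]
    if data.shape[0] <= k_mean:
        raise ParameterError(
            f"model {name!r}: n={data.shape[0]} too small for {k_mean} mean parameters"
        )
    if np.linalg.matrix_rank(model.exog) < k_mean:
        raise ParameterError(
            f"model {name!r}: design matrix is rank deficient (collinear terms in {formula!r})"
        )
    res = model.fit()
    k = k_mean + 1  # + residual variance
    return FitResult(
        name=name,
        response=response,
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        n=int(res.nobs),
        llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        rsquared=float(res.rsquared),
        sm_result=res,
    )


def fit_models(
    descriptors: pd.DataFrame,
    summaries: pd.DataFrame,
    regions: pd.Series | None = None,
    responses: tuple[str, ...] = ("circularity", "aspect_ratio"),
    windows: tuple[str, ...] = WINDOW_MODELS,
) -> list[FitResult]:
    """Fit the full battery of shape ~ weather-window models.

    Per response: one additive model per window including the
    climate-region categorical, one interaction (AT x AP) variant per
    window, and the three additive models without the region term — nine
    fits, all on the same complete cases so their AICs are comparable.
    """
    data = descriptors.merge(summaries, on="id")
    if regions is not None:
        reg = regions.rename("region")
        reg.index.name = "id"
        data = data.merge(reg.reset_index(), on="id")
    elif "region" not in data.columns:
        raise ParameterError("fit_models: region labels required (pass regions=)")
    covars = [f"{v}_{w}" for v, w in itertools.product(("AT", "MAX", "MIN", "AP"), windows)]
    data = data.dropna(subset=[*covars, *[r for r in responses if r in data.columns]])
    if data["region"].nunique() < 2:
        raise ParameterError("fit_models: need >= 2 regions for the region term")
    fits: list[FitResult] = []
    for response in responses:
        for w in windows:
            fits.append(
                _fit_one(w, _model_formulas(response, w, True, False), data, response)
            )
        for w in windows:
            fits.append(
                _fit_one(f"IN{w}", _model_formulas(response, w, True, True), data, response)
            )
        for w in windows:
            fits.append(
                _fit_one(
                    f"{w}_noregion", _model_formulas(response, w, False, False), data, response
                )
            )
    return fits


def compare_aic(fits: list[FitResult]) -> pd.DataFrame:
    """Delta-AIC comparison table, sorted ascending (best model first)."""
    if len(fits) < 2:
        raise ComparabilityError("compare_aic needs >= 2 fits")
    if len({f.response for f in fits}) != 1:
        raise ComparabilityError("fits compare different responses")
    if len({f.n for f in fits}) != 1:
        raise ComparabilityError(
            f"fits use different case counts: {sorted({f.n for f in fits})}"
        )
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best
    rows = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "response": [f.response for f in fits],
            "n": [f.n for f in fits],
            "llf": [f.llf for f in fits],
            "AIC": [f.aic for f in fits],
            "delta_AIC": [f.delta_aic for f in fits],
        }
    )
    return rows.sort_values("delta_AIC", kind="stable").reset_index(drop=True)


def cramers_v(table: pd.DataFrame | np.ndarray) -> tuple[float, float, float]:
    """Pearson chi-squared test of association and Cramer's V.

    Returns ``(chi2, p, V)`` with V = sqrt(chi2 / (n * (min(r, c) - 1))).
    No continuity correction, matching the definition of V.
    """
    arr = np.asarray(table, dtype=float)
    chi2, p, _, _ = scipy.stats.chi2_contingency(arr, correction=False)
    n = arr.sum()
    r, c = arr.shape
    denom = n * (min(r, c) - 1)
    v = float(np.sqrt(chi2 / denom)) if denom > 0 else np.nan
    return float(chi2), float(p), v


def region_tests(
    descriptors: pd.DataFrame,
    type_table: pd.DataFrame | None = None,
    responses: tuple[str, ...] = ("circularity", "aspect_ratio"),
    t_test_alternative: str = "greater",
) -> dict[str, Any]:
    """Association and mean-difference tests of shape across climate regions.

    ``descriptors`` must carry a ``region`` column.  The report holds the
    chi-squared test + Cramer's V on the optional type x region table, a
    one-way ANOVA of each descriptor on region, Tukey HSD pairwise region
    contrasts, and per-region one-sided t-tests of the region mean against
    all other regions pooled.
    """
    report: dict[str, Any] = {"warnings": []}
    if type_table is not None:
        chi2, p, v = cramers_v(type_table)
        report["chi2"] = {"statistic": chi2, "p": p, "cramers_v": v}
    counts = descriptors.groupby("region").size()
    small = counts[counts < 2].index.tolist()
    if small:
        report["warnings"].append(f"regions excluded from ANOVA (n < 2): {small}")
    ok = descriptors[~descriptors["region"].isin(small)]
    for resp in responses:
        groups = [g[resp].dropna().values for _, g in ok.groupby("region")]
        if len(groups) < 2:
            raise ParameterError("region_tests: need >= 2 regions with n >= 2")
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups if len(g)}) <= 1:
            report[f"anova_{resp}"] = {"F": np.nan, "p": np.nan, "note": "zero variance"}
        else:
            F, p = scipy.stats.f_oneway(*groups)
            report[f"anova_{resp}"] = {"F": float(F), "p": float(p)}
        tuk = pairwise_tukeyhsd(ok[resp].values, ok["region"].values)
        report[f"tukey_{resp}"] = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        )
        tt = {}
        for region, g in ok.groupby("region"):
            rest = ok.loc[ok["region"] != region, resp].dropna()
            stat, pv = scipy.stats.ttest_ind(
                g[resp].dropna(), rest, alternative=t_test_alternative
            )
            tt[region] = {"t": float(stat), "p": float(pv)}
        report[f"ttests_{resp}"] = tt
    return report


def trend(
    descriptors: pd.DataFrame,
    responses: tuple[str, ...] = ("circularity", "aspect_ratio"),
    min_years: int = 3,
) -> pd.DataFrame:
    """Per-region and overall OLS trends of each descriptor on year.

    Groups with fewer than ``min_years`` distinct years are skipped with a
    warning.  Returns a table of slope, standard error, p-value and n.
    """
    rows = []
    groups: list[tuple[str, pd.DataFrame]] = [("overall", descriptors)]
    if "region" in descriptors.columns:
        groups += [(str(r), g) for r, g in descriptors.groupby("region")]
    for label, g in groups:
        if g["year"].nunique() < min_years:
            warnings.warn(
                f"trend: group {label!r} has < {min_years} distinct years; skipped",
                stacklevel=2,
            )
            continue
        for resp in responses:
            sub = g.dropna(subset=[resp, "year"])
            X = sm.add_constant(sub["year"].astype(float))
            res = sm.OLS(sub[resp], X).fit()
            rows.append(
                {
                    "group": label,
                    "response": resp,
                    "slope": float(res.params["year"]),
                    "se": float(res.bse["year"]),
                    "p": float(res.pvalues["year"]),
                    "n": int(res.nobs),
                }
            )
    return pd.DataFrame(rows)
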