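"""Climatic drivers and spatial/interannual driver statistics.

Vapour-pressure deficit from temperature and dewpoint (Tetens), the
max-VPD-month climatology, partial Spearman correlations between
drivers and fire-regime properties, linear regime models, Tukey HSD
group contrasts, per-cell interannual climate sensitivity, and annual
trend fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

# Tetens saturation vapour pressure constants (kPa, degC)
_TETENS_A = 0.61078
_TETENS_B = 17.27
_TETENS_C = 237.15


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure (kPa) at temperature ``t_c`` (degC), Tetens form."""
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -_TETENS_C):
        raise ValueError(f"temperature must exceed {-_TETENS_C} degC")
    return _TETENS_A * np.exp((_TETENS_B * t) / (_TETENS_C + t))


def vpd(t_c, td_c, clamp: bool = False):
    """Vapour-pressure deficit (kPa) from temperature and dewpoint (degC).

    VPD = SVP(T) - SVP(Td). With ``clamp=False`` a supersaturated input
    (Td > T) yields a negative value and a warning; with ``clamp=True``
    the result is floored at zero.
    """
    out = saturation_vapour_pressure(t_c) - saturation_vapour_pressure(td_c)
    if np.any(np.asarray(out) < 0):
        if clamp:
            out = np.clip(out, 0.0, None)
        else:
            warnings.warn("dewpoint exceeds temperature; negative VPD returned",
                          stacklevel=2)
    return out


def climatological_max_vpd(monthly_vpd: np.ndarray):
    """Mean VPD of each pixel's climatological maximum-VPD month.

    Parameters
    ----------
    monthly_vpd
        Array of shape (n_years, 12, ...) of monthly VPD fields (kPa).

    Returns
    -------
    (vpd_max_month, month_index)
        Per-pixel multi-year mean VPD of the month whose climatological
        (multi-year mean) VPD is highest, and that month's index (1-12).
        Month ties resolve to the earliest month. Pixels whose
        climatology is all-missing come back as NaN.
    """
    v = np.asarray(monthly_vpd, dtype=float)
    if v.ndim < 2 or v.shape[1] != 12:
        raise ValueError("monthly_vpd must have shape (n_years, 12, ...)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        clim = np.nanmean(v, axis=0)            # (12, ...)
    allnan = np.all(np.isnan(clim), axis=0)
    safe = np.where(np.isnan(clim), -np.inf, clim)
    month0 = np.argmax(safe, axis=0)            # earliest month wins ties
    out = np.take_along_axis(clim, month0[None, ...], axis=0)[0]
    out = np.where(allnan, np.nan, out)
    month = np.where(allnan, 0, month0 + 1)
    return out, month


def annual_max_month_vpd(monthly_vpd: np.ndarray) -> np.ndarray:
    """Per-year VPD of each pixel's climatological maximum-VPD month.

    The month is fixed from the multi-year climatology (as in
    :func:`climatological_max_vpd`); the returned array (n_years, ...)
    holds each individual year's VPD in that month, the quantity the
    interannual sensitivity analysis correlates with annual fire
    activity.
    """
    v = np.asarray(monthly_vpd, dtype=float)
    _, month = climatological_max_vpd(v)
    m0 = np.clip(month - 1, 0, 11)
    return np.take_along_axis(v, m0[None, None, ...], axis=1)[:, 0]


def lightning_climatology(monthly_lightning: np.ndarray) -> np.ndarray:
    """Multi-year mean lightning density over the extended fire season.

    Averages months March through October (inclusive) across all years;
    input shape (n_years, 12, ...).
    """
    v = np.asarray(monthly_lightning, dtype=float)
    if v.ndim < 2 or v.shape[1] != 12:
        raise ValueError("monthly_lightning must have shape (n_years, 12, ...)")
    return v[:, 2:10].mean(axis=(0, 1))


def wilderness_fraction(human_footprint: np.ndarray) -> float:
    """Fraction of pixels completely untouched by humans.

    Only pixels with a human-footprint score of exactly zero count as
    wilderness — a conservative reading of footprint maps.
    """
    hfp = np.asarray(human_footprint, dtype=float)
    valid = np.isfinite(hfp)
    if not valid.any():
        return float("nan")
    return float((hfp[valid] == 0).mean())


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial Spearman correlation with its two-sided p-value."""

    rho: float
    p: float
    n: int
    covariates: tuple = field(default_factory=tuple)


def partial_spearman(x, y, Z=None, covariate_names=None) -> PartialCorrResult:
    """Partial Spearman correlation of ``x`` and ``y`` controlling for ``Z``.

    All variables are rank-transformed (average ranks on ties); the
    statistic is the Pearson correlation of the residuals from
    least-squares regressions of ranked x and ranked y on the ranked
    covariates. With no covariates this reduces exactly to Spearman's
    rho. The two-sided p-value uses the t approximation with
    ``n - 2 - |Z|`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if Z is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > |Z| + 3 observations (n={n}, |Z|={k})")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name} is constant")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if k:
        rz = np.column_stack([stats.rankdata(Z[:, j]) for j in range(k)])
        design = np.column_stack([np.ones(n), rz])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("covariate matrix is singular (collinear covariates)")
        coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        ex = rx - design @ coef_x
        ey = ry - design @ coef_y
    else:
        ex = rx - rx.mean()
        ey = ry - ry.mean()
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        raise ValueError("residuals have zero variance after controlling for Z")
    rho = float((ex * ey).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    names = tuple(covariate_names) if covariate_names is not None else tuple(range(k))
    return PartialCorrResult(rho=rho, p=max(p, np.finfo(float).tiny), n=n,
                             covariates=names)


def driver_correlations(table: pd.DataFrame, drivers: list[str],
                        properties: list[str],
                        groups: pd.Series | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Partial Spearman matrix of drivers vs regime properties.

    For each (driver, property) pair and each pyroregion group plus the
    pooled domain (`group = "all"`), the correlation controls for all
    *other* drivers. Groups too small for the covariate count are
    skipped with a log entry.
    """
    rows = []
    if groups is None:
        groups = pd.Series("all", index=table.index)
    group_ids = ["all"] + sorted({g for g in groups.dropna().unique() if g != "all"})
    for gid in group_ids:
        sub = table if gid == "all" else table.loc[groups == gid]
        for prop in properties:
            for drv in drivers:
                others = [d for d in drivers if d != drv]
                cols = [drv, prop] + others
                data = sub[cols].dropna()
                if len(data) <= len(others) + 3:
                    log.info("group %s skipped for %s~%s: n=%d too small",
                             gid, prop, drv, len(data))
                    continue
                try:
                    res = partial_spearman(
                        data[drv], data[prop],
                        data[others].to_numpy() if others else None,
                        covariate_names=others,
                    )
                except ValueError as exc:
                    log.info("group %s skipped for %s~%s: %s", gid, prop, drv, exc)
                    continue
                rows.append({"group": gid, "driver": drv, "property": prop,
                             "rho": res.rho, "p": res.p, "n": res.n,
                             "significant": res.p < alpha})
    return pd.DataFrame(rows)


def fit_regime_models(table: pd.DataFrame, responses: list[str],
                      predictors: list[str]) -> pd.DataFrame:
    """OLS models of log10-transformed regime responses on driver predictors.

    Each response y is transformed to log10(y + eps) with eps equal to
    one tenth of the smallest positive observed value, so zero cells
    remain in the fit. Returns one row per response with R^2, n and the
    coefficient vector.
    """
    import statsmodels.api as sm

    rows = []
    for resp in responses:
        data = table[[resp] + predictors].dropna()
        n = len(data)
        if n < 10 * max(len(predictors), 1):
            raise ValueError(
                f"response {resp}: need >= {10 * len(predictors)} complete cases, got {n}")
        y = data[resp].to_numpy(dtype=float)
        if np.any(y < 0):
            raise ValueError(f"response {resp} has negative values")
        pos = y[y > 0]
        eps = pos.min() / 10.0 if pos.size else 1.0
        ylog = np.log10(y + eps)
        X = sm.add_constant(data[predictors].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for response {resp}")
        fit = sm.OLS(ylog, X).fit()
        row = {"response": resp, "r2": float(fit.rsquared), "n": n,
               "log_offset": eps, "intercept": float(fit.params[0])}
        for j, name in enumerate(predictors):
            row[f"coef_{name}"] = float(fit.params[j + 1])
            row[f"p_{name}"] = float(fit.pvalues[j + 1])
        rows.append(row)
    return pd.DataFrame(rows)


def tukey_hsd(values, groups) -> pd.DataFrame:
    """All pairwise group-mean contrasts with Tukey-HSD adjusted p-values.

    Uses the studentized-range procedure (Tukey-Kramer for unequal group
    sizes). Groups with fewer than two observations are excluded and
    logged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = []
    samples = []
    for g in pd.unique(groups):
        sample = values[(groups == g) & ~np.isnan(values)]
        if sample.size < 2:
            log.info("tukey_hsd: group %r excluded (n=%d < 2)", g, sample.size)
            continue
        labels.append(g)
        samples.append(sample)
    if len(samples) < 2:
        raise ValueError("need at least two groups with n >= 2")
    res = stats.tukey_hsd(*samples)
    ci = res.confidence_interval(0.95)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append({
                "group1": labels[i], "group2": labels[j],
                "diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
            })
    return pd.DataFrame(rows)


def interannual_sensitivity(annual: pd.DataFrame, groups: pd.Series,
                            properties: list[str] = ("burned_pct", "n_fires", "mean_size_km2"),
                            vpd_col: str = "vpd_max_month",
                            min_fires: int = 5,
                            min_years: int = 3) -> pd.DataFrame:
    """Per-pyroregion mean +/- sd of interannual Spearman correlations.

    ``annual`` holds one row per (cell_id, year) with annual regime
    properties and the annual max-month VPD. A cell qualifies when it
    accumulated at least ``min_fires`` fires in total and has at least
    ``min_years`` years with fire data. Per qualifying cell the Spearman
    correlation of each property with VPD is computed and then averaged
    within the cell's pyroregion.
    """
    rows = []
    per_cell = []
    for cid, sub in annual.groupby("cell_id"):
        sub = sub.dropna(subset=[vpd_col])
        n_fire_years = int((sub["n_fires"].fillna(0) > 0).sum())
        total_fires = float(sub["n_fires"].fillna(0).sum())
        if total_fires < min_fires or n_fire_years < min_years:
            continue
        rec = {"cell_id": cid}
        for prop in properties:
            data = sub[[prop, vpd_col]].dropna()
            if len(data) < min_years or data[prop].nunique() < 2 or data[vpd_col].nunique() < 2:
                rec[prop] = np.nan
                continue
            rec[prop] = stats.spearmanr(data[prop], data[vpd_col]).statistic
        per_cell.append(rec)
    if not per_cell:
        log.info("interannual_sensitivity: no qualifying cells")
        return pd.DataFrame(columns=["group", "property", "mean_rho", "sd_rho", "n_cells"])
    cell_df = pd.DataFrame(per_cell).set_index("cell_id")
    cell_groups = groups.reindex(cell_df.index)
    for gid in sorted(cell_groups.dropna().unique()):
        sub = cell_df.loc[cell_groups == gid]
        for prop in properties:
            vals = sub[prop].dropna()
            if vals.empty:
                log.info("interannual_sensitivity: group %r has no qualifying cells for %s",
                         gid, prop)
                continue
            rows.append({"group": gid, "property": prop,
                         "mean_rho": float(vals.mean()),
                         "sd_rho": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                         "n_cells": int(len(vals))})
    return pd.DataFrame(rows)


def annual_trend(series: pd.Series) -> tuple[float, float]:
    """OLS slope of an annual total on calendar year, with two-sided p.

    ``series`` is indexed by year. Returns (slope per year, p-value of
    the slope's t statistic).
    """
    years = np.asarray(series.index, dtype=float)
    vals = np.asarray(series.to_numpy(), dtype=float)
    if years.size < 3:
        raise ValueError("need at least 3 years")
    if np.ptp(years) == 0:
        raise ValueError("year vector is constant")
    res = stats.linregress(years, vals)
    return float(res.slope), float(res.pvalue)
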