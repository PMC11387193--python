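"""Pyroregion classification by Gaussian mixture modelling.

Grid cells with at least one fire are clustered in the space of the
six fire-regime properties with finite Gaussian mixtures fitted by
expectation-maximization over a range of component counts and
covariance families; the model is selected by the Bayesian information
criterion (reported in the maximized convention 2 ln L - p ln n, so
larger is better). Hard labels come from the posterior argmax and the
per-cell uncertainty is one minus the maximum posterior probability.

Clusters are named with a three-letter code: fire frequency
(Common if the fire return interval is under 500 years, else Rare),
fire size (Large above 40 km^2 mean size, else Small), and intensity
or seasonality (Intense at mean 95th-percentile FRP >= 100 W m^-2,
otherwise Early for mean start on or before 30 June, else Cool). The
intensity test takes precedence over the timing test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from borealfire.regime import REGIME_PROPERTIES, fri

log = logging.getLogger(__name__)

#: covariance families fitted by default; "full" realises the
#: variable-volume/shape/orientation family the selection favours on
#: elongated regime clusters
DEFAULT_FAMILIES = ("spherical", "diag", "full")

FRI_THRESHOLD_YR = 500.0
LARGE_FIRE_KM2 = 40.0
INTENSE_WM2 = 100.0
EARLY_START_DOY = 181          # 30 June in a non-leap year

_LONG = {"C": "common", "R": "rare", "L": "large", "S": "small",
         "I": "intense", "E": "early", "O": "cool"}


@dataclass
class PyroregionModel:
    """Fitted mixture with its BIC table, assignments and names."""

    bic_table: pd.DataFrame            # k, family, bic, loglik, n_params, converged
    k: int
    family: str
    gmm: GaussianMixture
    feature_names: list = field(default_factory=lambda: list(REGIME_PROPERTIES))
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None

    @property
    def means_(self) -> np.ndarray:
        """Component means on the original feature scale."""
        m = self.gmm.means_
        if self.scaler_mean is not None:
            m = m * self.scaler_scale + self.scaler_mean
        return m

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X


def build_features(regime_table: pd.DataFrame, min_fires: int = 1,
                   standardize: bool = True):
    """Feature matrix of regime properties for cells with fires.

    Returns (X, cell_ids, mean, scale); rows with any missing property
    are dropped. Standardization is recorded so assignments can be
    reproduced on raw features.
    """
    sub = regime_table.loc[regime_table["n_fires"] >= min_fires,
                           ["cell_id"] + REGIME_PROPERTIES].dropna()
    X = sub[REGIME_PROPERTIES].to_numpy(dtype=float)
    if standardize and len(X):
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    else:
        mean = scale = None
    return X, sub["cell_id"].to_numpy(), mean, scale


def fit_gmm_bic(X: np.ndarray, k_range=range(1, 10),
                families=DEFAULT_FAMILIES, n_init: int = 10,
                seed: int = 0, select_rule="max",
                feature_names=None) -> PyroregionModel:
    """Fit mixtures over (k, family) and select by BIC.

    Each fit uses k-means++ seeded EM with ``n_init`` restarts and a
    small covariance ridge against singularities. Degenerate or
    non-converged fits are recorded in the table but never selected.
    ``select_rule`` is passed to :func:`select_k`.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    kmax = max(k_range)
    if n <= kmax * 2:
        raise ValueError(f"need n > 2*k_max rows (n={n}, k_max={kmax})")
    reg = 1e-6 * float(np.mean(np.var(X, axis=0)) or 1.0)

    records = []
    fits = {}
    for k in k_range:
        for fam in families:
            gmm = GaussianMixture(
                n_components=k, covariance_type=fam, n_init=n_init,
                init_params="k-means++", random_state=seed, reg_covar=reg,
                max_iter=300,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gmm.fit(X)
                converged = bool(gmm.converged_)
                loglik = float(gmm.score(X) * n)
                p = int(gmm._n_parameters())
                bic = 2.0 * loglik - p * np.log(n)
                ok = converged and np.isfinite(bic)
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.warning("GMM fit failed for k=%d family=%s: %s", k, fam, exc)
                converged, loglik, p, bic, ok = False, np.nan, np.nan, np.nan, False
            records.append({"k": k, "family": fam, "bic": bic, "loglik": loglik,
                            "n_params": p, "converged": converged and ok})
            if converged and np.isfinite(bic):
                fits[(k, fam)] = gmm
    table = pd.DataFrame(records)
    usable = table.loc[table["converged"]]
    if usable.empty:
        raise ValueError("all mixture fits degenerate; no model selectable")
    for k in k_range:
        if not (usable["k"] == k).any():
            log.warning("all fits degenerate at k=%d; absent from BIC table", k)
    # best family per k, then the k-selection rule
    best_per_k = usable.loc[usable.groupby("k")["bic"].idxmax()].set_index("k")
    k_sel = select_k(best_per_k["bic"], select_rule)
    fam_sel = str(best_per_k.loc[k_sel, "family"])
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(d)]
    return PyroregionModel(bic_table=table, k=int(k_sel), family=fam_sel,
                           gmm=fits[(int(k_sel), fam_sel)], feature_names=names)


def select_k(bic_by_k: pd.Series, rule="max") -> int:
    """Choose the component count from a BIC-vs-k series.

    Rules: ``"max"`` takes the argmax; ``("elbow", eps)`` stops before
    the first k whose gain over k-1 falls below ``eps`` times the BIC
    range (the flat part of the curve adds no structure); ``("fixed", k)``
    pins the count regardless of the table.
    """
    if len(bic_by_k) == 0:
        raise ValueError("empty BIC table")
    ks = np.asarray(bic_by_k.index, dtype=int)
    order = np.argsort(ks)
    ks = ks[order]
    bic = np.asarray(bic_by_k.to_numpy(), dtype=float)[order]
    if rule == "max":
        return int(ks[np.argmax(bic)])
    if isinstance(rule, tuple) and rule[0] == "fixed":
        return int(rule[1])
    if isinstance(rule, tuple) and rule[0] == "elbow":
        eps = float(rule[1])
        rng = float(bic.max() - bic.min())
        gains = np.diff(bic)
        small = np.nonzero(gains < eps * max(rng, np.finfo(float).tiny))[0]
        if small.size == 0:
            return int(ks[-1])
        first = small[0]
        if not np.all(gains[:first] >= eps * rng):
            log.info("non-monotone BIC gains; choosing smallest qualifying k")
        return int(ks[first])          # the k before the first negligible gain
    raise ValueError(f"unknown k-selection rule {rule!r}")


def assign_clusters(model: PyroregionModel, X: np.ndarray,
                    cell_ids=None) -> pd.DataFrame:
    """Hard labels and uncertainties for feature rows.

    Rows with missing values are flagged ``label = -1`` and carry NaN
    uncertainty. Uncertainty is 1 - max posterior, in [0, 1 - 1/k].
    """
    X = np.asarray(X, dtype=float)
    ok = np.all(np.isfinite(X), axis=1)
    n, k = len(X), model.k
    post = np.full((n, k), np.nan)
    if ok.any():
        post[ok] = model.gmm.predict_proba(model.transform(X[ok])
                                           if model.scaler_mean is not None else X[ok])
    filled = np.where(np.isnan(post), -1.0, post)
    label = np.where(ok, np.argmax(filled, axis=1), -1)
    unc = np.where(ok, 1.0 - np.max(filled, axis=1), np.nan)
    out = pd.DataFrame({"label": label.astype(int), "uncertainty": unc})
    for j in range(k):
        out[f"p_{j + 1}"] = post[:, j]
    if cell_ids is not None:
        out.insert(0, "cell_id", np.asarray(cell_ids))
    return out


def name_pyroregion(stats: dict) -> tuple[str, str]:
    """Three-letter pyroregion code from cluster-mean regime properties.

    ``stats`` must provide ``burned_pct_yr``, ``mean_size_km2``,
    ``mean_frp95_wm2`` and ``mean_start_doy``.
    """
    for key in ("burned_pct_yr", "mean_size_km2", "mean_frp95_wm2",
                "mean_start_doy"):
        if key not in stats or stats[key] is None or not np.isfinite(stats[key]):
            raise ValueError(f"missing cluster statistic {key!r}")
    letter1 = "C" if fri(stats["burned_pct_yr"]) < FRI_THRESHOLD_YR else "R"
    letter2 = "L" if stats["mean_size_km2"] > LARGE_FIRE_KM2 else "S"
    if stats["mean_frp95_wm2"] >= INTENSE_WM2:
        letter3 = "I"
    elif stats["mean_start_doy"] <= EARLY_START_DOY:
        letter3 = "E"
    else:
        letter3 = "O"          # internal key for "cool"
    code = letter1 + letter2 + ("C" if letter3 == "O" else letter3)
    long_name = "-".join((_LONG[letter1], _LONG[letter2], _LONG[letter3]))
    return code, long_name


def name_clusters(model: PyroregionModel, regime_table: pd.DataFrame,
                  assignments: pd.DataFrame) -> pd.DataFrame:
    """Name every cluster from the mean regime properties of its cells."""
    merged = assignments.merge(regime_table, on="cell_id", how="left")
    rows = []
    for lbl, sub in merged.loc[merged["label"] >= 0].groupby("label"):
        stats = {p: float(sub[p].mean()) for p in REGIME_PROPERTIES}
        code, long_name = name_pyroregion(stats)
        rows.append({"label": int(lbl), "code": code, "name": long_name,
                     "n_cells": int(len(sub)), **stats})
    return pd.DataFrame(rows)
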