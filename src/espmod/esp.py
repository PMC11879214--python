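"""Per-window effect-size profiles (ESPs).

Within each retained window the association between every exposure and the
outcome is summarised by a univariate effect size, optionally adjusted for
confounders: the OLS slope for a continuous outcome, the odds ratio e^beta
from logistic regression for a binary one.  Stacking the window profiles
gives the Nw x M ESP matrix; standardizing each exposure's effect size across
windows yields the dimensionless feature space in which windows are
clustered.

Tiny windows make logistic separation routine, and unpenalized maximum
likelihood then sends slopes to infinity, turning single windows into wild
outliers on the odds-ratio scale.  Window logistic fits therefore apply a
weak L2 penalty on the slope (``ridge``, default 1.0 — the conventional
default strength of regularized logistic classifiers), the same in every
window so effect sizes stay comparable; fits that still fail are retried
with a stronger penalty and slopes are finally clamped to |beta| <= 10.
Exposures
that fail in more than 20% of windows are dropped; isolated failures are
filled with the exposure's across-window mean raw effect so the matrix stays
complete for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glm import linear_fit, linear_slopes, logistic_fit, logistic_profile
from .cover import CoverGeometry
from .preprocess import ObservationTable

__all__ = [
    "EffectSize",
    "ESPMatrix",
    "WindowEffectProfiler",
    "fit_window_effect",
    "build_esp_matrix",
    "standardize_esp",
]

_BETA_CLAMP = 10.0
_MAX_FAIL_FRACTION = 0.20


@dataclass(frozen=True)
class EffectSize:
    """A single window-level effect size (slope or odds ratio)."""

    exposure: str
    window: int
    raw: float
    converged: bool = True


@dataclass
class ESPMatrix:
    """Window-by-exposure effect sizes, raw and standardized.

    ``raw`` holds E_m per window (slope / odds ratio); ``standardized`` holds
    e_m = (E_m - mean_l E_m) / sd_l E_m per exposure across windows, the
    clustering feature space.  Exposures dropped for zero variance or
    excessive fit failures are listed in ``dropped_exposures``.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame | None = None
    dropped_exposures: list[str] = field(default_factory=list)
    fit_failures: dict[str, int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.raw)

    def values(self) -> np.ndarray:
        if self.standardized is None:
            raise ValueError("ESP matrix is not standardized yet")
        return self.standardized.to_numpy(dtype=float)


def _confounder_matrix(
    table: ObservationTable, confounders, idx: np.ndarray
) -> np.ndarray | None:
    """Resolve the confounder design block for a window (may be rank-reduced)."""
    if confounders is None:
        return None
    if confounders == "covariates":
        cols = list(table.roles.continuous_covariates)
    else:
        cols = list(confounders)
    if not cols:
        return None
    C = table.data.iloc[idx][cols].to_numpy(dtype=float)
    # drop constant columns (no within-window variation -> collinear with intercept)
    keep = C.std(axis=0) > 0
    C = C[:, keep]
    return C if C.shape[1] else None


def fit_window_effect(
    table: ObservationTable,
    cover: CoverGeometry,
    window: int,
    exposure: str,
    confounders=None,
    ridge: float = 1.0,
) -> EffectSize:
    """Effect size of one exposure within one window.

    Continuous outcome: OLS slope of Y on X_m (plus confounders).  Binary
    outcome: odds ratio e^beta_m from logistic regression.
    """
    idx = cover.windows[window].member_idx
    y = table.outcome()[idx]
    x = table.data.iloc[idx][exposure].to_numpy(dtype=float)
    C = _confounder_matrix(table, confounders, idx)
    D = np.column_stack([np.ones_like(x), x] if C is None else [np.ones_like(x), x, C])
    if table.roles.outcome_family == "continuous":
        beta = linear_fit(y, D)
        return EffectSize(exposure=exposure, window=window, raw=float(beta[1]))
    beta, ok = logistic_fit(y, D, ridge=ridge)
    if not ok or abs(beta[1]) > _BETA_CLAMP:
        beta, ok = logistic_fit(y, D, ridge=max(1.0, ridge, 1e-4 * len(y)))
    b = float(np.clip(beta[1], -_BETA_CLAMP, _BETA_CLAMP))
    return EffectSize(exposure=exposure, window=window, raw=float(np.exp(b)), converged=bool(ok))


def _window_profile_binary(y, X, ridge=1.0):
    """Odds ratios for all exposures of one window (vectorised)."""
    b0, b1, ok = logistic_profile(y, X, ridge=ridge)
    bad = ~ok | (np.abs(b1) > _BETA_CLAMP)
    if bad.any():
        _, b1r, okr = logistic_profile(y, X[:, bad], ridge=max(1.0, ridge, 1e-4 * len(y)))
        b1 = b1.copy()
        b1[bad] = b1r
        ok = ok.copy()
        ok[bad] = okr
    b1 = np.clip(b1, -_BETA_CLAMP, _BETA_CLAMP)
    return np.exp(b1), ok


def build_esp_matrix(
    cover: CoverGeometry,
    table: ObservationTable,
    confounders=None,
    ridge: float = 1.0,
) -> ESPMatrix:
    """Raw ESP matrix: one row per retained window, one column per exposure.

    ``confounders`` is None (unadjusted, the validation-study setting),
    ``"covariates"`` (adjust for the continuous modifiers inside each window)
    or an explicit list of column names.
    """
    if cover.n_retained == 0:
        raise ValueError("cover is empty")
    exposures = list(table.roles.exposure_cols)
    binary = table.roles.outcome_family == "binary"
    y_all = table.outcome()
    X_all = table.data[exposures].to_numpy(dtype=float)
    rows = np.empty((cover.n_retained, len(exposures)))
    failed = np.zeros_like(rows, dtype=bool)
    for l, w in enumerate(cover.windows):
        idx = w.member_idx
        y, X = y_all[idx], X_all[idx]
        C = _confounder_matrix(table, confounders, idx)
        if binary:
            if C is None:
                em, ok = _window_profile_binary(y, X, ridge=ridge)
            else:
                em = np.empty(len(exposures))
                ok = np.ones(len(exposures), dtype=bool)
                for m in range(len(exposures)):
                    D = np.column_stack([np.ones_like(y), X[:, m], C])
                    beta, conv = logistic_fit(y, D, ridge=ridge)
                    if not conv or abs(beta[1]) > _BETA_CLAMP:
                        beta, conv = logistic_fit(y, D, ridge=max(1.0, ridge, 1e-4 * len(y)))
                    em[m] = np.exp(np.clip(beta[1], -_BETA_CLAMP, _BETA_CLAMP))
                    ok[m] = conv
        else:
            if C is None:
                em = linear_slopes(y, X)
            else:
                em = np.empty(len(exposures))
                for m in range(len(exposures)):
                    D = np.column_stack([np.ones_like(y), X[:, m], C])
                    em[m] = linear_fit(y, D)[1]
            ok = np.isfinite(em)
        rows[l] = em
        failed[l] = ~ok | ~np.isfinite(em)

    raw = pd.DataFrame(rows, columns=exposures)
    raw.index.name = "window"
    fail_frac = failed.mean(axis=0)
    drop = [exposures[m] for m in range(len(exposures)) if fail_frac[m] > _MAX_FAIL_FRACTION]
    fit_failures = {
        exposures[m]: int(failed[:, m].sum())
        for m in range(len(exposures))
        if failed[:, m].any()
    }
    # isolated failures: fill with the exposure's mean raw effect over good windows
    for m, name in enumerate(exposures):
        if name in drop or not failed[:, m].any():
            continue
        good = ~failed[:, m]
        raw.loc[failed[:, m], name] = rows[good, m].mean()
    raw = raw.drop(columns=drop)
    return ESPMatrix(raw=raw, dropped_exposures=drop, fit_failures=fit_failures)


def standardize_esp(esp: ESPMatrix) -> ESPMatrix:
    """Standardize each exposure's effect sizes across windows (sample SD).

    Zero-variance exposures carry no clustering information and are dropped
    (recorded in ``dropped_exposures``).  Idempotent on already-standardized
    matrices.
    """
    if esp.n_windows < 2:
        raise ValueError("standardization needs at least 2 windows")
    raw = esp.raw
    sd = raw.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all exposure effect sizes have zero variance across windows")
    std = (raw.loc[:, keep] - raw.loc[:, keep].mean(axis=0)) / sd[keep]
    dropped = esp.dropped_exposures + [c for c in raw.columns if not keep[c]]
    return ESPMatrix(
        raw=raw,
        standardized=std,
        dropped_exposures=dropped,
        fit_failures=esp.fit_failures,
    )


class WindowEffectProfiler(BaseEstimator):
    """Estimate the standardized ESP matrix over a window cover.

    Parameters
    ----------
    confounders : None, "covariates" or list of str, default None
        Confounder adjustment applied inside every window.
    log_odds : bool, default True
        For binary outcomes, standardize log odds ratios rather than odds
        ratios.  The log scale is symmetric and keeps single extreme windows
        from dominating the standardized feature space; set False to cluster
        raw odds ratios.
    ridge : float, default 1.0
        L2 penalty on the slope of every window logistic fit (0 = plain
        maximum likelihood).

    Attributes
    ----------
    esp_ : ESPMatrix with both raw and standardized matrices.
    """

    def __init__(self, confounders=None, log_odds: bool = True, ridge: float = 1.0):
        self.confounders = confounders
        self.log_odds = log_odds
        self.ridge = ridge

    def fit(self, table: ObservationTable, cover: CoverGeometry) -> "WindowEffectProfiler":
        esp = build_esp_matrix(cover, table, confounders=self.confounders, ridge=self.ridge)
        if self.log_odds and table.roles.outcome_family == "binary":
            esp = ESPMatrix(
                raw=np.log(esp.raw),
                dropped_exposures=esp.dropped_exposures,
                fit_failures=esp.fit_failures,
            )
        self.esp_ = standardize_esp(esp)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "esp_"):
            raise ValueError("profiler is not fitted")
        return self.esp_.standardized
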