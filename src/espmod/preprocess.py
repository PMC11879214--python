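"""Input table handling: column roles, missingness filters, imputation, transforms.

The pipeline expects a rectangular table of observations with declared column
roles: one outcome (continuous or binary), M omics exposures, J modifier
covariates (continuous and/or discrete) and optional confounders.  Exposure
columns are filtered for missingness (columns first, then rows), remaining
gaps are imputed with k nearest neighbours, and exposures are optionally
log(1+x)-transformed and standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

__all__ = [
    "ColumnRoles",
    "ObservationTable",
    "ExposurePreprocessor",
    "filter_missingness",
    "impute_knn",
    "transform_exposures",
]


@dataclass(frozen=True)
class ColumnRoles:
    """Declares which column plays which role in an observations table.

    Parameters
    ----------
    outcome_col : str
        Name of the outcome column Y.
    outcome_family : {"continuous", "binary"}
        Determines the per-window effect-size model (linear slope vs odds
        ratio from logistic regression).
    exposure_cols : list of str
        Omics exposure columns X_1..X_M (M >= 1).
    covariate_cols : list of str
        Modifier covariates Z_1..Z_J (J >= 1).
    discrete_covariates : list of str
        Subset of ``covariate_cols`` to treat as discrete (stratified
        exhaustively rather than covered by gliding windows).
    confounder_cols : list of str
        Confounders adjusted for inside each window.  May overlap with
        ``covariate_cols``; a covariate can confound and modify at once.
    """

    outcome_col: str
    outcome_family: str
    exposure_cols: tuple[str, ...]
    covariate_cols: tuple[str, ...]
    discrete_covariates: tuple[str, ...] = ()
    confounder_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposure_cols", tuple(self.exposure_cols))
        object.__setattr__(self, "covariate_cols", tuple(self.covariate_cols))
        object.__setattr__(self, "discrete_covariates", tuple(self.discrete_covariates))
        object.__setattr__(self, "confounder_cols", tuple(self.confounder_cols))
        if self.outcome_family not in ("continuous", "binary"):
            raise ValueError(
                f"outcome_family must be 'continuous' or 'binary', got {self.outcome_family!r}"
            )
        if len(self.exposure_cols) < 1:
            raise ValueError("at least one exposure column is required")
        if len(self.covariate_cols) < 1:
            raise ValueError("at least one covariate column is required")
        exp, cov = set(self.exposure_cols), set(self.covariate_cols)
        conf = set(self.confounder_cols)
        if exp & cov:
            raise ValueError(f"exposure/covariate roles overlap: {sorted(exp & cov)}")
        if exp & conf:
            raise ValueError(f"exposure/confounder roles overlap: {sorted(exp & conf)}")
        if self.outcome_col in exp | cov | conf:
            raise ValueError("outcome column cannot appear in any other role")
        unknown = set(self.discrete_covariates) - cov
        if unknown:
            raise ValueError(f"discrete covariates not in covariate_cols: {sorted(unknown)}")

    @property
    def continuous_covariates(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariate_cols if c not in self.discrete_covariates)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnRoles":
        return cls(
            outcome_col=d["outcome_col"],
            outcome_family=d["outcome_family"],
            exposure_cols=tuple(d["exposure_cols"]),
            covariate_cols=tuple(d["covariate_cols"]),
            discrete_covariates=tuple(d.get("discrete_covariates", ())),
            confounder_cols=tuple(d.get("confounder_cols", ())),
        )

    def to_dict(self) -> dict:
        return {
            "outcome_col": self.outcome_col,
            "outcome_family": self.outcome_family,
            "exposure_cols": list(self.exposure_cols),
            "covariate_cols": list(self.covariate_cols),
            "discrete_covariates": list(self.discrete_covariates),
            "confounder_cols": list(self.confounder_cols),
        }


@dataclass
class ObservationTable:
    """A validated, complete observations table ready for the window cover.

    Attributes
    ----------
    data : pandas.DataFrame
        N rows, all role columns numeric, no missing values.
    roles : ColumnRoles
    """

    data: pd.DataFrame
    roles: ColumnRoles

    def __post_init__(self) -> None:
        cols = (
            (self.roles.outcome_col,)
            + self.roles.exposure_cols
            + self.roles.covariate_cols
            + self.roles.confounder_cols
        )
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"table is missing role columns: {missing}")
        sub = self.data[list(dict.fromkeys(cols))]
        if sub.isna().any().any():
            raise ValueError("observation table contains missing values after preprocessing")
        if len(self.data) < 2:
            raise ValueError("at least 2 observations are required")
        if self.roles.outcome_family == "binary":
            y = set(np.unique(self.data[self.roles.outcome_col].to_numpy()))
            if y != {0, 1} and y != {0.0, 1.0}:
                raise ValueError(f"binary outcome must contain exactly the codes {{0,1}}, found {sorted(y)}")

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def outcome(self) -> np.ndarray:
        return self.data[self.roles.outcome_col].to_numpy(dtype=float)

    def exposures(self) -> pd.DataFrame:
        return self.data[list(self.roles.exposure_cols)]

    def covariates(self) -> pd.DataFrame:
        return self.data[list(self.roles.covariate_cols)]


def filter_missingness(
    raw: pd.DataFrame,
    roles: ColumnRoles,
    column_threshold: float = 0.20,
    row_threshold: float = 0.20,
) -> tuple[pd.DataFrame, ColumnRoles, dict]:
    """Drop exposure columns, then rows, with excessive missingness.

    A column is dropped when the fraction of missing values among all rows
    exceeds ``column_threshold``; afterwards a row is dropped when its missing
    fraction over the *retained* exposures exceeds ``row_threshold``.  The
    order matters and matches standard omics QC practice (variables first).

    Returns the filtered table, roles restricted to surviving exposures, and a
    provenance dict (dropped columns/rows).
    """
    if not (0 <= column_threshold <= 1) or not (0 <= row_threshold <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")
    exp = list(roles.exposure_cols)
    col_frac = raw[exp].isna().mean(axis=0)
    keep_cols = [c for c in exp if col_frac[c] <= column_threshold]
    dropped_cols = [c for c in exp if c not in keep_cols]
    if not keep_cols:
        raise ValueError("no exposures survive missingness filter")
    row_frac = raw[keep_cols].isna().mean(axis=1)
    keep_rows = row_frac <= row_threshold
    dropped_rows = list(raw.index[~keep_rows])
    out = raw.loc[keep_rows, [c for c in raw.columns if c not in dropped_cols]]
    new_roles = ColumnRoles(
        outcome_col=roles.outcome_col,
        outcome_family=roles.outcome_family,
        exposure_cols=tuple(keep_cols),
        covariate_cols=roles.covariate_cols,
        discrete_covariates=roles.discrete_covariates,
        confounder_cols=roles.confounder_cols,
    )
    log = {"dropped_columns": dropped_cols, "dropped_rows": dropped_rows}
    return out, new_roles, log


def impute_knn(table: pd.DataFrame, roles: ColumnRoles, k: int = 3) -> tuple[pd.DataFrame, int]:
    """Impute missing exposure cells with the mean of the k nearest rows.

    Distances are Euclidean over mutually observed exposures, computed on
    per-column standardized values so that scale does not dominate the
    neighbour search.  Observed cells are returned bit-identical; only missing
    cells are filled (on the original scale).

    Returns the completed table and the number of imputed cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exp = list(roles.exposure_cols)
    X = table[exp].to_numpy(dtype=float)
    mask = np.isnan(X)
    n_missing = int(mask.sum())
    if n_missing == 0:
        return table, 0
    if mask.all(axis=1).any():
        raise ValueError("row with all exposures missing; apply filter_missingness first")
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    Xs_full = imputer.fit_transform(Xs)
    X_full = Xs_full * sd + mu
    X_full[~mask] = X[~mask]  # keep observed entries bit-identical
    out = table.copy()
    out[exp] = X_full
    return out, n_missing


def transform_exposures(
    table: pd.DataFrame,
    roles: ColumnRoles,
    log_transform: bool = True,
    standardize: bool = True,
) -> ObservationTable:
    """Apply ln(1+x) to the exposures, then standardize each column.

    Standardization subtracts the column mean and divides by the sample
    standard deviation (denominator N-1).  The log transform suits
    concentration-like omics measurements; synthetic benchmark data is used
    untransformed (``log_transform=False``).
    """
    exp = list(roles.exposure_cols)
    out = table.copy()
    X = out[exp].to_numpy(dtype=float)
    if log_transform:
        bad = np.nonzero((X <= -1).any(axis=0))[0]
        if bad.size:
            raise ValueError(
                f"exposure {exp[bad[0]]!r} has values <= -1; cannot apply log(1+x)"
            )
        X = np.log1p(X)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValueError(f"exposure {exp[zero[0]]!r} has zero variance")
        X = (X - X.mean(axis=0)) / sd
    out[exp] = X
    return ObservationTable(data=out, roles=roles)


class ExposurePreprocessor(BaseEstimator, TransformerMixin):
    """Missingness filtering, kNN imputation and exposure transforms.

    A transformer over a pandas DataFrame with declared column roles; the
    fitted attribute ``roles_`` carries the (possibly reduced) exposure set
    forward to the window cover.

    Parameters
    ----------
    roles : ColumnRoles
    column_threshold, row_threshold : float, default 0.20
        Maximum tolerated missing fraction for an exposure column / a row.
    k : int, default 3
        Number of neighbours for imputation.
    log_transform : bool, default True
        Apply ln(1+x) to exposures before standardizing.
    standardize : bool, default True
    """

    def __init__(
        self,
        roles: ColumnRoles,
        column_threshold: float = 0.20,
        row_threshold: float = 0.20,
        k: int = 3,
        log_transform: bool = True,
        standardize: bool = True,
    ):
        self.roles = roles
        self.column_threshold = column_threshold
        self.row_threshold = row_threshold
        self.k = k
        self.log_transform = log_transform
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None) -> "ExposurePreprocessor":
        filtered, roles, log = filter_missingness(
            X, self.roles, self.column_threshold, self.row_threshold
        )
        complete, n_imputed = impute_knn(filtered, roles, self.k)
        self.roles_ = roles
        self.log_ = dict(log, n_imputed=n_imputed)
        self.table_ = transform_exposures(
            complete, roles, self.log_transform, self.standardize
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the cleaned table for the data seen at fit time."""
        if not hasattr(self, "table_"):
            raise ValueError("preprocessor is not fitted")
        return self.table_.data

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)
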