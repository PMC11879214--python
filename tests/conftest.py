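import numpy as np
import pandas as pd
import pytest

from espmod import ColumnRoles, ObservationTable


@pytest.fixture
def simple_roles():
    return ColumnRoles(
        outcome_col="Y",
        outcome_family="continuous",
        exposure_cols=("E1", "E2"),
        covariate_cols=("Z",),
    )


def make_table(
    z,
    y=None,
    exposures=None,
    outcome_family="continuous",
    n_exposures=2,
    seed=0,
    extra_covariates=None,
    discrete=None,
):
    """Build a small valid ObservationTable around given covariate values."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == 1 and z.shape[1] > 1 and extra_covariates is None:
        z = z.T
    n = z.shape[0]
    rng = np.random.default_rng(seed)
    if y is None:
        y = rng.integers(0, 2, n).astype(float) if outcome_family == "binary" else rng.normal(size=n)
    if exposures is None:
        exposures = rng.normal(size=(n, n_exposures))
    exposures = np.asarray(exposures, dtype=float)
    cols = {"Y": np.asarray(y, dtype=float)}
    for m in range(exposures.shape[1]):
        cols[f"E{m+1}"] = exposures[:, m]
    zcols = [f"Z{j+1}" for j in range(z.shape[1])] if z.shape[1] > 1 else ["Z"]
    for j, c in enumerate(zcols):
        cols[c] = z[:, j]
    roles = ColumnRoles(
        outcome_col="Y",
        outcome_family=outcome_family,
        exposure_cols=tuple(f"E{m+1}" for m in range(exposures.shape[1])),
        covariate_cols=tuple(zcols),
        discrete_covariates=tuple(discrete or ()),
    )
    return ObservationTable(data=pd.DataFrame(cols), roles=roles)


@pytest.fixture
def uniform_2d_table():
    """200 observations, two uniform covariates, binary outcome — the
    benchmark covariate layout."""
    rng = np.random.default_rng(42)
    z = rng.uniform(0, 1, size=(200, 2))
    y = np.repeat([0.0, 1.0], 100)
    return make_table(z, y=y, outcome_family="binary", n_exposures=3, seed=1,
                      extra_covariates=True)
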