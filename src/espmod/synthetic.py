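"""Synthetic benchmark generators with known effect-modification ground truth.

Three designs share a common frame: a balanced binary outcome (100
observations per class), 30 normally distributed exposures and two modifier
covariates Z1, Z2 ~ U(0,1).

* ``D1`` — no effect modification: every exposure is N(2, 0.5^2) for both
  outcome classes, independent of (Z1, Z2).  One true region.
* ``D2`` — two regions.  Region A (Z1 or Z2 <= 0.5): exposures as in D1 for
  both classes.  Region B (Z1, Z2 > 0.5): for cases (Y=1) the 30 exposures
  split into three random sets of 10 with means 2, 2.7 and 1.3 (SD 0.5).
* ``D3`` — three regions.  A (Z1 < 0.5): null; B (Z1, Z2 > 0.5): as D2's B;
  C (Z1 > 0.5, Z2 < 0.5): same shifted means but an independently drawn
  partition of the exposures into sets.

Region boundaries are smoothed: the half-space indicator 1{u > 0.5} is
replaced by a logistic ramp 1/(1 + exp(-(u - 0.5)/w)), giving a gradual
transition band of width ~w in membership probabilities; cases near a
boundary are assigned a region by sampling those probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ColumnRoles, ObservationTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "region_membership",
    "generate_dataset",
    "generate_reference_matrix",
    "synthetic_roles",
]

_REGIONS = {"D1": ("A",), "D2": ("A", "B"), "D3": ("A", "B", "C")}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one benchmark dataset."""

    design: str = "D1"
    n_per_class: int = 100
    n_exposures: int = 30
    base_mean: float = 2.0
    shifted_means: tuple[float, float] = (2.7, 1.3)
    sd: float = 0.5
    smoothing_width: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design not in _REGIONS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {sorted(_REGIONS)}")
        if self.n_exposures % 3 != 0:
            raise ValueError("n_exposures must be divisible by 3 (three variable sets)")


@dataclass
class SyntheticDataset:
    """A generated table plus its ground truth."""

    table: ObservationTable
    true_region: pd.Series            # region label per observation ("A"/"B"/"C")
    variable_sets: dict               # region -> {mean: list of exposure names}
    spec: SyntheticSpec


def synthetic_roles(n_exposures: int = 30) -> ColumnRoles:
    return ColumnRoles(
        outcome_col="Y",
        outcome_family="binary",
        exposure_cols=tuple(f"X{m+1}" for m in range(n_exposures)),
        covariate_cols=("Z1", "Z2"),
    )


def _ramp(u: np.ndarray, w: float) -> np.ndarray:
    """Smoothed indicator of u > 0.5 (crisp when w = 0)."""
    u = np.asarray(u, dtype=float)
    if w == 0:
        return (u > 0.5).astype(float)
    return 1.0 / (1.0 + np.exp(-(u - 0.5) / w))


def region_membership(design: str, z: np.ndarray, smoothing_width: float = 0.05) -> pd.DataFrame:
    """Region membership probabilities at covariate points ``z`` (rows in [0,1]^2).

    With zero smoothing these are crisp indicators of the design's regions;
    otherwise products of logistic ramps, summing to 1 across regions.
    """
    if design not in _REGIONS:
        raise ValueError(f"unknown design {design!r}")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    s1, s2 = _ramp(z[:, 0], smoothing_width), _ramp(z[:, 1], smoothing_width)
    if design == "D1":
        probs = {"A": np.ones(len(z))}
    elif design == "D2":
        b = s1 * s2                      # both above the threshold
        probs = {"A": 1.0 - b, "B": b}
    else:                                # D3
        probs = {"A": 1.0 - s1, "B": s1 * s2, "C": s1 * (1.0 - s2)}
    return pd.DataFrame(probs)


def _draw_sets(rng: np.random.Generator, names: list[str]) -> list[list[str]]:
    """Partition exposure names into three equal random sets."""
    perm = rng.permutation(len(names))
    third = len(names) // 3
    return [[names[i] for i in perm[j * third : (j + 1) * third]] for j in range(3)]


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one benchmark dataset (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    names = [f"X{m+1}" for m in range(spec.n_exposures)]
    y = np.repeat([0.0, 1.0], spec.n_per_class)
    Z = rng.uniform(0.0, 1.0, size=(n, 2))

    # all observations start from the null distribution
    X = rng.normal(spec.base_mean, spec.sd, size=(n, spec.n_exposures))

    probs = region_membership(spec.design, Z, spec.smoothing_width)
    regions = np.array(probs.columns)
    # controls are generated independently of (Z1, Z2); their "true region" is
    # still recorded from the covariates for diagnostics
    cum = probs.to_numpy().cumsum(axis=1)
    u = rng.uniform(size=n)
    region_idx = (u[:, None] > cum).sum(axis=1)
    true_region = pd.Series(regions[region_idx], name="true_region")

    means = (spec.base_mean,) + spec.shifted_means
    variable_sets: dict[str, dict[float, list[str]]] = {}
    for region in _REGIONS[spec.design]:
        if region == "A":
            continue
        sets = _draw_sets(rng, names)
        variable_sets[region] = {mu: cols for mu, cols in zip(means, sets)}
        shift = y == 1.0
        in_region = (true_region == region).to_numpy()
        rows = shift & in_region
        for mu, cols in variable_sets[region].items():
            idx = [names.index(c) for c in cols]
            X[np.ix_(rows, idx)] = rng.normal(mu, spec.sd, size=(rows.sum(), len(idx)))

    df = pd.DataFrame(X, columns=names)
    df.insert(0, "Y", y)
    df["Z1"], df["Z2"] = Z[:, 0], Z[:, 1]
    roles = synthetic_roles(spec.n_exposures)
    return SyntheticDataset(
        table=ObservationTable(data=df, roles=roles),
        true_region=true_region,
        variable_sets=variable_sets,
        spec=spec,
    )


def generate_reference_matrix(
    template: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Matrix of the template's shape with each column uniform over its range."""
    template = np.asarray(template, dtype=float)
    if template.size == 0:
        raise ValueError("template must be nonempty")
    rng = np.random.default_rng(rng)
    lo, hi = template.min(axis=0), template.max(axis=0)
    return rng.uniform(lo, hi, size=template.shape)
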