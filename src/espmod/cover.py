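"""Overlapping gliding-window cover of the modifier-covariate space.

Continuous covariates are covered by overlapping axis-aligned hyperrectangles
whose side lengths and gliding steps are derived from the data: for each
observation, the smallest box containing it and its n-1 nearest neighbours
(Euclidean distance on standardized covariates) is measured per dimension;
the window side L_j is the 95th percentile of those box sides and the gliding
step Delta_j their minimum.  Candidate window centres form the grid
Z_j^min + i*Delta_j, i = 0..floor((Z_j^max - Z_j^min)/Delta_j), crossed with
every observed combination of the discrete covariates; windows with too few
members are discarded.  Overlap means an observation typically belongs to
several windows, which is what later makes region membership fuzzy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .preprocess import ObservationTable

__all__ = [
    "WindowGeometry",
    "Window",
    "CoverGeometry",
    "WindowCover",
    "neighborhood_box_sides",
    "window_geometry",
    "enumerate_windows",
    "point_windows",
]


@dataclass(frozen=True)
class WindowGeometry:
    """Window side lengths and gliding steps, in original covariate units."""

    sides: tuple[float, ...]      # L_j per continuous covariate
    steps: tuple[float, ...]      # Delta_j per continuous covariate
    n_target: int
    percentile: float = 95.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sides", tuple(float(v) for v in self.sides))
        object.__setattr__(self, "steps", tuple(float(v) for v in self.steps))
        if len(self.sides) != len(self.steps):
            raise ValueError("sides and steps must have equal length")
        for L, d in zip(self.sides, self.steps):
            if not L > 0:
                raise ValueError("window sides must be positive")
            if not 0 < d:
                raise ValueError("gliding steps must be positive")


@dataclass(frozen=True)
class Window:
    """One retained window: a box in continuous-covariate space within a stratum."""

    stratum: tuple[float, ...]
    center: tuple[float, ...]
    member_idx: np.ndarray          # positional indices into the table

    @property
    def midpoint(self) -> tuple[float, ...]:
        return self.center

    @property
    def n_members(self) -> int:
        return len(self.member_idx)


@dataclass
class CoverGeometry:
    """The enumerated cover: geometry plus the retained windows."""

    geometry: WindowGeometry
    windows: list[Window]
    n_candidate: int
    continuous_cols: tuple[str, ...]
    discrete_cols: tuple[str, ...]
    z_min: tuple[float, ...]
    z_max: tuple[float, ...]
    empty_strata: list[tuple[float, ...]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.windows)

    def midpoints(self) -> np.ndarray:
        return np.array([w.center for w in self.windows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Cover report: one row per retained window."""
        rows = []
        for i, w in enumerate(self.windows):
            row = {"window": i, "n_members": w.n_members}
            row.update({c: v for c, v in zip(self.discrete_cols, w.stratum)})
            row.update({c: v for c, v in zip(self.continuous_cols, w.center)})
            rows.append(row)
        return pd.DataFrame(rows)


def neighborhood_box_sides(table: ObservationTable, n: int) -> np.ndarray:
    """Per-observation minimal-box side lengths over the n-point neighbourhood.

    Row i holds, per continuous covariate, the extent of the smallest
    axis-aligned box containing observation i and its n-1 nearest neighbours.
    Neighbours are found by Euclidean distance on covariates standardized by
    their sample SD; side lengths are reported in original units.
    """
    cols = table.roles.continuous_covariates
    Z = table.data[list(cols)].to_numpy(dtype=float)
    N = Z.shape[0]
    if N < 2:
        raise ValueError("at least 2 observations are required")
    if not 1 <= n <= N:
        raise ValueError(f"n must be in [1, {N}], got {n}")
    sd = Z.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Zs = (Z - Z.mean(axis=0)) / sd_safe
    nn = NearestNeighbors(n_neighbors=n).fit(Zs)
    _, idx = nn.kneighbors(Zs)
    pts = Z[idx]                                  # N x n x Jc
    return pts.max(axis=1) - pts.min(axis=1)


def window_geometry(
    side_matrix: np.ndarray,
    percentile: float = 95.0,
    n_target: int = 20,
) -> WindowGeometry:
    """Derive window sides (percentile) and gliding steps (minimum) per dimension.

    A zero minimum (coincident observations) falls back to the smallest
    positive side in that dimension; a dimension with no positive side at all
    is degenerate and rejected.
    """
    sides = np.asarray(side_matrix, dtype=float)
    if sides.ndim != 2 or sides.size == 0:
        raise ValueError("side matrix must be a nonempty 2-D array")
    L = np.percentile(sides, percentile, axis=0)   # linear interpolation
    steps = []
    for j in range(sides.shape[1]):
        col = sides[:, j]
        d = col.min()
        if d == 0:
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError(f"degenerate covariate in dimension {j}: all box sides are zero")
            d = pos.min()
        steps.append(d)
    if np.any(L <= 0):
        j = int(np.nonzero(L <= 0)[0][0])
        raise ValueError(f"degenerate covariate in dimension {j}: window side is zero")
    return WindowGeometry(sides=tuple(L), steps=tuple(steps), n_target=n_target, percentile=percentile)


def _stratum_values(table: ObservationTable) -> tuple[np.ndarray, list[tuple[float, ...]]]:
    """Observed combinations of the discrete covariates (one empty tuple if none)."""
    disc = table.roles.discrete_covariates
    if not disc:
        return np.zeros(table.n_obs, dtype=int), [()]
    D = table.data[list(disc)].to_numpy(dtype=float)
    uniq, codes = np.unique(D, axis=0, return_inverse=True)
    return codes, [tuple(row) for row in uniq]


def enumerate_windows(
    table: ObservationTable,
    geometry: WindowGeometry,
    min_obs: int = 1,
    min_class_count: int = 0,
) -> CoverGeometry:
    """Enumerate the candidate grid and retain sufficiently occupied windows.

    Candidate centres form the grid Z_j^min + i_j * Delta_j with
    i_j = 0..floor((Z_j^max - Z_j^min)/Delta_j), duplicated for every observed
    stratum of the discrete covariates.  Membership uses closed intervals
    [c_j - L_j/2, c_j + L_j/2].  A window is retained when it holds at least
    ``min_obs`` members and, for a binary outcome, at least
    ``min_class_count`` members of each outcome class (both classes must be
    present to fit a logistic model).
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    cols = table.roles.continuous_covariates
    Z = table.data[list(cols)].to_numpy(dtype=float)
    z_min, z_max = Z.min(axis=0), Z.max(axis=0)
    steps = np.asarray(geometry.steps)
    half = np.asarray(geometry.sides) / 2.0
    n_steps_f = np.floor((z_max - z_min) / steps)
    if np.prod(n_steps_f + 1) > 1e6:
        raise ValueError(
            "candidate grid exceeds 1e6 windows; gliding steps are degenerate "
            "relative to the covariate range (near-duplicate observations?)"
        )
    n_steps = n_steps_f.astype(int)
    axes = [z_min[j] + steps[j] * np.arange(n_steps[j] + 1) for j in range(len(cols))]

    binary = table.roles.outcome_family == "binary"
    y = table.outcome() if binary else None
    codes, strata = _stratum_values(table)

    windows: list[Window] = []
    empty_strata: list[tuple[float, ...]] = []
    n_candidate = 0
    for s_code, stratum in enumerate(strata):
        in_stratum = codes == s_code
        retained_before = len(windows)
        for center in itertools.product(*axes):
            n_candidate += 1
            c = np.asarray(center)
            inside = in_stratum & np.all(np.abs(Z - c) <= half, axis=1)
            if inside.sum() < min_obs:
                continue
            if binary and min_class_count > 0:
                y_in = y[inside]
                if (y_in == 1).sum() < min_class_count or (y_in == 0).sum() < min_class_count:
                    continue
            windows.append(
                Window(stratum=stratum, center=center, member_idx=np.nonzero(inside)[0])
            )
        if len(windows) == retained_before:
            empty_strata.append(stratum)
    if not windows:
        raise ValueError("cover is empty; reduce min_obs or increase n")
    return CoverGeometry(
        geometry=geometry,
        windows=windows,
        n_candidate=n_candidate,
        continuous_cols=cols,
        discrete_cols=table.roles.discrete_covariates,
        z_min=tuple(z_min),
        z_max=tuple(z_max),
        empty_strata=empty_strata,
    )


def point_windows(cover: CoverGeometry, z: dict | np.ndarray) -> list[int]:
    """Indices of every retained window containing covariate point ``z``.

    ``z`` may be a dict keyed by covariate name or an array ordered as
    continuous covariates followed by discrete covariates.  May be empty when
    the point lies in a sparse, uncovered region.
    """
    if isinstance(z, dict):
        zc = np.array([z[c] for c in cover.continuous_cols], dtype=float)
        zd = tuple(float(z[c]) for c in cover.discrete_cols)
    else:
        z = np.asarray(z, dtype=float).ravel()
        nc = len(cover.continuous_cols)
        zc, zd = z[:nc], tuple(z[nc:])
    half = np.asarray(cover.geometry.sides) / 2.0
    hits = []
    for i, w in enumerate(cover.windows):
        if w.stratum != zd:
            continue
        if np.all(np.abs(zc - np.asarray(w.center)) <= half):
            hits.append(i)
    return hits


class WindowCover(BaseEstimator):
    """Data-driven overlapping window cover of the covariate space.

    Parameters
    ----------
    n_target : int, default 20
        Neighbourhood size used to derive the geometry, and (by default) the
        minimum occupancy of a retained window.  Larger values give wider
        windows and smoother, lower-resolution profiles.
    percentile : float, default 95
        Percentile of neighbourhood box sides defining the window side.
    min_obs : int or None, default None
        Minimum members per retained window; defaults to ``n_target``.
    min_class_count : int, default 5
        For binary outcomes, the minimum count of each outcome class inside a
        retained window.
    sides, steps : sequence of float or None
        Manual override of the automatic L / Delta (original units).
    side_scale, step_scale : float, default 1.0
        Multipliers applied to the (automatic or manual) sides/steps; used by
        the window-parameter sensitivity experiments (e.g. 0.5 or 1.5).

    Attributes
    ----------
    side_matrix_ : ndarray of shape (N, Jc)
        Neighbourhood box sides per observation.
    geometry_ : WindowGeometry
    cover_ : CoverGeometry
    """

    def __init__(
        self,
        n_target: int = 20,
        percentile: float = 95.0,
        min_obs: int | None = None,
        min_class_count: int = 5,
        sides=None,
        steps=None,
        side_scale: float = 1.0,
        step_scale: float = 1.0,
    ):
        self.n_target = n_target
        self.percentile = percentile
        self.min_obs = min_obs
        self.min_class_count = min_class_count
        self.sides = sides
        self.steps = steps
        self.side_scale = side_scale
        self.step_scale = step_scale

    def fit(self, table: ObservationTable, y=None) -> "WindowCover":
        if self.sides is not None and self.steps is not None:
            self.side_matrix_ = None
            auto = WindowGeometry(
                sides=tuple(self.sides), steps=tuple(self.steps),
                n_target=self.n_target, percentile=self.percentile,
            )
        else:
            self.side_matrix_ = neighborhood_box_sides(table, self.n_target)
            auto = window_geometry(self.side_matrix_, self.percentile, self.n_target)
            if self.sides is not None:
                auto = WindowGeometry(tuple(self.sides), auto.steps, self.n_target, self.percentile)
            if self.steps is not None:
                auto = WindowGeometry(auto.sides, tuple(self.steps), self.n_target, self.percentile)
        self.geometry_ = WindowGeometry(
            sides=tuple(L * self.side_scale for L in auto.sides),
            steps=tuple(d * self.step_scale for d in auto.steps),
            n_target=self.n_target,
            percentile=self.percentile,
        )
        min_obs = self.n_target if self.min_obs is None else self.min_obs
        self.cover_ = enumerate_windows(
            table, self.geometry_, min_obs=min_obs, min_class_count=self.min_class_count
        )
        return self

    def point_windows(self, z) -> list[int]:
        return point_windows(self.cover_, z)
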