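"""End-to-end analysis: cover -> ESP -> cluster selection -> regions.

``EffectProfileClusterer`` composes the stage estimators behind a single
scikit-learn-style interface: ``fit`` takes a validated observation table and
exposes the cover, the ESP matrix, the cluster selection and the region
summary as fitted attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .cluster_select import ProfileClusterSelector
from .cover import WindowCover
from .esp import WindowEffectProfiler
from .preprocess import ObservationTable
from .regions import RegionSummary, membership_table, point_membership, summarize_regions

__all__ = ["EffectProfileClusterer"]


class EffectProfileClusterer(BaseEstimator, ClusterMixin):
    """Detect covariate regions with distinct effect-size profiles.

    Parameters mirror the stage estimators: window cover (``n_target``,
    ``percentile``, ``min_obs``, ``min_class_count``, manual/scaled geometry),
    effect sizes (``confounders``, ``log_odds``) and cluster selection
    (``alpha``, ``nref``, ``kmax``, ``fixed_k``, ``random_state``).

    Attributes (after ``fit``)
    --------------------------
    cover_ : CoverGeometry — retained windows and their members.
    esp_ : ESPMatrix — raw and standardized window effect sizes.
    selection_ : ClusterSelection — votes, elbow statistic, p-value, k_final.
    labels_ : ndarray — cluster label per retained window.
    regions_ : RegionSummary — centroids, dispersions, midpoints, rankings.
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
        confounders=None,
        log_odds: bool = True,
        alpha: float = 1e-3,
        nref: int = 2000,
        kmax: int | None = None,
        fixed_k: int | None = None,
        random_state: int | None = None,
    ):
        self.n_target = n_target
        self.percentile = percentile
        self.min_obs = min_obs
        self.min_class_count = min_class_count
        self.sides = sides
        self.steps = steps
        self.side_scale = side_scale
        self.step_scale = step_scale
        self.confounders = confounders
        self.log_odds = log_odds
        self.alpha = alpha
        self.nref = nref
        self.kmax = kmax
        self.fixed_k = fixed_k
        self.random_state = random_state

    def fit(self, table: ObservationTable, y=None) -> "EffectProfileClusterer":
        cover_est = WindowCover(
            n_target=self.n_target,
            percentile=self.percentile,
            min_obs=self.min_obs,
            min_class_count=self.min_class_count,
            sides=self.sides,
            steps=self.steps,
            side_scale=self.side_scale,
            step_scale=self.step_scale,
        ).fit(table)
        self.cover_ = cover_est.cover_
        profiler = WindowEffectProfiler(
            confounders=self.confounders, log_odds=self.log_odds
        ).fit(table, self.cover_)
        self.esp_ = profiler.esp_
        selector = ProfileClusterSelector(
            alpha=self.alpha,
            nref=self.nref,
            kmax=self.kmax,
            fixed_k=self.fixed_k,
            random_state=self.random_state,
        ).fit(self.esp_.values())
        self.selection_ = selector.selection_
        self.labels_ = selector.labels_
        self.regions_ = summarize_regions(self.esp_, self.labels_, self.cover_)
        return self

    @property
    def k_final_(self) -> int:
        return self.selection_.k_final

    def point_membership(self, z) -> dict:
        """Fuzzy cluster membership of one covariate point."""
        return point_membership(self.cover_, self.labels_, z)

    def membership_table(self, points: pd.DataFrame) -> pd.DataFrame:
        return membership_table(self.cover_, self.labels_, points)

    def write_artifacts(self, outdir: str | Path) -> None:
        """Write cover report, ESP matrices, selection JSON and region reports."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cover_.to_frame().to_csv(out / "cover.tsv", sep="\t", index=False)
        self.esp_.raw.to_csv(out / "esp_raw.tsv", sep="\t")
        self.esp_.standardized.to_csv(out / "esp_standardized.tsv", sep="\t")
        with open(out / "selection.json", "w") as fh:
            json.dump(self.selection_.to_dict(), fh, indent=2, sort_keys=True)
        self.regions_.centroids.to_csv(out / "region_centroids.tsv", sep="\t")
        self.regions_.dispersion.to_csv(out / "region_dispersion.tsv", sep="\t")
        self.regions_.midpoints.to_csv(out / "window_midpoints.tsv", sep="\t", index=False)
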