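"""Mapping window clusters back to covariate space.

Window clusters found in ESP space induce regions in the covariate space.
Because windows overlap, a covariate point can sit in windows with different
labels, so point-level membership is fuzzy: the membership fraction of a
cluster is the share of containing windows carrying that label.  Each region
is summarised by its centroid (mean standardized ESP of member windows) and
the dispersion of member windows around it; exposures are ranked by how far
their centroid coordinates lie apart between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cover import CoverGeometry, point_windows
from .esp import ESPMatrix

__all__ = [
    "RegionSummary",
    "summarize_regions",
    "point_membership",
    "project_windows_2d",
]


@dataclass
class RegionSummary:
    """Per-cluster ESP centroids, dispersions and window midpoints."""

    centroids: pd.DataFrame       # k x M mean standardized effect sizes
    dispersion: pd.DataFrame      # k x M SD of member-window coordinates
    midpoints: pd.DataFrame       # one row per window: stratum, center, label
    cluster_sizes: pd.Series
    exposure_gap: pd.Series       # per exposure: largest between-centroid gap

    def top_exposures(self, n: int = 20) -> list[str]:
        """The n exposures whose centroids differ most between clusters."""
        return list(self.exposure_gap.sort_values(ascending=False).index[:n])


def summarize_regions(
    esp: ESPMatrix, labels: np.ndarray, cover: CoverGeometry
) -> RegionSummary:
    """Summarise each window cluster as a covariate-space region.

    Centroid of cluster c is the mean of its windows' standardized ESP rows;
    dispersion is the standard deviation of those rows per exposure (zero for
    singleton clusters).
    """
    X = esp.standardized
    if X is None:
        raise ValueError("ESP matrix must be standardized")
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels must align with ESP matrix rows")
    ks = np.unique(labels)
    cent = X.groupby(labels).mean()
    disp = X.groupby(labels).std(ddof=1).fillna(0.0)
    sizes = pd.Series(labels).value_counts().sort_index()
    assert int(sizes.sum()) == cover.n_retained

    mid = cover.to_frame()
    mid["cluster"] = labels

    if len(ks) > 1:
        gap = pd.Series(
            {
                col: float(cent[col].max() - cent[col].min())
                for col in X.columns
            }
        )
    else:
        gap = pd.Series(0.0, index=X.columns)
    return RegionSummary(
        centroids=cent,
        dispersion=disp,
        midpoints=mid,
        cluster_sizes=sizes,
        exposure_gap=gap,
    )


def point_membership(
    cover: CoverGeometry, labels: np.ndarray, z
) -> dict:
    """Fuzzy cluster membership of a covariate point.

    Returns ``{"covered": bool, "fractions": {cluster: share}}`` where the
    share of a cluster is the fraction of retained windows containing ``z``
    that carry its label.  Fractions sum to 1 for covered points.
    """
    hits = point_windows(cover, z)
    if not hits:
        return {"covered": False, "fractions": {}}
    labs = np.asarray(labels)[hits]
    ks, counts = np.unique(labs, return_counts=True)
    return {
        "covered": True,
        "fractions": {int(k): float(c) / len(hits) for k, c in zip(ks, counts)},
    }


def membership_table(
    cover: CoverGeometry, labels: np.ndarray, points: pd.DataFrame
) -> pd.DataFrame:
    """Fuzzy membership for every row of ``points`` plus a majority label."""
    ks = sorted(set(np.asarray(labels).tolist()))
    rows = []
    for _, p in points.iterrows():
        m = point_membership(cover, labels, p.to_dict())
        row = {f"cluster_{k}": m["fractions"].get(k, 0.0) for k in ks}
        row["covered"] = m["covered"]
        row["majority"] = (
            max(m["fractions"], key=m["fractions"].get) if m["covered"] else -1
        )
        rows.append(row)
    return pd.DataFrame(rows, index=points.index)


def project_windows_2d(esp: ESPMatrix) -> np.ndarray:
    """Project standardized window ESPs onto their first two principal axes.

    Rows are centered but not re-scaled.  Sign convention: in each component
    the loading of largest magnitude is made positive, so plots are stable
    across runs.
    """
    X = esp.values()
    if X.shape[1] < 2:
        raise ValueError("PCA projection needs at least 2 exposures")
    pca = PCA(n_components=2, svd_solver="full")
    Y = pca.fit_transform(X)
    for c in range(2):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            Y[:, c] *= -1.0
    return Y
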