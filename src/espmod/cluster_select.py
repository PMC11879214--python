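"""Cluster-number selection for window ESPs.

Windows are clustered hierarchically (Ward linkage, Euclidean distance) in
standardized ESP space.  A consensus candidate k1 is taken as the most
frequent optimum across four indices — Calinski-Harabasz, Davies-Bouldin,
silhouette and the elbow statistic — falling back to the smallest vote when
no value repeats or votes tie.  Because these indices propose k > 1 even for
structureless data, k1 is then tested against a one-cluster null: reference
matrices with each feature drawn uniformly over its observed range are
clustered the same way, and the p-value is the fraction of references whose
elbow statistic at k1 exceeds the observed one.

The elbow statistic at k is the relative change of the inertia slope,
delta_k = s_k / s_{k+1} - 1 with s_k = I_k - I_{k-1}, where I_k is the
within-cluster sum of squared distances to cluster means at k clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

DEFAULT_KMAX = 5

__all__ = [
    "InertiaCurve",
    "ClusterSelection",
    "ProfileClusterSelector",
    "agglomerate",
    "inertia_curve",
    "index_votes",
    "reference_null_test",
    "select_clusters",
]


@dataclass
class InertiaCurve:
    """Inertia I_k for k = 1..kmax with slopes s_k and elbow statistic delta_k."""

    k: np.ndarray          # 1..kmax
    inertia: np.ndarray    # I_k
    slope: np.ndarray      # s_k = I_k - I_{k-1}, defined for k >= 2 (nan at k=1)
    delta: np.ndarray      # delta_k = s_k/s_{k+1} - 1, defined for 2 <= k <= kmax-1

    def delta_at(self, k: int) -> float:
        if not 2 <= k <= self.k[-1] - 1:
            raise ValueError(
                f"delta_{k} undefined for kmax={self.k[-1]}; increase kmax to at least {k + 1}"
            )
        return float(self.delta[k - 1])


@dataclass
class ClusterSelection:
    """Outcome of the automated cluster-number selection."""

    votes: dict[str, int]
    k1: int
    delta_obs: float | None
    p_value: float | None
    alpha: float
    k_final: int
    labels: np.ndarray
    curve: InertiaCurve
    nref: int
    seed: int | None = None
    fixed_k: int | None = None

    def to_dict(self) -> dict:
        return {
            "votes": self.votes,
            "k1": self.k1,
            "delta_obs": self.delta_obs,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "k_final": self.k_final,
            "nref": self.nref,
            "seed": self.seed,
            "fixed_k": self.fixed_k,
            "inertia": self.curve.inertia.tolist(),
            "delta": [None if not np.isfinite(d) else d for d in self.curve.delta],
            "labels": self.labels.tolist(),
        }


def _ward_linkage(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 windows")
    return linkage(X, method="ward")


def _cut(Z: np.ndarray, k: int) -> np.ndarray:
    n = Z.shape[0] + 1
    if k == 1:
        return np.zeros(n, dtype=int)
    if k >= n:
        return np.arange(n)
    return fcluster(Z, t=k, criterion="maxclust") - 1


def agglomerate(X: np.ndarray, k: int) -> np.ndarray:
    """Ward/Euclidean agglomerative labels for ``k`` clusters (deterministic)."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must be in [1, {X.shape[0]}]")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    return _cut(_ward_linkage(X), k)


def _inertia_of(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to cluster means."""
    total = float(np.einsum("ij,ij->", X, X))
    for c in np.unique(labels):
        mask = labels == c
        s = X[mask].sum(axis=0)
        total -= float(s @ s) / mask.sum()
    return total


def _inertia_from_heights(Z: np.ndarray, kmax: int) -> np.ndarray:
    """I_k for k=1..kmax from Ward merge heights (exact: each merge adds h^2/2)."""
    n = Z.shape[0] + 1
    costs = Z[:, 2] ** 2 / 2.0                       # merge order = ascending height
    cum = np.concatenate([[0.0], np.cumsum(costs)])  # cum[j] = inertia at n-j clusters
    ks = np.arange(1, kmax + 1)
    return cum[np.clip(n - ks, 0, n - 1)]


def _curve_from_inertia(I: np.ndarray) -> InertiaCurve:
    kmax = len(I)
    slope = np.full(kmax, np.nan)
    delta = np.full(kmax, np.nan)
    if kmax >= 2:
        slope[1:] = np.diff(I)
    for k in range(2, kmax):          # k index: position k-1; needs s_{k+1}
        s_k, s_k1 = slope[k - 1], slope[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta[k - 1] = s_k / s_k1 - 1.0 if s_k1 != 0 else np.nan
    return InertiaCurve(k=np.arange(1, kmax + 1), inertia=I, slope=slope, delta=delta)


def inertia_curve(X: np.ndarray, kmax: int, _linkage: np.ndarray | None = None) -> InertiaCurve:
    """Inertia curve from agglomerative labels at each k = 1..kmax."""
    X = np.asarray(X, dtype=float)
    if kmax > X.shape[0]:
        raise ValueError("kmax cannot exceed the number of windows")
    Z = _ward_linkage(X) if _linkage is None else _linkage
    I = np.array([_inertia_of(X, _cut(Z, k)) for k in range(1, kmax + 1)])
    return _curve_from_inertia(I)


def index_votes(X: np.ndarray, kmax: int, _linkage: np.ndarray | None = None) -> dict[str, int]:
    """Optimal k per index over k in [2, kmax] (elbow: [2, kmax-1])."""
    X = np.asarray(X, dtype=float)
    if kmax < 3:
        raise ValueError("kmax must be >= 3 so the elbow statistic is defined")
    Z = _ward_linkage(X) if _linkage is None else _linkage
    ch, db, sil = {}, {}, {}
    for k in range(2, kmax + 1):
        labels = _cut(Z, k)
        if len(np.unique(labels)) < 2:
            continue
        try:
            ch[k] = calinski_harabasz_score(X, labels)
            db[k] = davies_bouldin_score(X, labels)
            sil[k] = silhouette_score(X, labels)
        except ValueError:
            continue
    if not ch:
        raise ValueError("no valid clustering index could be computed")
    curve = inertia_curve(X, kmax, _linkage=Z)
    elbow_ks = [k for k in range(2, kmax) if np.isfinite(curve.delta[k - 1])]
    votes = {
        "calinski_harabasz": max(ch, key=ch.get),
        "davies_bouldin": min(db, key=db.get),
        "silhouette": max(sil, key=sil.get),
        "elbow": max(elbow_ks, key=lambda k: curve.delta[k - 1]),
    }
    return votes


def consensus_k(votes: dict[str, int]) -> int:
    """Most frequent vote; ties or no repeats resolve to the smallest vote."""
    counts = Counter(votes.values())
    top = max(counts.values())
    winners = [k for k, c in counts.items() if c == top]
    if top > 1 and len(winners) == 1:
        return winners[0]
    return min(votes.values())


def reference_null_test(
    X: np.ndarray,
    k1: int,
    nref: int = 2000,
    rng: np.random.Generator | int | None = None,
    kmax: int | None = None,
) -> tuple[float, float]:
    """One-cluster null test: observed elbow vs uniformly scattered references.

    Each reference matrix has every feature drawn uniformly over that
    feature's observed range; p = (# references with delta_k1 > observed
    delta_k1) / nref.
    """
    X = np.asarray(X, dtype=float)
    if k1 < 2:
        raise ValueError("k1 must be >= 2")
    if nref < 1:
        raise ValueError("nref must be >= 1")
    rng = np.random.default_rng(rng)
    kmax = kmax or min(DEFAULT_KMAX, X.shape[0] - 1)
    # the consensus k1 may sit at the top of the search range; the elbow
    # statistic needs I_{k1+1}, so extend the curve rather than fail
    kmax = max(kmax, k1 + 1)
    if kmax > X.shape[0]:
        raise ValueError(
            f"delta_{k1} needs the inertia at {k1 + 1} clusters but only "
            f"{X.shape[0]} windows exist"
        )
    curve = inertia_curve(X, kmax)
    delta_obs = curve.delta_at(k1)
    lo, hi = X.min(axis=0), X.max(axis=0)
    exceed = 0
    for _ in range(nref):
        R = rng.uniform(lo, hi, size=X.shape)
        Zr = _ward_linkage(R)
        I = _inertia_from_heights(Zr, k1 + 1)
        s_k, s_k1 = I[k1 - 1] - I[k1 - 2], I[k1] - I[k1 - 1]
        if s_k1 == 0:
            continue
        if s_k / s_k1 - 1.0 > delta_obs:
            exceed += 1
    return float(delta_obs), exceed / nref


def select_clusters(
    X: np.ndarray,
    alpha: float = 1e-3,
    nref: int = 2000,
    kmax: int | None = None,
    seed: int | None = None,
    fixed_k: int | None = None,
) -> ClusterSelection:
    """Full selection: four-index vote, reference-null test, final labels.

    ``fixed_k`` bypasses the automatic choice (the significance test is
    skipped and ``k_final = fixed_k``).
    """
    X = np.asarray(X, dtype=float)
    Z = _ward_linkage(X)
    kmax = kmax or min(DEFAULT_KMAX, X.shape[0] - 1)
    curve = inertia_curve(X, kmax, _linkage=Z)
    if fixed_k is not None:
        labels = _cut(Z, fixed_k)
        return ClusterSelection(
            votes={}, k1=fixed_k, delta_obs=None, p_value=None, alpha=alpha,
            k_final=fixed_k, labels=labels, curve=curve, nref=0, seed=seed,
            fixed_k=fixed_k,
        )
    votes = index_votes(X, kmax, _linkage=Z)
    k1 = consensus_k(votes)
    rng = np.random.default_rng(seed)
    delta_obs, p = reference_null_test(X, k1, nref=nref, rng=rng, kmax=kmax)
    k_final = k1 if p < alpha else 1
    labels = _cut(Z, k_final)
    return ClusterSelection(
        votes=votes, k1=k1, delta_obs=delta_obs, p_value=p, alpha=alpha,
        k_final=k_final, labels=labels, curve=curve, nref=nref, seed=seed,
    )


class ProfileClusterSelector(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of window ESPs with automated k selection.

    Parameters
    ----------
    alpha : float, default 1e-3
        Significance level of the one-cluster null test.
    nref : int, default 2000
        Number of uniform reference matrices (p-value resolution 1/nref).
    kmax : int or None
        Largest k searched; defaults to min(5, Nw - 1).  Small by design:
        with a few dozen windows, larger k fragments the cover into
        micro-clusters whose indices are dominated by noise.
    fixed_k : int or None
        Manual override of the cluster number.
    random_state : int or None
        Seed for the reference draws.

    Attributes
    ----------
    selection_ : ClusterSelection
    labels_ : ndarray of window cluster labels at ``k_final``.
    """

    def __init__(
        self,
        alpha: float = 1e-3,
        nref: int = 2000,
        kmax: int | None = None,
        fixed_k: int | None = None,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.nref = nref
        self.kmax = kmax
        self.fixed_k = fixed_k
        self.random_state = random_state

    def fit(self, X, y=None) -> "ProfileClusterSelector":
        self.selection_ = select_clusters(
            np.asarray(X, dtype=float),
            alpha=self.alpha,
            nref=self.nref,
            kmax=self.kmax,
            seed=self.random_state,
            fixed_k=self.fixed_k,
        )
        self.labels_ = self.selection_.labels
        return self
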