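"""Recurring connectivity states via Manhattan-distance k-means.

Windowed FNC vectors from all subjects are clustered with city-block
(L1) k-means: assignment minimizes L1 distance and the centroid update
is the coordinate-wise median, the L1-optimal center. Five random
restarts (distance-weighted L1 seeding) are run and the lowest-cost
solution kept. k is selected on per-subject exemplar windows — local
maxima of the across-pair variance of the FNC vector — by the elbow
criterion on the cost curve, with mean silhouette reported alongside.

Fitting mirrors the two-stage convention of the reference pipeline:
cluster the exemplars, then assign every window of every subject to the
frozen centroids. States are finally relabeled in order of first
emergence in the concatenated assignment stream, so "State 1" is the
first state any subject visits; relabeling is a pure permutation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .types import WindowedFNCSeries


def _l1_nearest(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, distances to own center); ties go to the lowest index."""
    D = cdist(X, centers, metric="cityblock")
    labels = D.argmin(axis=1)
    return labels, D[np.arange(X.shape[0]), labels]


def _l1_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++-style) seeding with L1 distances."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d = cdist(X, centers[:1], metric="cityblock").ravel()
    for j in range(1, k):
        total = d.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j:] = X[rng.integers(n, size=k - j)]
            break
        centers[j] = X[rng.choice(n, p=d / total)]
        d = np.minimum(d, cdist(X, centers[j : j + 1], metric="cityblock").ravel())
    return centers


class ManhattanKMeans(ClusterMixin, BaseEstimator):
    """k-means under the city-block metric with median centroid updates.

    Parameters
    ----------
    n_clusters : number of states k.
    n_init : random restarts; the lowest total L1 cost wins (default 5).
    max_iter : Lloyd iteration cap per restart.
    random_state : seed for seeding and empty-cluster repair.

    Attributes
    ----------
    cluster_centers_ : (k, n_features) coordinate-wise medians.
    labels_ : training assignments (0-based).
    inertia_ : total L1 cost of the best restart.
    cost_history_ : per-iteration cost of the best restart
        (non-increasing by construction).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_init: int = 5,
        max_iter: int = 300,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        k = self.n_clusters
        centers = _l1_seed(X, k, rng)
        history: list[float] = []
        labels = np.full(X.shape[0], -1)
        for _ in range(self.max_iter):
            labels, dists = _l1_nearest(X, centers)
            # repair empty clusters at the point farthest from its center
            for j in range(k):
                if not (labels == j).any():
                    far = int(dists.argmax())
                    centers[j] = X[far]
                    labels[far] = j
                    dists[far] = 0.0
            cost = float(dists.sum())
            if history and cost > history[-1] + 1e-9:  # pragma: no cover
                raise AssertionError("L1 k-means cost increased")
            if history and history[-1] - cost <= 1e-12:
                history.append(cost)
                break
            history.append(cost)
            for j in range(k):
                centers[j] = np.median(X[labels == j], axis=0)
        labels, dists = _l1_nearest(X, centers)
        return centers, labels, float(dists.sum()), history

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (observations x features)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        if X.shape[0] < self.n_clusters:
            raise ValueError("more clusters than observations")
        rng = np.random.default_rng(self.random_state)
        best = None
        self.run_costs_ = []
        for _ in range(self.n_init):
            centers, labels, cost, history = self._single_run(X, rng)
            self.run_costs_.append(cost)
            if best is None or cost < best[2]:
                best = (centers, labels, cost, history)
        self.cluster_centers_, self.labels_, self.inertia_, self.cost_history_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError("feature dimension mismatch with fitted centroids")
        return _l1_nearest(X, self.cluster_centers_)[0]

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def select_exemplars(
    series: list[WindowedFNCSeries],
) -> tuple[np.ndarray, np.ndarray]:
    """Exemplar windows: local maxima of across-pair variance per subject.

    Returns (stacked exemplar matrix, subject index of each exemplar).
    Endpoints qualify when greater than their single neighbor; a flat
    variance profile falls back to the first global maximum.
    """
    rows, owners = [], []
    for si, s in enumerate(series):
        if s.n_windows < 3:
            raise ValueError("need at least 3 windows per subject for exemplars")
        v = s.data.var(axis=1)
        peaks = [w for w in range(1, s.n_windows - 1) if v[w] > v[w - 1] and v[w] > v[w + 1]]
        if v[0] > v[1]:
            peaks.insert(0, 0)
        if v[-1] > v[-2]:
            peaks.append(s.n_windows - 1)
        if not peaks:
            peaks = [int(v.argmax())]
        rows.append(s.data[sorted(peaks)])
        owners.extend([si] * len(peaks))
    return np.vstack(rows), np.asarray(owners)


def choose_k(
    X: np.ndarray,
    k_range=range(2, 9),
    method: str = "elbow",
    n_init: int = 5,
    seed: int | None = None,
) -> tuple[int, dict]:
    """Select the number of states on (exemplar) observations.

    elbow: k maximizing the drop ratio of total L1 cost — the cost drop
    achieved by moving to k divided by the drop achieved by moving past
    it, (cost[k-1] - cost[k]) / (cost[k] - cost[k+1]) — a scale-free
    kink detector. silhouette: k maximizing mean silhouette under the
    city-block metric. Returns (k, diagnostics) with both full curves.
    """
    ks = sorted(k_range)
    if method not in {"elbow", "silhouette"}:
        raise ValueError("method must be 'elbow' or 'silhouette'")
    if method == "elbow" and len(ks) < 3:
        raise ValueError("elbow needs at least 3 candidate k values")
    X = np.asarray(X, dtype=float)
    costs, sils = {}, {}
    for k in ks:
        km = ManhattanKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        costs[k] = km.inertia_
        if 2 <= k <= X.shape[0] - 1:
            sils[k] = float(silhouette_score(X, km.labels_, metric="cityblock"))
    diagnostics = {"cost": costs, "silhouette": sils}
    if method == "silhouette":
        chosen = max(sils, key=sils.get)
    else:
        c = np.array([costs[k] for k in ks])
        drops = c[:-1] - c[1:]
        with np.errstate(divide="ignore"):
            ratio = np.where(drops[1:] > 0, drops[:-1] / drops[1:], np.inf)
        chosen = ks[1 + int(ratio.argmax())]
        diagnostics["drop_ratio"] = dict(zip(ks[1:-1], ratio.tolist()))
    diagnostics["chosen"] = chosen
    diagnostics["method"] = method
    return chosen, diagnostics


@dataclass
class StateModel:
    """Fitted brain-state model with emergence-ordered 1-based labels."""

    k: int
    centroids: np.ndarray                      # k x n_pairs, emergence order
    labels: dict[str, np.ndarray]              # subject_id -> 1-based sequence
    inertia: float
    n_init: int
    seed: int | None
    emergence_order: np.ndarray                # original centroid index of state s
    diagnostics: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.labels)

    def concatenated_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[s] for s in self.labels])


def _emergence_permutation(flat_labels: np.ndarray, k: int) -> np.ndarray:
    """Order of first occurrence; states never assigned go last."""
    first = np.full(k, np.iinfo(np.int64).max)
    for j in range(k):
        hits = np.flatnonzero(flat_labels == j)
        if hits.size:
            first[j] = hits[0]
    return np.argsort(first, kind="stable")


def fit_states(
    series: list[WindowedFNCSeries],
    k: int = 4,
    n_init: int = 5,
    seed: int | None = None,
    two_stage: bool = True,
) -> StateModel:
    """Cluster all subjects' windows into k states.

    two_stage (default): fit on exemplars, then one full assignment pass
    with frozen centroids. Single-stage fits on every window directly.
    """
    X_all = np.vstack([s.data for s in series])
    if two_stage:
        X_fit, _ = select_exemplars(series)
    else:
        X_fit = X_all
    km = ManhattanKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X_fit)
    flat = km.predict(X_all)
    perm = _emergence_permutation(flat, k)
    relabel = np.empty(k, dtype=int)
    relabel[perm] = np.arange(k)
    flat_1based = relabel[flat] + 1
    labels: dict[str, np.ndarray] = {}
    pos = 0
    for s in series:
        labels[s.subject_id] = flat_1based[pos : pos + s.n_windows]
        pos += s.n_windows
    return StateModel(
        k=k,
        centroids=km.cluster_centers_[perm],
        labels=labels,
        inertia=float(cdist(X_all, km.cluster_centers_, "cityblock").min(axis=1).sum()),
        n_init=n_init,
        seed=seed,
        emergence_order=perm,
        diagnostics={"fit_inertia": km.inertia_, "run_costs": km.run_costs_,
                     "two_stage": two_stage},
    )


def assign_states(
    series: list[WindowedFNCSeries], centroids: np.ndarray
) -> dict[str, np.ndarray]:
    """Assign windows to the L1-nearest centroid (1-based labels)."""
    centroids = np.asarray(centroids, dtype=float)
    out = {}
    for s in series:
        if s.n_pairs != centroids.shape[1]:
            raise ValueError("centroid dimension does not match pair dimension")
        out[s.subject_id] = _l1_nearest(s.data, centroids)[0] + 1
    return out


def state_summary(model: StateModel) -> "object":
    """Per-state total window counts and occurrence percentages."""
    import pandas as pd

    flat = model.concatenated_labels()
    counts = np.array([(flat == s).sum() for s in range(1, model.k + 1)])
    pct = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {"state": np.arange(1, model.k + 1), "n_windows": counts, "percent": pct}
    )
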