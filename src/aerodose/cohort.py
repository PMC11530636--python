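"""Cohort morphometry: feature ranking and phenotype clustering.

A cohort of airway morphometries (trachea diameter t_d, carina angle
b_a, lumen volume, cumulative bronchial length, plus age/weight/sex) is
(1) ranked by Random-Forest predictive importance for age or weight and
(2) clustered in its two leading features with an RBF kernel k-means
into nine groups on the (small|mean|big t_d) x (small|mean|big b_a)
grid, labelled ss..bb, with one representative subject per cluster (the
point nearest its centroid in kernel feature space).

The regressor and clusterer are exercised on synthetic cohorts only;
no claim is made about predicting real subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .geometry import CLUSTER_ANCHORS

FEATURES = ("t_d", "b_a", "volume", "total_length")
GRID_LABELS = ("ss", "sm", "sb", "ms", "mm", "mb", "bs", "bm", "bb")

__all__ = [
    "FEATURES",
    "GRID_LABELS",
    "FeatureRanking",
    "ClusterReport",
    "KernelKMeans",
    "synthetic_cohort",
    "rank_feature_importance",
    "fit_kernel_kmeans",
    "label_clusters_and_select",
    "cluster_cohort",
]


def synthetic_cohort(n: int, seed: int = 0, clusters=None) -> pd.DataFrame:
    """Synthetic cohort table anchored at the nine phenotype clusters.

    Subjects are assigned uniformly to clusters; (t_d, b_a) are drawn
    from each cluster's Gaussian (mean, sd) clipped to its printed
    range.  Volume and cumulative length scale allometrically with t_d
    (V ~ t_d^3, L ~ t_d) with log-normal scatter; age and weight are
    increasing, noisy functions of t_d (t_d is the dominant predictor by
    construction, with b_a a weaker secondary signal).
    """
    rng = np.random.default_rng(seed)
    names = list(clusters or CLUSTER_ANCHORS)
    rows = []
    for i in range(n):
        name = names[int(rng.integers(len(names)))]
        a = CLUSTER_ANCHORS[name]
        td = float(np.clip(rng.normal(a["t_d"][0], a["t_d"][1]), a["t_d"][2], a["t_d"][3]))
        ba = float(np.clip(rng.normal(a["b_a"][0], a["b_a"][1]), a["b_a"][2], a["b_a"][3]))
        volume = 9.0 * td**3 * rng.lognormal(0.0, 0.08)
        length = 55.0 * td * rng.lognormal(0.0, 0.08)
        age = 2.2 * (td - 10.0) + 0.08 * (ba - 80.0) + rng.normal(0.0, 1.5)
        weight = 5.5 * (td - 8.0) + 0.15 * (ba - 80.0) + rng.normal(0.0, 4.0)
        rows.append(dict(subject_id=f"s{i:04d}", cluster=name, t_d=td, b_a=ba,
                         volume=volume, total_length=length,
                         age=max(age, 2.0), weight=max(weight, 10.0),
                         sex=("m", "f")[int(rng.integers(2))]))
    return pd.DataFrame(rows)


@dataclass
class FeatureRanking:
    """Ordered feature importances plus held-out regression error."""

    table: pd.DataFrame  # columns feature, importance (descending)
    rmse: float
    target: str

    @property
    def top_feature(self) -> str:
        return str(self.table.iloc[0]["feature"])


def rank_feature_importance(cohort: pd.DataFrame, target: str = "age",
                            features=FEATURES, seed: int = 0,
                            n_estimators: int = 200,
                            test_size: float = 0.25) -> FeatureRanking:
    """Random-Forest importance ranking of morphometric features.

    Importances are non-negative and sum to 1; the report includes the
    held-out RMSE of the forest.  Deterministic under a fixed seed.
    """
    if target not in ("age", "weight"):
        raise ValueError("target must be 'age' or 'weight'")
    cols = list(features) + [target]
    data = cohort[cols].dropna()
    if len(data) < 20:
        raise ValueError(f"need >= 20 complete rows, got {len(data)}")
    X = data[list(features)].to_numpy()
    y = data[target].to_numpy()
    for j, name in enumerate(features):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"feature {name!r} is constant; importance will be 0",
                          stacklevel=2)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_size,
                                              random_state=seed)
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(X_tr, y_tr)
    rmse = float(np.sqrt(mean_squared_error(y_te, forest.predict(X_te))))
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    table = pd.DataFrame({"feature": np.asarray(features)[order],
                          "importance": imp[order]})
    return FeatureRanking(table=table, rmse=rmse, target=target)


class KernelKMeans(BaseEstimator, ClusterMixin):
    """k-means in the feature space of an RBF kernel.

    Distances to cluster means are evaluated through the kernel trick:
    ||phi(x) - c_j||^2 = K_xx - 2 mean_i K_xi + mean_il K_il over cluster
    members.  Initialization is k-means++-style seeding in kernel space;
    the within-cluster objective is non-increasing over iterations.

    Parameters
    ----------
    n_clusters : number of clusters k.
    gamma : RBF bandwidth; None selects 1/(2 h^2) with h the median
        pairwise distance of the fit data.
    max_iter, tol : Lloyd-iteration controls.
    random_state : seed for the k-means++ draws.
    """

    def __init__(self, n_clusters: int = 9, gamma: float | None = None,
                 max_iter: int = 300, tol: float = 1e-10,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma is not None:
            if self.gamma <= 0:
                raise ValueError("gamma must be > 0")
            return self.gamma
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        med = np.median(np.sqrt(d2[np.triu_indices(len(X), 1)]))
        if med == 0:
            raise ValueError("all points identical: bandwidth heuristic undefined "
                             "(pass gamma explicitly)")
        return 1.0 / (2.0 * med**2)

    @staticmethod
    def _point_to_cluster_dist2(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
        """(n, k) squared kernel-space distances to each cluster mean."""
        n = K.shape[0]
        dist = np.tile(np.diag(K)[:, None], (1, k)).astype(float)
        for j in range(k):
            mask = labels == j
            nj = mask.sum()
            if nj == 0:
                dist[:, j] = np.inf
                continue
            dist[:, j] += -2.0 * K[:, mask].sum(1) / nj + K[np.ix_(mask, mask)].sum() / nj**2
        return dist

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n = len(X)
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if n < k:
            raise ValueError(f"n_samples={n} < n_clusters={k}")
        if k > 1 and np.unique(X, axis=0).shape[0] < k:
            raise ValueError("fewer distinct points than clusters")
        rng = np.random.default_rng(self.random_state)
        gamma = self._resolve_gamma(X) if (self.gamma is None and k > 1) else \
            (self.gamma if self.gamma is not None else 1.0)
        K = rbf_kernel(X, X, gamma=gamma)

        # k-means++ seeding in kernel space: phi-distances between points
        d_pp = np.add.outer(np.diag(K), np.diag(K)) - 2.0 * K
        centers = [int(rng.integers(n))]
        while len(centers) < k:
            dmin = d_pp[:, centers].min(1)
            total = dmin.sum()
            if total <= 0:
                remaining = [i for i in range(n) if i not in centers]
                centers.append(int(rng.choice(remaining)))
                continue
            centers.append(int(rng.choice(n, p=dmin / total)))
        labels = np.argmin(d_pp[:, centers], axis=1)

        history = []
        for it in range(self.max_iter):
            dist = self._point_to_cluster_dist2(K, labels, k)
            new_labels = np.argmin(dist, axis=1)
            obj = float(dist[np.arange(n), new_labels].sum())
            history.append(obj)
            if np.array_equal(new_labels, labels) and it > 0:
                break
            if len(history) > 1 and history[-2] - obj < self.tol:
                labels = new_labels
                break
            labels = new_labels

        self.gamma_ = gamma
        self.labels_ = labels
        self.inertia_ = history[-1] if history else 0.0
        self.objective_history_ = np.asarray(history)
        self.n_iter_ = len(history)
        self.X_fit_ = X
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def transform_dist2(self, X) -> np.ndarray:
        """Squared kernel-space distances of X rows to the fitted means."""
        X = np.asarray(X, float)
        Kxy = rbf_kernel(X, self.X_fit_, gamma=self.gamma_)
        dist = np.ones((len(X), self.n_clusters))  # K_xx = 1 for RBF
        for j in range(self.n_clusters):
            mask = self.labels_ == j
            nj = mask.sum()
            Kff = rbf_kernel(self.X_fit_[mask], self.X_fit_[mask], gamma=self.gamma_)
            dist[:, j] += -2.0 * Kxy[:, mask].sum(1) / nj + Kff.sum() / nj**2
        return dist

    def predict(self, X):
        return np.argmin(self.transform_dist2(X), axis=1)


@dataclass
class ClusterReport:
    """Fitted clustering of a cohort in normalized (t_d, b_a)."""

    model: KernelKMeans
    scaler: StandardScaler
    assignments: pd.Series  # subject_id -> cluster index
    labels: dict[int, str]  # cluster index -> grid name (k == 9)
    representatives: dict[int, str]  # cluster index -> subject_id
    representative_dist: dict[int, float]
    flagged: list[int] = field(default_factory=list)  # ambiguous representatives

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.assignments.index,
                           "cluster": self.assignments.values})
        df["label"] = [self.labels.get(c, str(c)) for c in df["cluster"]]
        df["representative"] = [self.representatives[c] == s
                                for s, c in zip(df["subject_id"], df["cluster"])]
        return df


def fit_kernel_kmeans(points: np.ndarray, k: int = 9, seed: int = 0,
                      gamma: float | None = None) -> KernelKMeans:
    """Fit the RBF kernel k-means on pre-normalized (t_d, b_a) points."""
    return KernelKMeans(n_clusters=k, gamma=gamma, random_state=seed).fit(points)


def _tertile_letters(values: np.ndarray) -> list[str]:
    """s/m/b letters by rank tertile; ties broken by ascending index."""
    k = len(values)
    if k % 3 != 0:
        raise ValueError("tertile labelling needs k divisible by 3")
    order = np.argsort(values, kind="stable")  # stable => ascending index on ties
    letters = [""] * k
    third = k // 3
    for pos, idx in enumerate(order):
        letters[idx] = "smb"[min(pos // third, 2)]
    return letters


def label_clusters_and_select(model: KernelKMeans, points: np.ndarray,
                              ids=None, ambiguity_threshold: float | None = None):
    """Grid-label clusters and pick one representative point per cluster.

    Labels follow the position of each cluster centroid (input-space mean
    of its members) relative to the per-feature tertiles of the centroid
    coordinates: first letter for t_d (column 0), second for b_a
    (column 1).  The representative is the member nearest its centroid
    in kernel feature space (exhaustively verifiable through the
    kernel).  Clusters whose representative distance exceeds
    ``ambiguity_threshold`` are flagged, not dropped.

    Returns (labels, representatives, rep_dist, flagged).
    """
    points = np.asarray(points, float)
    k = model.n_clusters
    if k != 9:
        raise ValueError("grid labelling is defined for k = 9")
    ids = np.asarray(ids if ids is not None else np.arange(len(points)))
    centroids = np.vstack([points[model.labels_ == j].mean(0) for j in range(k)])
    td_letters = _tertile_letters(centroids[:, 0])
    ba_letters = _tertile_letters(centroids[:, 1])
    labels = {j: td_letters[j] + ba_letters[j] for j in range(k)}

    dist = model.transform_dist2(points)
    reps, rep_dist, flagged = {}, {}, []
    for j in range(k):
        members = np.flatnonzero(model.labels_ == j)
        best = members[np.argmin(dist[members, j])]
        reps[j] = ids[best]
        rep_dist[j] = float(np.sqrt(max(dist[best, j], 0.0)))
        if ambiguity_threshold is not None and rep_dist[j] > ambiguity_threshold:
            flagged.append(j)
    return labels, reps, rep_dist, flagged


def cluster_cohort(cohort: pd.DataFrame, k: int = 9, seed: int = 0,
                   gamma: float | None = None,
                   features: tuple[str, str] = ("t_d", "b_a"),
                   ambiguity_threshold: float | None = None) -> ClusterReport:
    """Standardize (t_d, b_a), fit the kernel k-means and label the grid."""
    X_raw = cohort[list(features)].to_numpy(float)
    scaler = StandardScaler().fit(X_raw)
    X = scaler.transform(X_raw)
    model = fit_kernel_kmeans(X, k=k, seed=seed, gamma=gamma)
    if k == 9:
        labels, reps, rep_dist, flagged = label_clusters_and_select(
            model, X, ids=cohort["subject_id"].to_numpy(),
            ambiguity_threshold=ambiguity_threshold)
    else:
        labels = {j: str(j) for j in range(k)}
        dist = model.transform_dist2(X)
        reps, rep_dist, flagged = {}, {}, []
        for j in range(k):
            members = np.flatnonzero(model.labels_ == j)
            best = members[np.argmin(dist[members, j])]
            reps[j] = cohort["subject_id"].to_numpy()[best]
            rep_dist[j] = float(np.sqrt(max(dist[best, j], 0.0)))
    assignments = pd.Series(model.labels_, index=cohort["subject_id"], name="cluster")
    return ClusterReport(model=model, scaler=scaler, assignments=assignments,
                         labels=labels, representatives=reps,
                         representative_dist=rep_dist, flagged=flagged)
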