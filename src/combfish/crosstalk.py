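"""Fluorescence channel cross-talk estimation by scaled k-means.

Each dye ``d`` has a characteristic channel signature ``c_d`` (optical
bleedthrough plus chemical cross-reactivity), assumed constant across
rounds.  Every well-isolated spot in round ``r`` emits a scaled copy of one
signature, so the signatures are recovered by clustering the per-round
channel vectors ``V_{s,r}`` onto rays: minimize

    sum_{s,r} min_{d, lambda} | V_{s,r} - lambda * c_d |**2

over unit vectors ``c_d`` and non-negative scales ``lambda``.  This is
k-means where a cluster is a direction rather than a centroid: the
assignment step projects each vector on each ray, and the update step
replaces each ray by the principal direction of its assigned vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .imgproc import SpotCloud

__all__ = [
    "CrosstalkMatrix",
    "ScaledKMeans",
    "select_isolated_spots",
    "scaled_kmeans",
    "match_columns_to_dyes",
]


class CrosstalkMatrix:
    """Unit-norm dye signatures as columns of an (n_channels, n_dyes) array."""

    def __init__(
        self,
        columns: np.ndarray,
        assignments: np.ndarray | None = None,
        scales: np.ndarray | None = None,
        objective: float = float("nan"),
    ):
        columns = np.asarray(columns, dtype=float)
        norms = np.linalg.norm(columns, axis=0)
        if np.any(norms <= 0):
            raise ValueError("cross-talk columns must be nonzero")
        self.columns = columns / norms
        self.assignments = assignments
        self.scales = scales
        self.objective = objective

    @property
    def n_channels(self) -> int:
        return self.columns.shape[0]

    @property
    def n_dyes(self) -> int:
        return self.columns.shape[1]

    def column(self, dye: int) -> np.ndarray:
        return self.columns[:, dye]

    @classmethod
    def identity(cls, n: int) -> "CrosstalkMatrix":
        return cls(np.eye(n))


def select_isolated_spots(
    reference_image: np.ndarray,
    spots: SpotCloud,
    r_inner_px: float = 4.0,
    r_outer_px: float = 14.0,
    annulus_threshold: float | None = None,
    threshold_fraction: float = 0.2,
) -> SpotCloud:
    """Keep spots whose surrounding annulus (4-14 px by default) is dim.

    The mean reference intensity over pixels at radius
    ``r_inner <= r <= r_outer`` must fall below ``annulus_threshold``;
    if no threshold is given it defaults to ``threshold_fraction`` times
    the median peak intensity of the input spots.  Spots whose annulus
    does not fit inside the image are dropped.
    """
    if r_inner_px >= r_outer_px:
        raise ValueError("r_inner_px must be smaller than r_outer_px")
    image = np.asarray(reference_image, dtype=float)
    w = int(np.ceil(r_outer_px))
    yy, xx = np.mgrid[-w : w + 1, -w : w + 1]
    rr = np.hypot(yy, xx)
    annulus = (rr >= r_inner_px) & (rr <= r_outer_px)

    if annulus_threshold is None:
        peaks = image[spots.coordinates[:, 0], spots.coordinates[:, 1]]
        annulus_threshold = threshold_fraction * float(np.median(peaks)) if len(peaks) else 0.0

    keep = []
    for i, (r, c) in enumerate(spots.coordinates):
        if r - w < 0 or c - w < 0 or r + w + 1 > image.shape[0] or c + w + 1 > image.shape[1]:
            continue
        patch = image[r - w : r + w + 1, c - w : c + w + 1]
        if patch[annulus].mean() < annulus_threshold:
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    return SpotCloud(
        coordinates=spots.coordinates[keep],
        intensities=spots.intensities[keep],
        tile=spots.tile,
        round=spots.round,
        channel=spots.channel,
    )


class ScaledKMeans:
    """Cluster channel vectors onto rays ``lambda * c_d`` (sklearn style).

    Parameters
    ----------
    n_clusters:
        Number of dye signatures to fit.
    max_iter:
        Iteration cap; the alternation otherwise stops as soon as the
        assignment is unchanged.

    Attributes (after ``fit``)
    --------------------------
    columns_ : (n_channels, n_clusters) unit-norm signatures.
    labels_ : per-vector dye assignment.
    scales_ : per-vector non-negative projection scale.
    objective_ : final value of the summed squared residual.
    objective_path_ : objective after every iteration (non-increasing).
    n_iter_ : iterations run.
    """

    def __init__(self, n_clusters: int = 7, max_iter: int = 100):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "max_iter": self.max_iter}

    def set_params(self, **params) -> "ScaledKMeans":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _principal_direction(vectors: np.ndarray) -> np.ndarray:
        """Dominant unit eigenvector of the scatter, sign so that the mean
        projection of the vectors on it is non-negative."""
        scatter = vectors.T @ vectors
        w, v = np.linalg.eigh(scatter)
        direction = v[:, -1]
        if vectors.mean(axis=0) @ direction < 0:
            direction = -direction
        return direction

    def _init_columns(self, V: np.ndarray) -> np.ndarray:
        """Group vectors by argmax channel and normalize the group means.

        Dyes are channel-dominant by design, so this starts every ray
        inside its basin of attraction.  Empty channels are seeded with the
        corresponding unit basis vector.
        """
        n_channels = V.shape[1]
        cols = np.zeros((n_channels, self.n_clusters))
        argmax = V.argmax(axis=1)
        for d in range(self.n_clusters):
            group = V[argmax == d] if d < n_channels else np.empty((0, n_channels))
            if len(group) == 0:
                mean = np.eye(n_channels)[min(d, n_channels - 1)]
            else:
                mean = group.mean(axis=0)
            norm = np.linalg.norm(mean)
            cols[:, d] = mean / norm if norm > 0 else np.eye(n_channels)[d % n_channels]
        return cols

    def fit(self, X: np.ndarray, y=None) -> "ScaledKMeans":
        V = np.asarray(X, dtype=float)
        if V.ndim != 2:
            raise ValueError("expected a 2D array of channel vectors")
        if len(V) < self.n_clusters:
            raise ValueError(
                f"need at least n_clusters={self.n_clusters} vectors, got {len(V)}"
            )
        cols = self._init_columns(V)
        labels = np.full(len(V), -1)
        path: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # assignment: projections on every ray; lambda = max(0, V.c_d)
            proj = V @ cols  # (n, k)
            lam = np.maximum(proj, 0.0)
            # residual^2 = |V|^2 - 2 lam proj + lam^2 = |V|^2 - lam^2 (at optimum)
            sq_norm = (V**2).sum(axis=1, keepdims=True)
            resid = sq_norm - 2 * lam * proj + lam**2
            new_labels = resid.argmin(axis=1)
            scales = lam[np.arange(len(V)), new_labels]
            path.append(float(resid[np.arange(len(V)), new_labels].sum()))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            # update: principal direction per cluster; empty clusters are
            # re-seeded from the currently worst-fit vector
            worst = np.argsort(resid[np.arange(len(V)), labels])[::-1]
            worst_iter = iter(worst)
            for d in range(self.n_clusters):
                members = V[labels == d]
                if len(members) == 0:
                    seed = V[next(worst_iter)]
                    norm = np.linalg.norm(seed)
                    cols[:, d] = seed / norm if norm > 0 else cols[:, d]
                else:
                    cols[:, d] = self._principal_direction(members)

        self.columns_ = cols
        self.labels_ = labels
        self.scales_ = np.maximum(V @ cols, 0.0)[np.arange(len(V)), labels]
        self.objective_ = path[-1]
        self.objective_path_ = np.asarray(path)
        self.n_iter_ = n_iter
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def scaled_kmeans(vectors: np.ndarray, n_dyes: int, max_iter: int = 100) -> CrosstalkMatrix:
    """Functional wrapper around :class:`ScaledKMeans`."""
    model = ScaledKMeans(n_clusters=n_dyes, max_iter=max_iter).fit(vectors)
    return CrosstalkMatrix(
        columns=model.columns_,
        assignments=model.labels_,
        scales=model.scales_,
        objective=model.objective_,
    )


def match_columns_to_dyes(crosstalk: CrosstalkMatrix) -> CrosstalkMatrix:
    """Permute columns so dye d's signature peaks in channel d.

    k-means clusters carry no dye labels; because each dye is imaged
    principally in its own channel, the permutation maximizing the matrix
    diagonal (solved as a linear assignment) recovers the dye identity.
    """
    cols = crosstalk.columns
    if cols.shape[0] != cols.shape[1]:
        raise ValueError("dye matching assumes n_channels == n_dyes")
    _, perm = linear_sum_assignment(-cols)  # maximize sum_d cols[d, perm[d]]
    new_assign = None
    if crosstalk.assignments is not None:
        relabel = np.empty(len(perm), dtype=int)
        relabel[perm] = np.arange(len(perm))  # old cluster j -> dye index
        new_assign = relabel[crosstalk.assignments]
    return CrosstalkMatrix(
        columns=cols[:, perm],
        assignments=new_assign,
        scales=crosstalk.scales,
        objective=crosstalk.objective,
    )
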