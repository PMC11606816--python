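"""PCA and hierarchical clustering of sample profiles.

Samples are the observations (table columns), features the variables. PCA is an
eigendecomposition of the feature covariance across samples, computed via SVD of
the centered (optionally unit-variance scaled) sample-by-feature matrix. Output
is deterministic: each component's sign is fixed so that its largest-magnitude
loading is positive (ties broken by feature-index order).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2

from .errors import ConfigurationError, ValidationError
from .tabular_io import AbundanceTable

_SCALINGS = ("center_only", "unit_variance")


@dataclasses.dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_fraction: np.ndarray  # per-component fraction of total variance
    scaling_used: str
    dropped_features: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(table: AbundanceTable, scaling: str = "unit_variance") -> PCAResult:
    """Principal component analysis of sample profiles.

    ``scaling="unit_variance"`` (default, the convention of common
    chemometrics software) standardizes each feature to unit variance after
    centering; zero-variance features are dropped with a warning.
    ``scaling="center_only"`` keeps features on their native scale, so total
    variance equals the sum of per-feature variances.
    """
    if scaling not in _SCALINGS:
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    if table.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")

    X = table.data.to_numpy().T  # samples x features
    feature_ids = list(table.feature_ids)
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0, ddof=1)

    dropped: list[str] = []
    if scaling == "unit_variance":
        zero = sd <= 0
        if zero.any():
            dropped = [feature_ids[i] for i in np.flatnonzero(zero)]
            warnings.warn(
                f"dropping {len(dropped)} zero-variance feature(s) under "
                f"unit-variance scaling: {dropped}"
            )
            Xc = Xc[:, ~zero]
            sd = sd[~zero]
            feature_ids = [f for f in feature_ids if f not in set(dropped)]
        Xc = Xc / sd

    n_samples = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(n_samples - 1, Xc.shape[1])
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]

    # Deterministic sign: the largest-magnitude loading of each component is
    # positive; np.argmax takes the first (lowest feature index) on ties.
    for j in range(n_comp):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    var = s**2 / (n_samples - 1)
    total = (Xc**2).sum() / (n_samples - 1)
    explained = var / total if total > 0 else np.zeros_like(var)

    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    scores = pd.DataFrame(U * s, index=table.sample_ids, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=feature_ids, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=explained,
        scaling_used=scaling,
        dropped_features=dropped,
    )


@dataclasses.dataclass
class SampleClustering:
    """Agglomerative clustering of samples with a flat cut at k clusters."""

    linkage_matrix: np.ndarray
    labels: pd.Series  # sample id -> cluster label (1..k)
    k: int
    method: str
    metric: str


def cluster_samples(
    table: AbundanceTable,
    k: int,
    method: str = "average",
    metric: str = "euclidean",
) -> SampleClustering:
    """Average-linkage (by default) agglomeration of sample columns, cut at k."""
    n = table.n_samples
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range for {n} samples")
    X = table.data.to_numpy().T
    Z = linkage(pdist(X, metric=metric), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return SampleClustering(
        linkage_matrix=Z,
        labels=pd.Series(labels, index=table.sample_ids, name="cluster"),
        k=k,
        method=method,
        metric=metric,
    )


def hotelling_ellipse(
    scores: pd.DataFrame, level: float = 0.95, n_points: int = 100
) -> np.ndarray:
    """Coordinates of the Hotelling confidence ellipse for a 2-component score
    plot (optional plot annotation; not part of the tested pipeline)."""
    pts = scores.iloc[:, :2].to_numpy()
    cov = np.cov(pts, rowvar=False)
    radius = np.sqrt(chi2.ppf(level, df=2))
    theta = np.linspace(0, 2 * np.pi, n_points)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    L = np.linalg.cholesky(cov)
    return (pts.mean(axis=0)[:, None] + radius * (L @ circle)).T
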