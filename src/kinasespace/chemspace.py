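"""Correlation-metric PCA of the descriptor panel.

Variables are centered and scaled to unit variance (sample SD) before the
decomposition, so loadings live on the unit correlation circle and the
variance decomposition is that of the correlation matrix.  Components
carry a fixed sign convention (the largest-magnitude loading of each
component is positive) so repeated fits are bit-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCA_VARIABLES",
    "PCAModel",
    "ClassEllipse",
    "Projection",
    "fit_pca",
    "project",
    "correlation_circle",
]

#: The 10-descriptor panel used for the chemical-space PCA.
PCA_VARIABLES = ["MW", "ClogP", "TPSA", "HBA", "HBD", "NRB", "NAR", "FCSP3", "MQN8", "MQN10"]


@dataclass
class PCAModel:
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: pd.DataFrame      # variable x component, orthonormal columns
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray
    contributions: pd.DataFrame  # variable x component, percent

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ClassEllipse:
    label: str
    center: np.ndarray         # (2,) mean in (PC1, PC2)
    covariance: np.ndarray     # (2, 2)
    level: float = 0.95

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of 2D points inside the confidence ellipse."""
        d = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        md2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return md2 <= stats.chi2.ppf(self.level, df=2)


@dataclass
class Projection:
    scores: pd.DataFrame
    class_ellipses: dict[str, ClassEllipse]


def _as_matrix(vectors, variables: Sequence[str]) -> pd.DataFrame:
    if isinstance(vectors, pd.DataFrame):
        missing = [v for v in variables if v not in vectors.columns]
        if missing:
            raise ValueError(f"unknown variables {missing}")
        return vectors[list(variables)]
    frame = pd.DataFrame([v.as_dict() for v in vectors])
    return _as_matrix(frame, variables)


def fit_pca(vectors, variables: Sequence[str] = PCA_VARIABLES) -> PCAModel:
    """Fit a correlation-metric PCA on the given descriptor variables.

    Components are ordered by decreasing eigenvalue; ``explained_ratio``
    sums to one over all components and per-component variable
    contributions (100·loading²) sum to 100%.
    """
    frame = _as_matrix(vectors, variables)
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than variables (n={n}, p={p})")
    if np.isnan(X).any():
        raise ValueError("missing values in descriptor matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sds) if s == 0]
    if constant:
        raise ValueError(f"constant variable(s) cannot be scaled to unit variance: {constant}")
    Z = (X - means) / sds
    # SVD of the standardized matrix: eigenvalues of the correlation matrix
    # are s^2/(n-1); right singular vectors are the loadings.
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    V = Vt.T
    # sign convention: largest-|loading| entry of each component positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    comp_names = [f"PC{k + 1}" for k in range(V.shape[1])]
    loadings = pd.DataFrame(V, index=list(variables), columns=comp_names)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAModel(
        variables=list(variables),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_ratio=eigenvalues / eigenvalues.sum(),
        contributions=contributions,
    )


def project(
    model: PCAModel,
    vectors,
    labels: Optional[Sequence[str]] = None,
    ellipse_level: float = 0.95,
) -> Projection:
    """Project descriptor vectors onto the fitted components.

    When class labels are given, a Gaussian confidence ellipse (chi-square
    quantile, 2 dof) of the (PC1, PC2) score cloud is fitted per class.
    """
    frame = _as_matrix(vectors, model.variables)
    Z = (frame.to_numpy(dtype=float) - model.means) / model.sds
    scores = pd.DataFrame(
        Z @ model.loadings.to_numpy(),
        index=frame.index,
        columns=list(model.loadings.columns),
    )
    ellipses: dict[str, ClassEllipse] = {}
    if labels is not None:
        labels = np.asarray([str(l) for l in labels])
        xy = scores.iloc[:, :2].to_numpy()
        for label in pd.unique(labels):
            pts = xy[labels == label]
            if len(pts) < 3:
                continue
            ellipses[label] = ClassEllipse(
                label=label,
                center=pts.mean(axis=0),
                covariance=np.cov(pts, rowvar=False),
                level=ellipse_level,
            )
    return Projection(scores=scores, class_ellipses=ellipses)


def correlation_circle(model: PCAModel) -> pd.DataFrame:
    """Variable coordinates on the PC1/PC2 correlation circle.

    Each coordinate is the correlation between a variable and a component,
    loading · sqrt(eigenvalue); all points lie within the unit disk.
    """
    if model.n_components < 2:
        raise ValueError("correlation circle needs at least two components")
    L = model.loadings.to_numpy()
    coords = L[:, :2] * np.sqrt(model.eigenvalues[:2])
    return pd.DataFrame(coords, index=model.loadings.index, columns=["x", "y"])
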