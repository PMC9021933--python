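"""PCA morphospaces, shape reconstruction along axes, topology comparison.

One morphospace per morphometric approach: trait ratios (TM, z-scored
features), aligned landmark coordinates (LA, covariance PCA) and elliptic
Fourier coefficients (OA, covariance PCA). Three axes are retained by
default for an even comparison between approaches.

Sign convention: each retained axis is flipped, if necessary, so that its
largest-magnitude loading is positive. This makes reported scores
reproducible; cross-approach correlations are sign-aware and therefore
document the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shapes import ShapeError


@dataclass
class Morphospace:
    """PCA ordination of individuals.

    ``scores`` are centred; ``loadings`` columns are orthonormal;
    ``explained`` are fractions of the *total* variance, non-increasing.
    ``mean_form`` (and ``scale`` for standardized PCA) allow reconstruction
    in the original variable space.
    """

    scores: np.ndarray          # (n, n_axes)
    loadings: np.ndarray        # (p, n_axes)
    explained: np.ndarray       # (n_axes,)
    mean_form: np.ndarray       # (p,)
    method_tag: str
    variable_names: list[str]
    ids: list[str] | None = None
    scale: np.ndarray | None = None  # per-variable std when standardized

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class TopologyComparison:
    """Pearson correlations among the retained axes of several morphospaces."""

    matrix: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def build_morphospace(
    features: np.ndarray,
    n_axes: int = 3,
    standardize: bool = False,
    method_tag: str = "",
    variable_names: list[str] | None = None,
    ids: list[str] | None = None,
) -> Morphospace:
    """Centred (optionally z-scored) PCA via singular value decomposition."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ShapeError("need a 2-D feature matrix with more than one individual")
    if np.isnan(x).any():
        raise ShapeError("feature matrix contains missing values")
    n, p = x.shape
    mean = x.mean(axis=0)
    xc = x - mean
    scale = None
    if standardize:
        scale = xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ShapeError("cannot z-score a constant feature column")
        xc = xc / scale
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_axes > rank:
        raise ShapeError(f"n_axes={n_axes} exceeds matrix rank {rank}")
    var = s ** 2 / (n - 1)
    explained_all = var / var.sum()
    scores = u[:, :n_axes] * s[:n_axes]
    loadings = vt[:n_axes].T
    # deterministic sign: largest-magnitude loading of each axis positive
    for j in range(n_axes):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    if variable_names is None:
        variable_names = [f"v{i+1}" for i in range(p)]
    return Morphospace(
        scores=scores,
        loadings=loadings,
        explained=explained_all[:n_axes],
        mean_form=mean,
        method_tag=method_tag,
        variable_names=list(variable_names),
        ids=list(ids) if ids is not None else None,
        scale=scale,
    )


def reconstruct_along_axis(space: Morphospace, axis: int, score: float) -> np.ndarray:
    """Variable-space vector at a given score along one retained axis.

    ``axis`` is 1-based (PC1 = 1). For landmark spaces reshape the result to
    (k, 2); for outline spaces reinterpret it as flattened EFT coefficients
    and invert (see :func:`fishmorph.pipeline.reconstruct_outline`).
    """
    if not 1 <= axis <= space.n_axes:
        raise ShapeError(f"axis {axis} out of range 1..{space.n_axes}")
    direction = space.loadings[:, axis - 1]
    if space.scale is not None:
        direction = direction * space.scale
    return space.mean_form + score * direction


def cross_correlate(spaces: list[Morphospace]) -> TopologyComparison:
    """Pairwise Pearson r among all retained score vectors of the spaces."""
    ref = spaces[0]
    for sp in spaces[1:]:
        if sp.scores.shape[0] != ref.scores.shape[0]:
            raise ShapeError("morphospaces cover different numbers of individuals")
        if sp.ids is not None and ref.ids is not None and sp.ids != ref.ids:
            raise ShapeError("morphospaces cover different individuals or order")
    cols, labels = [], []
    for sp in spaces:
        for j in range(sp.n_axes):
            cols.append(sp.scores[:, j])
            labels.append(f"PC{j+1}_{sp.method_tag or '?'}")
    matrix = np.corrcoef(np.stack(cols))
    return TopologyComparison(matrix=matrix, labels=labels)


def species_mean_scores(space: Morphospace, species_labels) -> pd.DataFrame:
    """Average individual scores per species (first-appearance order)."""
    labels = pd.Series(list(species_labels), dtype=object)
    if labels.isna().any() or (labels == "").any():
        bad = labels.index[labels.isna() | (labels == "")][0]
        raise ShapeError(f"individual at position {bad} has no species label")
    if len(labels) != space.scores.shape[0]:
        raise ShapeError("species labels do not match the number of individuals")
    df = pd.DataFrame(space.scores,
                      columns=[f"PC{j+1}" for j in range(space.n_axes)])
    df["species"] = labels.to_numpy()
    return df.groupby("species", sort=False).mean()
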