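"""Procrustes superimposition.

Two standardisations are provided, matching the two geometric-morphometric
routes through the pipeline:

* :func:`full_gpa` — full generalized Procrustes analysis of homologous
  landmark configurations. Each configuration is centred, scaled to unit
  centroid size, and iteratively rotated onto an evolving consensus until the
  consensus stabilises. Position, size and rotation are removed; reflections
  are never applied (all specimens are digitised facing the same way — a
  configuration whose optimal orthogonal map would be a reflection is aligned
  with the best proper rotation and a warning is emitted).

* :func:`anchor_align` — similarity alignment of a whole outline estimated on
  its five anchor pseudo-landmarks only. The best least-squares similarity
  (translation + isotropic scale + rotation, no reflection) mapping the
  anchors onto a reference is applied to every outline vertex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .shapes import LandmarkConfig, OutlineShape, ShapeError


@dataclass
class AlignedSet:
    """Result of a generalized Procrustes alignment."""

    configs: list[LandmarkConfig]
    mean_shape: LandmarkConfig
    iterations: int
    residual: float

    def coordinate_matrix(self) -> np.ndarray:
        """(n_individuals, 2k) matrix of aligned coordinates (x1,y1,x2,...)."""
        return np.stack([c.coords.ravel() for c in self.configs])

    def report(self) -> dict:
        return {"iterations": self.iterations, "residual": self.residual,
                "n_configs": len(self.configs)}


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared deviations from the centroid."""
    c = np.asarray(coords, dtype=float)
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum()))


def _center_scale(coords: np.ndarray, label: str = "") -> np.ndarray:
    c = coords - coords.mean(axis=0)
    size = np.sqrt((c ** 2).sum())
    if size < 1e-12:
        raise ShapeError(f"degenerate configuration '{label}': all points coincident")
    return c / size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||source @ R - target||_F (rows = points).

    Reflections are disallowed; if the unconstrained optimum is a reflection,
    the best proper rotation is returned and a warning emitted.
    """
    m = source.T @ target
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        warnings.warn(
            "optimal orthogonal map is a reflection; using best proper rotation",
            stacklevel=2,
        )
    corr = np.ones(len(s))
    corr[-1] = d
    return u @ np.diag(corr) @ vt


def full_gpa(
    configs: list[LandmarkConfig], tol: float = 1e-10, max_iter: int = 100
) -> AlignedSet:
    """Full generalized Procrustes alignment of landmark configurations.

    The consensus is initialised to the first configuration; iteration stops
    when the Frobenius change of the consensus drops below ``tol`` or after
    ``max_iter`` rounds. The residual is the summed squared deviation of the
    aligned configurations from the final consensus.
    """
    if len(configs) < 2:
        raise ShapeError("GPA needs at least 2 configurations")
    k = configs[0].coords.shape[0]
    names = configs[0].names
    for cfg in configs:
        if cfg.coords.shape[0] != k:
            raise ShapeError(
                f"mixed landmark counts: '{cfg.id}' has {cfg.coords.shape[0]}, expected {k}"
            )
    x = np.stack([_center_scale(c.coords, c.id) for c in configs])

    consensus = x[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(x)):
            x[i] = x[i] @ optimal_rotation(x[i], consensus)
        new = x.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new ** 2).sum())
        change = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if change < tol:
            break
    residual = float(((x - consensus) ** 2).sum())

    aligned = [
        LandmarkConfig(coords=x[i], names=names, id=c.id, species=c.species)
        for i, c in enumerate(configs)
    ]
    mean = LandmarkConfig(coords=consensus, names=names, id="consensus")
    return AlignedSet(configs=aligned, mean_shape=mean, iterations=iterations,
                      residual=residual)


# ---------------------------------------------------------------------------
# anchor-based similarity alignment of whole outlines
# ---------------------------------------------------------------------------

def similarity_transform(source: np.ndarray, target: np.ndarray):
    """Least-squares similarity (s, R, t) with x' = s * (x - mean_s) @ R + mean_t.

    Estimated a la Umeyama with the reflection branch disabled.
    Returns ``(scale, rotation, source_mean, target_mean)``.
    """
    s_mean = source.mean(axis=0)
    t_mean = target.mean(axis=0)
    sc = source - s_mean
    tc = target - t_mean
    denom = (sc ** 2).sum()
    if denom < 1e-12:
        raise ShapeError("degenerate anchor configuration")
    m = sc.T @ tc
    u, sv, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.ones(len(sv))
    corr[-1] = d
    if d < 0:
        warnings.warn(
            "anchor alignment would require a reflection; using proper rotation",
            stacklevel=2,
        )
    rotation = u @ np.diag(corr) @ vt
    scale = float((sv * corr).sum() / denom)
    return scale, rotation, s_mean, t_mean


def anchor_align(shape: OutlineShape, reference_anchors: np.ndarray) -> OutlineShape:
    """Align a whole outline onto reference anchor positions.

    The similarity transform is estimated on the shape's five anchors only and
    then applied to every outline vertex.
    """
    if shape.anchors is None:
        raise ShapeError(f"outline '{shape.id}': anchors are not set")
    ref = np.asarray(reference_anchors, dtype=float)
    if ref.shape != (5, 2):
        raise ShapeError("reference anchors must be a (5, 2) array")
    scale, rot, s_mean, t_mean = similarity_transform(shape.anchor_coords, ref)
    new = scale * (shape.points - s_mean) @ rot + t_mean
    return shape.with_points(new)


def anchor_reference(shapes: list[OutlineShape], tol: float = 1e-10,
                     max_iter: int = 100) -> np.ndarray:
    """Consensus (5, 2) anchor configuration for a batch of outlines.

    A mini-GPA on the anchor configurations: the population reference onto
    which each outline is then aligned.
    """
    configs = [
        LandmarkConfig(coords=s.anchor_coords, names=("a1", "a2", "a3", "a4", "a5"),
                       id=s.id)
        for s in shapes
    ]
    if len(configs) == 1:
        return _center_scale(configs[0].coords, configs[0].id)
    return full_gpa(configs, tol=tol, max_iter=max_iter).mean_shape.coords


def align_outlines(shapes: list[OutlineShape]) -> tuple[list[OutlineShape], np.ndarray]:
    """Anchor-Procrustes align a population of outlines to their consensus."""
    ref = anchor_reference(shapes)
    return [anchor_align(s, ref) for s in shapes], ref
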