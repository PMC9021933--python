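"""End-to-end morphospace construction for the three approaches.

Ties the stage modules together: measurements -> trait PCA (TM), landmark
configurations -> GPA -> coordinate PCA (LA), outlines -> anchor Procrustes
-> elliptic Fourier coefficients -> coefficient PCA (OA). Feature
standardisation follows standard practice: trait ratios are z-scored
(heterogeneous scales); aligned coordinates and Fourier coefficients are
centred only (covariance PCA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import efa as _efa
from .align import AlignedSet, align_outlines, full_gpa
from .morphospace import Morphospace, build_morphospace, reconstruct_along_axis
from .shapes import LandmarkConfig, OutlineShape, resample_outline
from .traits import TraitCatalog, compute_traits


def trait_morphospace(
    measurements: pd.DataFrame,
    catalog: TraitCatalog | None = None,
    n_axes: int = 3,
    standardize: bool = True,
) -> tuple[Morphospace, pd.DataFrame]:
    """TM: trait table -> z-scored PCA morphospace. Returns (space, traits)."""
    catalog = catalog or TraitCatalog()
    traits = compute_traits(measurements, catalog)
    x = traits[catalog.trait_names].to_numpy(float)
    ids = list(traits["id"].astype(str)) if "id" in traits else None
    space = build_morphospace(
        x, n_axes=n_axes, standardize=standardize, method_tag="TM",
        variable_names=catalog.trait_names, ids=ids,
    )
    return space, traits


def landmark_morphospace(
    configs: list[LandmarkConfig], n_axes: int = 3, standardize: bool = False
) -> tuple[Morphospace, AlignedSet]:
    """LA: configurations -> full GPA -> covariance PCA on aligned coordinates."""
    aligned = full_gpa(configs)
    x = aligned.coordinate_matrix()
    names = [f"{n}_{ax}" for n in configs[0].names for ax in ("x", "y")]
    space = build_morphospace(
        x, n_axes=n_axes, standardize=standardize, method_tag="LA",
        variable_names=names, ids=[c.id for c in configs],
    )
    return space, aligned


@dataclass
class OutlineAnalysis:
    """Side products of the OA route needed for reconstruction."""

    n_harmonics: int
    reference_anchors: np.ndarray
    aligned: list[OutlineShape]
    coefficients: np.ndarray


def outline_morphospace(
    outlines: list[OutlineShape],
    n_points: int = 300,
    threshold: float = 0.99,
    h_max: int = 32,
    n_axes: int = 3,
    standardize: bool = False,
    per_shape: bool = False,
) -> tuple[Morphospace, OutlineAnalysis]:
    """OA: anchor-align, resample, calibrate harmonics, PCA on coefficients."""
    resampled = [resample_outline(s, n_points) for s in outlines]
    aligned, ref = align_outlines(resampled)
    h_star = _efa.calibrate_harmonics(aligned, threshold=threshold, h_max=h_max,
                                      per_shape=per_shape)
    mat, names = _efa.coefficient_matrix(aligned, h_star)
    space = build_morphospace(
        mat, n_axes=n_axes, standardize=standardize, method_tag="OA",
        variable_names=names, ids=[s.id for s in outlines],
    )
    info = OutlineAnalysis(n_harmonics=h_star, reference_anchors=ref,
                           aligned=aligned, coefficients=mat)
    return space, info


def reconstruct_landmarks(space: Morphospace, axis: int, score: float) -> np.ndarray:
    """LA reconstruction along an axis as a (k, 2) landmark configuration."""
    return reconstruct_along_axis(space, axis, score).reshape(-1, 2)


def reconstruct_outline(space: Morphospace, axis: int, score: float,
                        n: int = 300) -> OutlineShape:
    """OA reconstruction along an axis, inverted to an outline polygon."""
    vec = reconstruct_along_axis(space, axis, score)
    coeffs = _efa.EFTCoefficients.from_flat(vec)
    return _efa.eft_inverse(coeffs, n)
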