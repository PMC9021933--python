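"""Elliptic Fourier analysis of closed outlines.

A closed contour is parameterised by cumulative chord length t in [0, T] and
its x(t), y(t) signals are decomposed into harmonic sums

    x(t) ~ A0 + sum_h a_h cos(2 pi h t / T) + b_h sin(2 pi h t / T)
    y(t) ~ C0 + sum_h c_h cos(2 pi h t / T) + d_h sin(2 pi h t / T)

with the Kuhl-Giardina closed-form coefficients for a piecewise-linear
contour. The positional constants A0/C0 are excluded throughout: outlines are
treated as centred, consistent with the preceding anchor-Procrustes
standardisation. No post-hoc ellipse normalisation is applied either —
orientation, scale and start point (the snout tip) are already standardised
upstream, and renormalising would discard real rotational differences.

Harmonic power P_h = (a_h^2 + b_h^2 + c_h^2 + d_h^2) / 2 measures each
harmonic's contribution; the truncation order is calibrated as the smallest H
reaching a target cumulative power fraction (0.99 by default) on average over
a collection of outlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shapes import OutlineShape, ShapeError


@dataclass
class EFTCoefficients:
    """Per-harmonic quadruples (a_h, b_h, c_h, d_h), h = 1..H."""

    harmonics: np.ndarray  # (H, 4)
    id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise ShapeError("harmonics must be an (H, 4) array")
        if len(self.harmonics) < 1:
            raise ShapeError("need at least one harmonic")
        if not np.all(np.isfinite(self.harmonics)):
            raise ShapeError("non-finite EFT coefficients")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def truncated(self, h: int) -> "EFTCoefficients":
        return EFTCoefficients(self.harmonics[:h], id=self.id, species=self.species)

    def flatten(self) -> np.ndarray:
        """1-D feature vector (a1, b1, c1, d1, a2, ...)."""
        return self.harmonics.ravel()

    @staticmethod
    def from_flat(vec: np.ndarray, id: str = "", species: str = "") -> "EFTCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4:
            raise ShapeError("flat coefficient vector length must be a multiple of 4")
        return EFTCoefficients(vec.reshape(-1, 4), id=id, species=species)


@dataclass
class HarmonicPowerProfile:
    power: np.ndarray
    cumulative_fraction: np.ndarray


def _chain(points: np.ndarray):
    closed = np.vstack([points, points[:1]])
    delta = np.diff(closed, axis=0)
    dt = np.hypot(delta[:, 0], delta[:, 1])
    if np.any(dt == 0):
        raise ShapeError("outline has zero-length segments")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return delta, dt, t, t[-1]


def parameter_mean(shape: OutlineShape) -> np.ndarray:
    """Arc-length-weighted mean point (the A0/C0 constants of the expansion)."""
    pts = shape.points
    closed = np.vstack([pts, pts[:1]])
    delta = np.diff(closed, axis=0)
    dt = np.hypot(delta[:, 0], delta[:, 1])
    mid = 0.5 * (closed[:-1] + closed[1:])
    return (mid * dt[:, None]).sum(axis=0) / dt.sum()


def eft_forward(shape: OutlineShape, n_harmonics: int) -> EFTCoefficients:
    """Kuhl-Giardina elliptic Fourier coefficients of a closed outline.

    Exact piecewise-linear integration over the polygon parameterised by
    cumulative chord length; traversal starts at the outline's first vertex
    (the snout tip for anchored outlines).
    """
    if n_harmonics < 1:
        raise ShapeError("need at least one harmonic")
    pts = shape.points
    if len(pts) < 2 * n_harmonics + 2:
        import warnings

        warnings.warn(
            f"outline has {len(pts)} points for {n_harmonics} harmonics; "
            "recommend >= 2H+2",
            stacklevel=2,
        )
    delta, dt, t, total = _chain(pts)
    h = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    omega = 2.0 * np.pi * h / total
    cos = np.cos(omega * t[None, :])  # (H, P+1)
    sin = np.sin(omega * t[None, :])
    dcos = cos[:, 1:] - cos[:, :-1]
    dsin = sin[:, 1:] - sin[:, :-1]
    const = total / (2.0 * (h[:, 0] ** 2) * np.pi ** 2)
    vx = delta[:, 0] / dt
    vy = delta[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    d = const * (dsin @ vy)
    return EFTCoefficients(np.column_stack([a, b, c, d]), id=shape.id,
                           species=shape.species)


def eft_inverse(coeffs: EFTCoefficients, n: int) -> OutlineShape:
    """Reconstruct an outline from truncated coefficients.

    Samples ``n`` points uniformly in the curve parameter; the curve is
    centred at the origin (the positional constants are excluded by
    construction). An all-zero coefficient set is degenerate and rejected.
    """
    if n < 8:
        raise ShapeError(f"reconstruction needs n >= 8 points, got {n}")
    harm = coeffs.harmonics
    if np.all(harm == 0.0):
        raise ShapeError("all-zero coefficients reconstruct to a single point")
    tau = np.arange(n) / n  # t / T in [0, 1)
    h = np.arange(1, len(harm) + 1)[:, None]
    ang = 2.0 * np.pi * h * tau[None, :]
    cos, sin = np.cos(ang), np.sin(ang)
    x = harm[:, 0] @ cos + harm[:, 1] @ sin
    y = harm[:, 2] @ cos + harm[:, 3] @ sin
    return OutlineShape(points=np.column_stack([x, y]), anchors=None,
                        id=coeffs.id, species=coeffs.species)


def harmonic_power(coeffs: EFTCoefficients) -> HarmonicPowerProfile:
    """Per-harmonic power and its cumulative fraction of the total."""
    power = 0.5 * (coeffs.harmonics ** 2).sum(axis=1)
    total = power.sum()
    if total <= 0:
        raise ShapeError("all-zero coefficients: cumulative power fraction undefined")
    cum = np.minimum(np.cumsum(power) / total, 1.0)
    cum[-1] = 1.0  # exact by normalisation
    return HarmonicPowerProfile(power=power, cumulative_fraction=cum)


def calibrate_harmonics(
    shapes: list[OutlineShape],
    threshold: float = 0.99,
    h_max: int = 32,
    per_shape: bool = False,
) -> int:
    """Smallest harmonic order reaching the target cumulative power fraction.

    Each outline is decomposed at ``h_max`` harmonics (the reference total
    power); the retained order H* is the smallest H whose cumulative power
    fraction reaches ``threshold`` on the mean profile across shapes, or on
    the worst shape when ``per_shape`` is set.
    """
    if not 0.0 < threshold < 1.0:
        raise ShapeError(f"threshold must be in (0, 1), got {threshold}")
    if not shapes:
        raise ShapeError("need at least one outline to calibrate")
    profiles = np.stack(
        [harmonic_power(eft_forward(s, h_max)).cumulative_fraction for s in shapes]
    )
    curve = profiles.min(axis=0) if per_shape else profiles.mean(axis=0)
    reached = np.nonzero(curve >= threshold)[0]
    if len(reached) == 0:
        return h_max
    return int(reached[0]) + 1


def coefficient_matrix(
    shapes: list[OutlineShape], n_harmonics: int
) -> tuple[np.ndarray, list[str]]:
    """(n_shapes, 4H) feature matrix and its column names (a1, b1, c1, d1, ...)."""
    mat = np.stack([eft_forward(s, n_harmonics).flatten() for s in shapes])
    names = [
        f"{letter}{h}" for h in range(1, n_harmonics + 1) for letter in "abcd"
    ]
    return mat, names
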