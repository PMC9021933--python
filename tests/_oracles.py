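"""Independent oracles used by unit and acceptance tests.

Each oracle computes its quantity by a route independent of the package
implementation: dense numeric integration, brute-force enumeration,
Monte-Carlo rejection sampling or hand formulas.
"""

from __future__ import annotations

import numpy as np


def eft_dense_integration(points: np.ndarray, n_harmonics: int,
                          substeps: int = 100_000) -> np.ndarray:
    """Fourier coefficients of the chord-length-parameterised contour by
    trapezoidal quadrature of the defining integrals."""
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    tq = np.linspace(0.0, total, substeps + 1)
    x = np.interp(tq, t, closed[:, 0])
    y = np.interp(tq, t, closed[:, 1])
    out = []
    for h in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * h * tq / total)
        s = np.sin(2 * np.pi * h * tq / total)
        out.append([
            2 / total * np.trapezoid(x * c, tq),
            2 / total * np.trapezoid(x * s, tq),
            2 / total * np.trapezoid(y * c, tq),
            2 / total * np.trapezoid(y * s, tq),
        ])
    return np.array(out)


def silhouette_brute_force(scores: np.ndarray, labels) -> np.ndarray:
    """O(n^2) loop implementation of Rousseeuw silhouette widths."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = list(labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([np.linalg.norm(scores[i] - scores[j]) for j in own])
        b = np.inf
        for g in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == g]
            b = min(b, np.mean([np.linalg.norm(scores[i] - scores[j])
                                for j in members]))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def hull_volume_monte_carlo(points: np.ndarray, n_samples: int = 1_000_000,
                            seed: int = 0) -> float:
    """Convex-hull volume by rejection sampling in the bounding box.

    A sample is inside the hull iff it satisfies every facet inequality of
    the Delaunay triangulation membership test done by hand via half-space
    checks on the hull facets.
    """
    from scipy.spatial import ConvexHull  # facet equations only

    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    box = np.prod(hi - lo)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, pts.shape[1]))
    # facet normal form: A x + b <= 0 inside
    a = hull.equations[:, :-1]
    b = hull.equations[:, -1]
    inside = np.all(samples @ a.T + b <= 1e-12, axis=1)
    return box * inside.mean()


def benjamini_yekutieli_hand(p_values) -> np.ndarray:
    """Step-up BY adjustment computed directly from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adjusted = np.empty(m)
    prev = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m * c / rank_from_top, prev, 1.0)
        adjusted[i] = val
        prev = val
    return adjusted


def full_procrustes_distance_grid(x: np.ndarray, y: np.ndarray,
                                  step: float = 1e-4) -> float:
    """min over rotation angle of ||x - y R||^2 after centring/unit-scaling."""

    def norm(z):
        z = z - z.mean(axis=0)
        return z / np.sqrt((z ** 2).sum())

    a, b = norm(np.asarray(x, float)), norm(np.asarray(y, float))
    theta = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(theta), np.sin(theta)
    # ||a - b R||^2 = 2 - 2 tr(R^T b^T a); expand for the 2x2 rotation
    m = b.T @ a
    trace_term = (m[0, 0] + m[1, 1]) * cos + (m[1, 0] - m[0, 1]) * sin
    return float((2.0 - 2.0 * trace_term).min())
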