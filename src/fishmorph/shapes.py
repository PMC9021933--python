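"""Geometric containers and outline geometry for 2-D fish form data.

All coordinates follow the mathematical convention: y increases upward and
closed polygons bounding a region are traversed counter-clockwise (CCW).
Image rasters, which are y-down, are flipped on ingestion (see
:mod:`fishmorph.io`).

An :class:`OutlineShape` stores the body contour as an ordered sequence of
vertices (the closing edge from the last vertex back to the first is
implicit). Five named *anchors* — pseudo-landmarks on the contour used for
Procrustes standardisation of whole outlines — are stored as indices into
the vertex array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import measure as _skmeasure

#: Canonical anchor names, in the order they are met when traversing the
#: outline CCW from the snout tip (ventral side first).
ANCHOR_NAMES = (
    "snout_tip",
    "pelvic_origin",
    "caudal_ventral",
    "caudal_dorsal",
    "dorsal_fin_origin",
)

#: Standard 12-landmark teleost scheme (configurable at generation time).
LANDMARK_NAMES = (
    "snout_tip",
    "mouth_corner",
    "eye_center",
    "dorsal_fin_origin",
    "dorsal_fin_end",
    "peduncle_dorsal",
    "caudal_base_upper",
    "caudal_base_lower",
    "peduncle_ventral",
    "anal_fin_origin",
    "pelvic_insertion",
    "pectoral_insertion",
)

#: Measurement schema: 17 linear measures (image units) and 3 areas (units^2).
LENGTH_NAMES = (
    "standard_length",
    "body_depth",
    "head_length",
    "head_depth",
    "snout_length",
    "eye_diameter",
    "eye_height",
    "mouth_height",
    "caudal_peduncle_depth",
    "caudal_peduncle_length",
    "caudal_fin_depth",
    "caudal_fin_length",
    "pectoral_fin_length",
    "pectoral_insertion_height",
    "dorsal_spine_length",
    "dorsal_fin_base_length",
    "pelvic_fin_length",
)
AREA_NAMES = ("body_area", "caudal_fin_area", "pectoral_fin_area")
MEASUREMENT_NAMES = LENGTH_NAMES + AREA_NAMES


class ShapeError(ValueError):
    """Raised when an input violates a geometric contract."""


@dataclass
class OutlineShape:
    """Closed 2-D contour of one individual.

    Parameters
    ----------
    points : (n, 2) float array
        Vertices of the closed polygon, CCW, last->first edge implicit.
    anchors : dict or None
        Mapping of anchor name -> vertex index. When set, must contain the
        five :data:`ANCHOR_NAMES`, with ``snout_tip`` first in traversal
        order.
    id, species : str
        Individual identifier and species label.
    """

    points: np.ndarray
    anchors: dict[str, int] | None = None
    id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ShapeError("outline points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ShapeError("outline needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ShapeError("outline contains non-finite coordinates")
        d = np.diff(self.points, axis=0)
        if np.any(np.all(d == 0.0, axis=1)):
            raise ShapeError("outline has consecutive duplicate points")
        if self.anchors is not None:
            missing = set(ANCHOR_NAMES) - set(self.anchors)
            if missing:
                raise ShapeError(f"missing anchors: {sorted(missing)}")
            idx = [int(self.anchors[k]) for k in ANCHOR_NAMES]
            if idx[0] != 0:
                raise ShapeError("snout_tip anchor must be at index 0")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ShapeError("anchors must be strictly increasing along the outline")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def anchor_coords(self) -> np.ndarray:
        """(5, 2) coordinates of the anchors in canonical order."""
        if self.anchors is None:
            raise ShapeError("anchors are not set")
        return self.points[[self.anchors[k] for k in ANCHOR_NAMES]]

    def with_points(self, points: np.ndarray) -> "OutlineShape":
        """Copy of this shape with the same metadata and new vertices."""
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class LandmarkConfig:
    """One individual's 12 homologous landmarks."""

    coords: np.ndarray
    names: tuple[str, ...] = LANDMARK_NAMES
    id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise ShapeError(
                f"landmark config '{self.id}': expected {len(self.names)} points, "
                f"got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError(f"landmark config '{self.id}': non-finite coordinates")
        # coincident landmarks indicate a digitisation error
        dif = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.hypot(dif[..., 0], dif[..., 1])
        np.fill_diagonal(dist, np.inf)
        if dist.min() == 0.0:
            raise ShapeError(f"landmark config '{self.id}': coincident landmarks")


@dataclass
class MeasurementRecord:
    """17 linear measures + 3 areas for one individual (arbitrary image unit)."""

    values: dict[str, float]
    id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ShapeError(
                    f"measurement '{name}' of individual '{self.id}' must be "
                    f"strictly positive and finite, got {v!r}"
                )


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive for CCW)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    d = np.roll(p, -1, axis=0) - p
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the vertex sequence oriented CCW (reversing if needed)."""
    points = np.asarray(points, dtype=float)
    if polygon_area(points) < 0:
        return points[::-1].copy()
    return points


def is_simple_polygon(points: np.ndarray) -> bool:
    """True if the closed polygon has no self-intersection."""
    from shapely.geometry import LinearRing

    try:
        return bool(LinearRing(np.asarray(points, dtype=float)).is_simple)
    except Exception:
        return False


# ---------------------------------------------------------------------------
# mask -> outline extraction
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component, deterministic tie-break.

    Ties on pixel count are broken by the smallest (row, column) of each
    component's topmost-leftmost pixel.
    """
    labels = _skmeasure.label(mask, connectivity=2)
    n = labels.max()
    best_key, best = None, None
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        rr, cc = np.nonzero(comp)
        top = rr.min()
        left = cc[rr == top].min()
        key = (-size, top, left)
        if best_key is None or key < best_key:
            best_key, best = key, comp
    return best


def extract_outline(mask: np.ndarray, id: str = "", species: str = "") -> OutlineShape:
    """Trace the crack boundary of the largest foreground blob of a binary mask.

    The boundary runs along pixel edges (marching-squares "crack" resolution,
    threshold 0.5), so for a hole-free blob the shoelace area of the returned
    polygon equals the number of foreground pixels exactly. Holes are ignored.
    The result is a closed CCW polygon in y-up coordinates; anchors are unset.

    Raises
    ------
    ShapeError
        If the mask has no foreground ("no foreground") or the largest
        component is smaller than 16 pixels ("degenerate shape").
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError("mask must be 2-D")
    fg = mask > 0
    if not fg.any():
        raise ShapeError("no foreground pixels in mask")
    comp = _largest_component(fg)
    if comp.sum() < 16:
        raise ShapeError("degenerate shape: largest component smaller than 16 pixels")

    h, w = comp.shape
    pad = np.zeros((h + 2, w + 2), dtype=bool)
    pad[1:-1, 1:-1] = comp

    # Directed crack edges with the foreground cell on the *left* of the
    # direction of travel; chaining them yields CCW loops in y-up coordinates.
    # Pixel (r, c) of the padded grid occupies x in [c-1, c] ... use original
    # indices: cell (r, c) spans x in [c, c+1], y in [h-1-r, h-r].
    edges: dict[tuple[float, float], list[tuple[float, float]]] = {}

    rr, cc = np.nonzero(comp)
    for r, c in zip(rr.tolist(), cc.tolist()):
        y_top = float(h - r)
        y_bot = float(h - r - 1)
        x_l = float(c)
        x_r = float(c + 1)
        if r == 0 or not comp[r - 1, c]:  # background above: go -x along top
            edges.setdefault((x_r, y_top), []).append((x_l, y_top))
        if r == h - 1 or not comp[r + 1, c]:  # background below: go +x along bottom
            edges.setdefault((x_l, y_bot), []).append((x_r, y_bot))
        if c == 0 or not comp[r, c - 1]:  # background left: go -y along left side
            edges.setdefault((x_l, y_top), []).append((x_l, y_bot))
        if c == w - 1 or not comp[r, c + 1]:  # background right: go +y
            edges.setdefault((x_r, y_bot), []).append((x_r, y_top))

    loops: list[np.ndarray] = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        prev_dir = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs.pop()
            else:
                # pinch vertex (8-connected diagonal): take the leftmost turn
                # relative to the incoming direction for a deterministic trace
                def turn(cand):
                    d = (cand[0] - cur[0], cand[1] - cur[1])
                    cross = prev_dir[0] * d[1] - prev_dir[1] * d[0]
                    dot = prev_dir[0] * d[0] + prev_dir[1] * d[1]
                    return np.arctan2(cross, dot)

                nxt = max(outs, key=turn)
                outs.remove(nxt)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            loop.append(cur)
        loops.append(np.array(loop, dtype=float))

    # outer boundary = loop with the largest positive (CCW) area; CW loops
    # are hole boundaries and are dropped
    outer = max(loops, key=polygon_area)
    return OutlineShape(points=outer, anchors=None, id=id, species=species)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_outline(shape: OutlineShape, n: int) -> OutlineShape:
    """Resample a closed outline to exactly ``n`` equal-arc-length points.

    The new start point is the ``snout_tip`` anchor when anchors are set,
    otherwise the original first vertex. Orientation is preserved and the
    remaining anchors are re-snapped to the nearest resampled vertex.
    """
    if n < 8:
        raise ShapeError(f"resampling needs n >= 8 points, got {n}")
    pts = shape.points
    if shape.anchors is not None:
        start = shape.anchors["snout_tip"]
        pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ShapeError("outline has zero perimeter")
    tq = np.arange(n) * (total / n)
    new = np.column_stack(
        [np.interp(tq, t, closed[:, 0]), np.interp(tq, t, closed[:, 1])]
    )

    anchors = None
    if shape.anchors is not None:
        # arc position of each original anchor, in the rolled frame
        n_old = len(shape.points)
        anchors = {}
        for name in ANCHOR_NAMES:
            old_idx = (shape.anchors[name] - shape.anchors["snout_tip"]) % n_old
            pos = t[old_idx]
            anchors[name] = int(np.argmin(np.abs(tq - pos)))
        anchors["snout_tip"] = 0
        # guard: snapping must preserve the strict ordering
        ordered = [anchors[k] for k in ANCHOR_NAMES]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ShapeError("resampling too coarse to keep anchors distinct")
    return replace(shape, points=new, anchors=anchors)
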