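"""Parametric synthetic fish: outlines, landmarks, measurements, assemblages.

The generator emulates the statistical structure of a lateral-view photo
collection of reef fish: each individual is a smooth closed body outline
with a forked caudal fin, 12 homologous landmarks and 5 outline anchors at
analytically known loci, and a complete 17-length + 3-area measurement
record derived from the same parameters — so trait recovery is exact up to
noise. Group structure (family/genus/feeding group) enters as parameter
shifts of controllable effect size ``delta``, species as intermediate random
effects, and individuals as within-species perturbations. An
exposure-stratified site x species occurrence matrix completes the inputs
the community analyses need.

Body model. With standard length SL = 1 and maximum body depth D = 1/E
(E = elongation), the half-depth profile along the body axis s in [0, 1] is

    h(s) = (D / 2) * rise(s) * taper(s) + fin bumps

where rise climbs from the pointed snout through the head (reaching
``head_depth_ratio`` at the end of the head) to 1 at the deepest station
s = 0.42, and taper descends smoothly to ``peduncle_width_ratio`` at the
caudal-fin base. Dorsal and anal fins are smooth sine-squared bumps whose
supports avoid the deepest station, so the measured body depth equals D
exactly. A forked caudal fin (length, depth and fork depth parameters) is
appended behind s = 1. Outline noise is Gaussian displacement along the
local outward normal, smoothed circularly along the contour (correlation
length 5% of the perimeter) so perturbed outlines stay smooth and simple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .groups import GroupingScheme
from .diversity import SiteAssemblage
from .shapes import (
    LANDMARK_NAMES,
    LandmarkConfig,
    MeasurementRecord,
    OutlineShape,
    ShapeError,
    resample_outline,
)

# fixed stations of the body plan (fractions of standard length)
_S_PEAK = 0.42          # deepest station
_DF_A, _DF_B = 0.50, 0.80   # dorsal fin support
_AF_SPAN = 0.18         # anal fin support length
_AF_HEIGHT = 0.10       # anal fin bump height (x body depth)
_PED_LEN = 0.12         # caudal peduncle length (x SL)
_PELVIC_S = 0.35        # pelvic insertion station


@dataclass
class FishParams:
    """Parameters of one fish body plan (ratios of SL or body depth D)."""

    elongation: float = 2.6            # SL / body depth, in (1.2, 6)
    head_length_ratio: float = 0.30    # head length / SL
    head_depth_ratio: float = 0.80     # depth at end of head / D
    snout_length_ratio: float = 0.10   # snout length / SL
    eye_size_ratio: float = 0.30      # eye diameter / head depth
    eye_height_ratio: float = 0.55     # eye centre height above axis / (D/2)
    mouth_height_ratio: float = 0.50   # body half-depth fraction at the mouth
    peduncle_width_ratio: float = 0.25  # peduncle depth / D
    caudal_fin_depth_ratio: float = 0.85  # caudal fin depth / D
    caudal_fin_length_ratio: float = 0.18  # caudal fin length / SL
    caudal_fork_depth: float = 0.45    # fork notch depth / caudal fin length
    dorsal_fin_height: float = 0.15    # dorsal bump height / D
    anal_fin_position: float = 0.62    # anal fin origin station / SL
    pelvic_fin_length: float = 0.10    # / SL
    pectoral_fin_length: float = 0.18  # / SL
    pectoral_insertion_height: float = 0.50  # above ventral extreme / D
    pectoral_fin_aspect: float = 2.2   # fin length^2 / fin area
    noise_sd: float = 0.0              # outline perturbation / SL
    seed: int = 0

    _RANGES = {
        "elongation": (1.2, 6.0),
        "head_length_ratio": (0.12, 0.40),
        "head_depth_ratio": (0.4, 1.0),
        "snout_length_ratio": (0.03, 0.2),
        "eye_size_ratio": (0.05, 0.6),
        "eye_height_ratio": (0.1, 0.9),
        "mouth_height_ratio": (0.1, 0.9),
        "peduncle_width_ratio": (0.08, 0.5),
        "caudal_fin_depth_ratio": (0.3, 1.6),
        "caudal_fin_length_ratio": (0.08, 0.35),
        "caudal_fork_depth": (0.0, 0.8),
        "dorsal_fin_height": (0.0, 0.45),
        "anal_fin_position": (0.52, 0.76),
        "pelvic_fin_length": (0.04, 0.25),
        "pectoral_fin_length": (0.06, 0.35),
        "pectoral_insertion_height": (0.2, 0.85),
        "pectoral_fin_aspect": (1.2, 4.0),
        "noise_sd": (0.0, 0.08),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ShapeError(
                    f"parameter '{name}' = {v} outside valid range [{lo}, {hi}]"
                )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bump(s: np.ndarray, a: float, b: float) -> np.ndarray:
    inside = (s > a) & (s < b)
    out = np.zeros_like(s)
    out[inside] = np.sin(np.pi * (s[inside] - a) / (b - a)) ** 2
    return out


def _base_profile(s: np.ndarray, p: FishParams) -> np.ndarray:
    """Fin-free half-depth profile (D/2) * rise(s) * taper(s)."""
    depth = 1.0 / p.elongation
    sh = p.head_length_ratio
    hd = p.head_depth_ratio
    rise = np.where(
        s <= sh,
        hd * np.sin(0.5 * np.pi * np.clip(s / sh, 0.0, 1.0)),
        hd + (1.0 - hd) * _smoothstep((s - sh) / (_S_PEAK - sh)),
    )
    taper = 1.0 - (1.0 - p.peduncle_width_ratio) * _smoothstep(
        (s - _S_PEAK) / (1.0 - _S_PEAK)
    )
    return 0.5 * depth * rise * taper


def _h_top(s: np.ndarray, p: FishParams) -> np.ndarray:
    depth = 1.0 / p.elongation
    return _base_profile(s, p) + depth * p.dorsal_fin_height * _bump(s, _DF_A, _DF_B)


def _h_bot(s: np.ndarray, p: FishParams) -> np.ndarray:
    depth = 1.0 / p.elongation
    a = p.anal_fin_position
    return _base_profile(s, p) + depth * _AF_HEIGHT * _bump(s, a, min(a + _AF_SPAN, 0.96))


def _caudal_fin_path(p: FishParams, n_seg: int = 12) -> np.ndarray:
    """Fin vertices from the ventral base to the dorsal base (exclusive ends)."""
    depth = 1.0 / p.elongation
    half_base = 0.5 * depth * p.peduncle_width_ratio
    cfl = p.caudal_fin_length_ratio
    half_tip = 0.5 * depth * p.caudal_fin_depth_ratio
    notch_x = 1.0 + cfl * (1.0 - p.caudal_fork_depth)
    corners = np.array([
        [1.0, -half_base],
        [1.0 + cfl, -half_tip],
        [notch_x, 0.0],
        [1.0 + cfl, half_tip],
        [1.0, half_base],
    ])
    pts = []
    for a, b in zip(corners[:-1], corners[1:]):
        frac = np.linspace(0.0, 1.0, n_seg, endpoint=False)[:, None]
        pts.append(a + frac * (b - a))
    path = np.vstack(pts)
    return path[1:]  # drop the ventral base point (already on the body path)


def _analytic_outline(p: FishParams, n_side: int = 400) -> tuple[np.ndarray, dict]:
    """Noise-free dense outline (CCW from snout) + anchor vertex indices."""
    s = np.linspace(0.0, 1.0, n_side + 1)
    ventral = np.column_stack([s, -_h_bot(s, p)])      # includes snout (0,0)
    fin = _caudal_fin_path(p)
    s_back = s[::-1][1:-1]                             # dorsal, excludes s=1 and s=0
    dorsal = np.column_stack([s_back, _h_top(s_back, p)])
    points = np.vstack([ventral, fin, dorsal])

    def nearest(target_xy):
        return int(np.argmin(((points - np.asarray(target_xy)) ** 2).sum(axis=1)))

    depth = 1.0 / p.elongation
    half_base = 0.5 * depth * p.peduncle_width_ratio
    anchors = {
        "snout_tip": 0,
        "pelvic_origin": nearest((_PELVIC_S, -_h_bot(np.array([_PELVIC_S]), p)[0])),
        "caudal_ventral": nearest((1.0, -half_base)),
        "caudal_dorsal": nearest((1.0, half_base)),
        "dorsal_fin_origin": nearest((_DF_A, _h_top(np.array([_DF_A]), p)[0])),
    }
    return points, anchors


def _analytic_landmarks(p: FishParams) -> np.ndarray:
    depth = 1.0 / p.elongation
    half_base = 0.5 * depth * p.peduncle_width_ratio
    sn = p.snout_length_ratio
    eye_x = sn + 0.5 * (p.head_length_ratio - sn)
    eye_y = 0.5 * depth * p.eye_height_ratio * 0.9
    afp = p.anal_fin_position
    s_ped = 1.0 - 0.5 * _PED_LEN

    def hb(x):
        return _h_bot(np.array([x]), p)[0]

    def ht(x):
        return _h_top(np.array([x]), p)[0]

    coords = {
        "snout_tip": (0.0, 0.0),
        "mouth_corner": (sn, -hb(sn)),
        "eye_center": (eye_x, eye_y),
        "dorsal_fin_origin": (_DF_A, ht(_DF_A)),
        "dorsal_fin_end": (_DF_B, ht(_DF_B)),
        "peduncle_dorsal": (s_ped, ht(s_ped)),
        "caudal_base_upper": (1.0, half_base),
        "caudal_base_lower": (1.0, -half_base),
        "peduncle_ventral": (s_ped, -hb(s_ped)),
        "anal_fin_origin": (afp, -hb(afp)),
        "pelvic_insertion": (_PELVIC_S, -hb(_PELVIC_S)),
        "pectoral_insertion": (
            p.head_length_ratio,
            p.pectoral_insertion_height * depth - 0.5 * depth,
        ),
    }
    return np.array([coords[name] for name in LANDMARK_NAMES])


def _analytic_measurements(p: FishParams) -> dict[str, float]:
    depth = 1.0 / p.elongation

    def hb(x):
        return _h_bot(np.array([x]), p)[0]

    # body area by dense quadrature of the analytic profiles (deterministic)
    s = np.linspace(0.0, 1.0, 2001)
    body_area = float(np.trapezoid(_h_top(s, p) + _h_bot(s, p), s))
    cfl = p.caudal_fin_length_ratio
    half_base = 0.5 * depth * p.peduncle_width_ratio
    half_tip = 0.5 * depth * p.caudal_fin_depth_ratio
    # fin = trapezoid(base..tips) minus the fork notch triangle
    fin_area = float(
        cfl * (half_base + half_tip) - cfl * p.caudal_fork_depth * half_tip
    )
    eye_y = 0.5 * depth * p.eye_height_ratio * 0.9
    vals = {
        "standard_length": 1.0,
        "body_depth": depth,
        "head_length": p.head_length_ratio,
        "head_depth": p.head_depth_ratio * depth,
        "snout_length": p.snout_length_ratio,
        "eye_diameter": p.eye_size_ratio * p.head_depth_ratio * depth,
        "eye_height": eye_y + 0.5 * depth,
        "mouth_height": max(2.0 * hb(p.snout_length_ratio) * p.mouth_height_ratio,
                            1e-6),
        "caudal_peduncle_depth": p.peduncle_width_ratio * depth,
        "caudal_peduncle_length": _PED_LEN,
        "caudal_fin_depth": p.caudal_fin_depth_ratio * depth,
        "caudal_fin_length": cfl,
        "pectoral_fin_length": p.pectoral_fin_length,
        "pectoral_insertion_height": p.pectoral_insertion_height * depth,
        "dorsal_spine_length": max(p.dorsal_fin_height, 0.02) * depth,
        "dorsal_fin_base_length": _DF_B - _DF_A,
        "pelvic_fin_length": p.pelvic_fin_length,
        "body_area": body_area,
        "caudal_fin_area": fin_area,
        "pectoral_fin_area": p.pectoral_fin_length ** 2 / p.pectoral_fin_aspect,
    }
    return vals


def _clearance(points: np.ndarray, exclude: int = 12) -> np.ndarray:
    """Distance from each vertex to the nearest non-neighbouring vertex.

    Measures how close the opposite side of the curve is (e.g. across a thin
    caudal-fin lobe); noise displacement is capped by it so perturbed
    outlines stay simple.
    """
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :])
    band = np.minimum(band, n - band)
    dist[band <= exclude] = np.inf
    return dist.min(axis=1)


def _correlated_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Circularly smoothed Gaussian noise, unit-calibrated then scaled by sd."""
    raw = rng.normal(size=n)
    width = max(int(round(0.05 * n)), 1)
    k = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    k /= k.sum()
    sm = np.convolve(np.concatenate([raw[-3 * width:], raw, raw[:3 * width]]), k,
                     mode="same")[3 * width: 3 * width + n]
    std = sm.std()
    if std > 0:
        sm = sm / std
    return sd * sm


def generate_fish(
    params: FishParams,
    n_points: int = 300,
    rng: np.random.Generator | None = None,
    id: str = "",
    species: str = "",
    with_mask: bool = False,
    mask_size: int = 256,
):
    """Generate one fish: (outline, landmarks, measurements[, mask]).

    Deterministic given ``params.seed`` (or an explicit ``rng``). At
    ``noise_sd = 0`` the outline, landmarks and measurements all derive from
    the same analytic body plan.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    dense, anchors = _analytic_outline(params)

    if params.noise_sd > 0:
        tang = np.roll(dense, -1, axis=0) - np.roll(dense, 1, axis=0)
        norms = np.column_stack([tang[:, 1], -tang[:, 0]])
        norms /= np.linalg.norm(norms, axis=1, keepdims=True)
        cap = 0.4 * _clearance(dense)  # keep the two sides of thin lobes apart
        from .shapes import is_simple_polygon

        sd = params.noise_sd
        for attempt in range(6):
            disp = np.clip(_correlated_noise(len(dense), sd, rng), -cap, cap)
            candidate = dense + disp[:, None] * norms
            if is_simple_polygon(candidate):
                dense = candidate
                break
            sd *= 0.5  # rare: shrink amplitude rather than emit a crossing
        else:
            raise ShapeError("could not generate a simple noisy outline")

    shape = OutlineShape(points=dense, anchors=anchors, id=id, species=species)
    shape = resample_outline(shape, n_points)

    lm = _analytic_landmarks(params)
    if params.noise_sd > 0:
        lm = lm + rng.normal(scale=params.noise_sd, size=lm.shape)
    landmarks = LandmarkConfig(coords=lm, id=id, species=species)

    vals = _analytic_measurements(params)
    if params.noise_sd > 0:
        jitter = rng.normal(scale=params.noise_sd, size=len(vals))
        vals = {
            k: max(v * (1.0 + j), 1e-9)
            for (k, v), j in zip(vals.items(), jitter)
        }
    record = MeasurementRecord(values=vals, id=id, species=species)

    if not with_mask:
        return shape, landmarks, record, None
    mask = rasterize_outline(shape, mask_size)
    return shape, landmarks, record, mask


def rasterize_outline(shape: OutlineShape, size: int = 256) -> np.ndarray:
    """Binary mask (y-down raster) of the filled outline polygon."""
    from skimage.draw import polygon as _sk_polygon

    pts = shape.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = (hi - lo).max()
    margin = 0.05
    scale = (1.0 - 2 * margin) * size / span
    xy = (pts - lo) * scale + margin * size
    rows = size - 1 - xy[:, 1]  # y-up -> raster rows
    cols = xy[:, 0]
    rr, cc = _sk_polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


# ---------------------------------------------------------------------------
# assemblages
# ---------------------------------------------------------------------------

#: parameters that vary between and within species, with the scale ("span")
#: used for the between/within standard deviations
_VARYING = (
    "elongation",
    "head_length_ratio",
    "head_depth_ratio",
    "eye_size_ratio",
    "eye_height_ratio",
    "peduncle_width_ratio",
    "caudal_fin_depth_ratio",
    "caudal_fork_depth",
    "dorsal_fin_height",
    "anal_fin_position",
    "pectoral_fin_length",
    "pectoral_insertion_height",
)


@dataclass
class AssemblageDesign:
    """Design of a group-structured synthetic fish collection."""

    n_species: int = 40
    n_individuals: int = 111
    scheme: GroupingScheme | None = None
    group_effects: dict[str, dict[str, float]] | None = None
    effect_size: float = 1.0            # delta, scales all group effects
    between_species_sd: float = 0.06    # fraction of each parameter's span
    within_species_sd: float = 0.02
    noise_sd: float = 0.01              # outline/measurement noise per fish
    n_points: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ShapeError("effect_size must be >= 0")
        if self.between_species_sd <= 0 or self.within_species_sd <= 0:
            raise ShapeError("variance parameters must be positive")
        if self.scheme is not None:
            sizes: dict[str, int] = {}
            for g in self.scheme.species_to_group.values():
                sizes[g] = sizes.get(g, 0) + 1
            if min(sizes.values()) < 2:
                raise ShapeError("every group needs at least 2 species")


@dataclass
class FishDataset:
    """All per-individual products of one synthetic assemblage."""

    outlines: list[OutlineShape]
    landmarks: list[LandmarkConfig]
    measurements: pd.DataFrame
    meta: pd.DataFrame            # id, species, genus, family, feeding groups
    species_params: dict[str, FishParams]

    @property
    def species_labels(self) -> list[str]:
        return list(self.meta["species"])


def default_scheme(n_species: int = 40, n_groups: int = 3,
                   name: str = "family") -> GroupingScheme:
    """Balanced species -> group mapping sp001.. into n_groups groups."""
    mapping = {
        f"sp{i + 1:03d}": f"{name[0].upper()}{i % n_groups + 1}"
        for i in range(n_species)
    }
    return GroupingScheme(name=name, species_to_group=mapping)


#: a "strong" group-effect preset: groups separate mainly in elongation,
#: secondarily in head/peduncle form — the dominant axes of real reef fish
STRONG_EFFECTS: dict[str, dict[str, float]] = {
    "F1": {"elongation": -0.9, "head_depth_ratio": 0.10,
           "dorsal_fin_height": 0.08, "peduncle_width_ratio": -0.05},
    "F2": {"elongation": 0.0, "caudal_fork_depth": 0.15,
           "eye_size_ratio": 0.08},
    "F3": {"elongation": 0.9, "head_length_ratio": 0.04,
           "peduncle_width_ratio": 0.08, "head_depth_ratio": -0.08},
}


def _species_sizes(n_species: int, n_individuals: int) -> list[int]:
    base = n_individuals // n_species
    extra = n_individuals - base * n_species
    return [base + (1 if i < extra else 0) for i in range(n_species)]


def generate_assemblage(design: AssemblageDesign) -> FishDataset:
    """Generate a full group-structured dataset, reproducible per seed.

    Species parameter vectors = defaults + delta * group effect +
    between-species noise; individuals add within-species noise. Parameters
    are clipped to their valid ranges.
    """
    rng = np.random.default_rng(design.seed)
    scheme = design.scheme or default_scheme(design.n_species)
    effects = design.group_effects
    if effects is None:
        groups = sorted(set(scheme.species_to_group.values()))
        effects = {g: STRONG_EFFECTS.get(g, {}) for g in groups}
    base = FishParams()
    spans = {k: hi - lo for k, (lo, hi) in FishParams._RANGES.items()}

    species = list(scheme.species_to_group)
    if len(species) != design.n_species:
        raise ShapeError("scheme species count does not match the design")
    sizes = _species_sizes(design.n_species, design.n_individuals)

    # taxonomy: 11 genera spread over 3 families when shapes allow, else a
    # round-robin nesting consistent with the grouping
    n_genera = min(11, design.n_species)
    genus_of = {sp: f"gen{(i % n_genera) + 1:02d}" for i, sp in enumerate(species)}
    family_of = {sp: scheme.species_to_group[sp] for sp in species}

    species_params: dict[str, FishParams] = {}
    for sp in species:
        eff = effects.get(scheme.species_to_group[sp], {})
        kw = {}
        for name in _VARYING:
            lo, hi = FishParams._RANGES[name]
            shift = design.effect_size * eff.get(name, 0.0)
            val = (
                getattr(base, name)
                + shift
                + rng.normal(0.0, design.between_species_sd * spans[name])
            )
            kw[name] = float(np.clip(val, lo + 1e-6, hi - 1e-6))
        for name, shift in eff.items():
            if name not in FishParams._RANGES:
                raise ShapeError(f"group effect references unknown parameter '{name}'")
        species_params[sp] = replace(base, noise_sd=design.noise_sd, **kw)

    outlines, landmarks, rows, meta_rows = [], [], [], []
    counter = 0
    for sp, size in zip(species, sizes):
        sp_par = species_params[sp]
        for _ in range(size):
            counter += 1
            ind_id = f"ind{counter:04d}"
            kw = {}
            for name in _VARYING:
                lo, hi = FishParams._RANGES[name]
                val = getattr(sp_par, name) + rng.normal(
                    0.0, design.within_species_sd * spans[name]
                )
                kw[name] = float(np.clip(val, lo + 1e-6, hi - 1e-6))
            par = replace(sp_par, **kw)
            shape, lm, rec, _ = generate_fish(
                par, n_points=design.n_points, rng=rng, id=ind_id, species=sp
            )
            outlines.append(shape)
            landmarks.append(lm)
            rows.append({"id": ind_id, "species": sp} | rec.values)
            meta_rows.append({
                "id": ind_id, "species": sp,
                "genus": genus_of[sp], "family": family_of[sp],
            })
    measurements = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows)
    return FishDataset(
        outlines=outlines, landmarks=landmarks, measurements=measurements,
        meta=meta, species_params=species_params,
    )


def feeding_schemes(dataset: FishDataset,
                    seed: int = 0) -> list[GroupingScheme]:
    """Three feeding-functional groupings over the dataset's species.

    The bioerosion and turf-interaction schemes are nested in family (so
    they carry morphological signal); the macroalgae scheme is assigned
    independently at random (no signal), mirroring the contrast the
    community analyses are meant to resolve.
    """
    rng = np.random.default_rng(seed)
    species = list(dict.fromkeys(dataset.meta["species"]))
    fam = {sp: dataset.meta.loc[dataset.meta["species"] == sp, "family"].iloc[0]
           for sp in species}
    families = sorted(set(fam.values()))
    bio_map, turf_map, mac_map = {}, {}, {}
    bio_levels = ["excavator", "scraper", "non_bioeroder"]
    turf_levels = ["intensive_farmer", "cropper", "remover", "non_consumer"]
    mac_levels = ["browser", "incidental", "non_consumer"]
    for i, sp in enumerate(species):
        fi = families.index(fam[sp])
        bio_map[sp] = bio_levels[(fi + i % 2) % len(bio_levels)]
        turf_map[sp] = turf_levels[(fi * 2 + i % 2) % len(turf_levels)]
        mac_map[sp] = mac_levels[rng.integers(len(mac_levels))]
    # guarantee >= 2 species per group for the random scheme
    counts: dict[str, int] = {}
    for g in mac_map.values():
        counts[g] = counts.get(g, 0) + 1
    for level in mac_levels:
        while counts.get(level, 0) < 2:
            sp = species[int(rng.integers(len(species)))]
            if counts.get(mac_map[sp], 0) > 2:
                counts[mac_map[sp]] -= 1
                mac_map[sp] = level
                counts[level] = counts.get(level, 0) + 1
    return [
        GroupingScheme("bioerosion", bio_map),
        GroupingScheme("turf_interaction", turf_map),
        GroupingScheme("macroalgae_interaction", mac_map),
    ]


def generate_occurrence(
    species: list[str],
    n_sites: int = 12,
    strata_sizes: tuple[int, int, int] = (4, 5, 3),
    occupancy: tuple[float, float, float] = (0.75, 0.6, 0.45),
    species_scores: pd.DataFrame | None = None,
    filtering_strength: float = 0.0,
    seed: int = 0,
    max_retries: int = 100,
) -> SiteAssemblage:
    """Exposure-stratified Bernoulli occurrence matrix.

    ``strata_sizes`` gives the number of low/moderate/high-exposure sites;
    ``occupancy`` the per-stratum presence probability. A positive
    ``filtering_strength`` biases occupancy against species far from the
    morphospace centroid (environmental filtering); requires
    ``species_scores``. Sites are redrawn (bounded retries) until every site
    hosts at least 4 species.
    """
    if sum(strata_sizes) != n_sites:
        raise ShapeError("strata sizes must sum to n_sites")
    if any(not 0 <= p <= 1 for p in occupancy):
        raise ShapeError("occupancy probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    levels = ["low"] * strata_sizes[0] + ["moderate"] * strata_sizes[1] + \
        ["high"] * strata_sizes[2]
    site_ids = [chr(ord("A") + i) for i in range(n_sites)]
    extremity = np.zeros(len(species))
    if filtering_strength > 0:
        if species_scores is None:
            raise ShapeError("filtering requires species_scores")
        pts = species_scores.loc[species].to_numpy(float)
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        extremity = d / (d.max() if d.max() > 0 else 1.0)
    rows = []
    for site, level in zip(site_ids, levels):
        p_base = occupancy[("low", "moderate", "high").index(level)]
        p = np.clip(p_base * np.exp(-filtering_strength * extremity), 0.0, 1.0)
        for attempt in range(max_retries):
            draw = (rng.random(len(species)) < p).astype(int)
            if draw.sum() >= 4:
                break
        else:
            raise ShapeError(
                f"site '{site}': could not draw >= 4 species in {max_retries} tries"
            )
        rows.append(draw)
    occurrence = pd.DataFrame(rows, index=site_ids, columns=list(species))
    exposure = pd.Series(levels, index=site_ids, name="exposure")
    return SiteAssemblage(occurrence=occurrence, exposure=exposure)
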