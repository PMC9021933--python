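"""Group differentiation in a morphospace: silhouettes and a permutation null.

The silhouette width of individual i (Rousseeuw) is

    s(i) = (b(i) - a(i)) / max(a(i), b(i))

with a(i) the mean Euclidean distance to the other members of i's group
(tightness) and b(i) the smallest mean distance to the members of any other
group (separation). Members of singleton groups get s = 0 by convention, as
does the degenerate a = b = 0 case. The overall statistic for a grouping is
the mean of s over all individuals.

Significance is assessed with a species-level permutation null: group labels
are shuffled *among species* (conspecific individuals always share a null
label, and group sizes in species are preserved), the overall silhouette is
recomputed, and a one-sided (greater) p-value is estimated with the
add-one-correction p = (1 + #{null >= observed}) / (1 + B). Families of
tests are adjusted with the Benjamini-Yekutieli false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .shapes import ShapeError


@dataclass
class GroupingScheme:
    """A named species -> group mapping (taxonomic or feeding-functional)."""

    name: str
    species_to_group: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.species_to_group.values())) < 2:
            raise ShapeError(f"scheme '{self.name}' needs at least 2 groups")

    def labels_for(self, species_seq) -> np.ndarray:
        out = []
        for sp in species_seq:
            if sp not in self.species_to_group:
                raise ShapeError(f"scheme '{self.name}': species '{sp}' unmapped")
            out.append(self.species_to_group[sp])
        return np.asarray(out, dtype=object)


@dataclass
class SilhouetteResult:
    per_individual_s: np.ndarray
    per_group_mean: dict[str, float]
    overall_s: float
    null_distribution: np.ndarray | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None


def _codes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels, dtype=object)
    uniq = list(dict.fromkeys(labels))
    lut = {g: i for i, g in enumerate(uniq)}
    return np.array([lut[g] for g in labels]), uniq


def _silhouette_from_dist(dist: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    n = len(codes)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    sums = dist @ onehot                     # (n, g) summed distance to each group
    own = counts[codes]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), codes] / (own - 1)
    other = sums / counts[None, :]
    other[np.arange(n), codes] = np.inf
    b = other.min(axis=1)
    s = np.zeros(n)
    ok = own > 1
    denom = np.maximum(a, b)
    nz = ok & (denom > 0)
    s[nz] = (b[nz] - a[nz]) / denom[nz]
    return s


def silhouette(scores: np.ndarray, labels) -> SilhouetteResult:
    """Silhouette widths of a grouping on Euclidean morphospace distances."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    codes, uniq = _codes(labels)
    if len(uniq) < 2:
        raise ShapeError("silhouette needs at least 2 groups")
    if len(codes) != scores.shape[0]:
        raise ShapeError("labels do not match the number of individuals")
    dist = squareform(pdist(scores))
    s = _silhouette_from_dist(dist, codes, len(uniq))
    per_group = {g: float(s[codes == i].mean()) for i, g in enumerate(uniq)}
    return SilhouetteResult(
        per_individual_s=s, per_group_mean=per_group, overall_s=float(s.mean())
    )


def permutation_test(
    scores: np.ndarray,
    species_labels,
    scheme: GroupingScheme,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SilhouetteResult:
    """Species-level permutation null for the overall silhouette width.

    Each replicate permutes the species -> group assignment (preserving group
    sizes at species level) and propagates it to individuals; the observed
    overall silhouette is compared one-sided (greater).
    """
    if n_permutations < 99:
        raise ShapeError(
            f"need at least 99 permutations for a stable p-value, got {n_permutations}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species_labels = np.asarray(list(species_labels), dtype=object)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T

    observed = silhouette(scores, scheme.labels_for(species_labels))
    dist = squareform(pdist(scores))

    species = list(dict.fromkeys(species_labels))
    group_of = [scheme.species_to_group[sp] for sp in species]
    sp_index = {sp: i for i, sp in enumerate(species)}
    indiv_sp = np.array([sp_index[sp] for sp in species_labels])

    null = np.empty(n_permutations)
    group_arr = np.asarray(group_of, dtype=object)
    for b in range(n_permutations):
        shuffled = group_arr[rng.permutation(len(group_arr))]
        codes, uniq = _codes(shuffled[indiv_sp])
        null[b] = _silhouette_from_dist(dist, codes, len(uniq)).mean()
    p_raw = (1.0 + np.sum(null >= observed.overall_s)) / (1.0 + n_permutations)
    observed.null_distribution = null
    observed.p_raw = float(p_raw)
    return observed


def adjust_fdr_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (harmonic correction, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ShapeError("p-values must lie in (0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def differentiation_table(
    spaces: dict[str, np.ndarray],
    species_labels,
    schemes: list[GroupingScheme],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Silhouette + permutation p for every scheme x approach, BY-adjusted.

    ``spaces`` maps approach tag -> (n, n_axes) score matrix over the same
    individuals. The FDR family is all scheme x approach tests of the call.
    Rows carry ``s``, ``p_raw``, ``p_adjusted`` and a significance flag at
    adjusted p < .01.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for scheme in schemes:
        for tag, scores in spaces.items():
            res = permutation_test(scores, species_labels, scheme,
                                   n_permutations=n_permutations, seed=rng)
            rows.append({"scheme": scheme.name, "approach": tag,
                         "s": res.overall_s, "p_raw": res.p_raw})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adjust_fdr_by(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < 0.01
    return df
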