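"""Community-scale morphological diversity from species scores + occurrence.

Species-aggregated morphospace positions are combined with a site x species
presence/absence matrix to give two indices per site:

* richness — percentage of the species pool's convex-hull volume occupied by
  the hull of the species present at the site (100 when a site hosts every
  pool species). Sites with fewer than 4 species present, or coplanar
  points, have no 3-D hull: their richness is reported as missing (NaN) with
  a warning, never as zero.
* dispersion — mean Euclidean distance of the present species from their
  unweighted centroid (0 for a single-species site).

Site rankings from different approaches are compared by Spearman rank
correlation, and indices are compared across wave-exposure levels with
one-way ANOVA (plus Shapiro-Wilk on residuals, a residual-vs-fitted table
for homoscedasticity inspection, and Tukey HSD follow-up under a
Bonferroni-corrected threshold).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy import stats

from .shapes import ShapeError


@dataclass
class SiteAssemblage:
    """Site x species presence/absence with a wave-exposure label per site."""

    occurrence: pd.DataFrame            # sites x species in {0, 1}
    exposure: pd.Series                 # site -> {low, moderate, high}
    exposure_energy: pd.Series | None = None  # site -> J/m^3, optional

    def __post_init__(self) -> None:
        occ = self.occurrence
        vals = occ.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ShapeError("occurrence entries must be 0/1")
        if (vals.sum(axis=1) < 1).any():
            empty = occ.index[vals.sum(axis=1) < 1][0]
            raise ShapeError(f"site '{empty}' has no species present")
        missing = set(occ.index) - set(self.exposure.index)
        if missing:
            raise ShapeError(f"sites without exposure label: {sorted(missing)}")

    @property
    def site_ids(self) -> list:
        return list(self.occurrence.index)

    def species_at(self, site) -> list:
        row = self.occurrence.loc[site]
        return list(row.index[row.astype(bool)])


def _hull_volume(points: np.ndarray) -> float | None:
    if len(points) < points.shape[1] + 1:
        return None
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return None


def morphological_richness(
    species_scores: pd.DataFrame, assemblage: SiteAssemblage
) -> pd.Series:
    """Percent of the pool convex-hull volume filled by each site's species."""
    pts = species_scores.to_numpy(dtype=float)
    pool_volume = _hull_volume(pts)
    if pool_volume is None or pool_volume <= 0:
        raise ShapeError("species pool hull is degenerate")
    out = {}
    for site in assemblage.site_ids:
        present = assemblage.species_at(site)
        missing = set(present) - set(species_scores.index)
        if missing:
            raise ShapeError(f"site '{site}': species without scores {sorted(missing)}")
        vol = _hull_volume(species_scores.loc[present].to_numpy(dtype=float))
        if vol is None:
            warnings.warn(
                f"site '{site}': fewer than 4 affinely independent species; "
                "richness undefined", stacklevel=2,
            )
            out[site] = np.nan
        else:
            out[site] = 100.0 * vol / pool_volume
    return pd.Series(out, name="richness")


def morphological_dispersion(
    species_scores: pd.DataFrame, assemblage: SiteAssemblage
) -> pd.Series:
    """Mean distance of each site's species from their centre of gravity."""
    out = {}
    for site in assemblage.site_ids:
        pts = species_scores.loc[assemblage.species_at(site)].to_numpy(dtype=float)
        centroid = pts.mean(axis=0)
        out[site] = float(np.linalg.norm(pts - centroid, axis=1).mean())
    return pd.Series(out, name="dispersion")


def rank_congruence(index_a: pd.Series, index_b: pd.Series,
                    exact_max: int = 8) -> tuple[float, float]:
    """Spearman rank correlation between two site indices.

    Average ranks are used for ties. The two-sided p-value is an exact
    permutation probability for n <= ``exact_max`` sites and the
    t-approximation above that. Sites with a missing index value on either
    side are dropped pairwise.
    """
    a, b = index_a.align(index_b, join="inner")
    if set(index_a.index) != set(index_b.index):
        raise ShapeError("site sets differ between the two indices")
    keep = a.notna() & b.notna()
    a, b = a[keep].to_numpy(float), b[keep].to_numpy(float)
    n = len(a)
    if n < 4:
        raise ShapeError(f"need at least 4 sites, got {n}")
    rho, p_approx = stats.spearmanr(a, b)
    if n > exact_max:
        return float(rho), float(p_approx)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    obs = abs(np.corrcoef(ra, rb)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(ra, rb[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return float(rho), count / total


@dataclass
class ExposureReport:
    """One-way ANOVA of a diversity index across exposure levels."""

    f_statistic: float
    p_value: float
    df: tuple[int, int]
    shapiro_statistic: float
    shapiro_p: float
    residual_table: pd.DataFrame        # fitted vs residual per site
    bonferroni_alpha: float
    significant: bool
    tukey: pd.DataFrame | None          # Tukey HSD pairwise adjusted p


def exposure_comparison(index: pd.Series, exposure: pd.Series,
                        n_tests: int = 6) -> ExposureReport:
    """ANOVA of a site index across exposure levels with diagnostics.

    ``n_tests`` sets the Bonferroni-corrected significance threshold
    0.05 / n_tests (default 6 = 2 indices x 3 approaches); a significant
    ANOVA is followed by Tukey HSD pairwise comparisons.
    """
    idx, expo = index.align(exposure, join="inner")
    keep = idx.notna()
    idx, expo = idx[keep], expo[keep]
    levels = list(dict.fromkeys(expo))
    groups = [idx[expo == lev].to_numpy(float) for lev in levels]
    if len(groups) < 2:
        raise ShapeError("need at least 2 exposure levels")
    for lev, g in zip(levels, groups):
        if len(g) < 2:
            raise ShapeError(
                f"exposure level '{lev}' has a single site: no within-group variance"
            )
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # all groups identical
        f, p = 0.0, 1.0
    n = sum(len(g) for g in groups)
    df = (len(groups) - 1, n - len(groups))
    fitted = expo.map({lev: g.mean() for lev, g in zip(levels, groups)}).astype(float)
    residuals = idx - fitted
    table = pd.DataFrame({"fitted": fitted, "residual": residuals,
                          "exposure": expo})
    sh_stat, sh_p = stats.shapiro(residuals.to_numpy(float))
    alpha = 0.05 / n_tests
    significant = bool(p < alpha)
    tukey = None
    if len(groups) >= 2:
        res = stats.tukey_hsd(*groups)
        rows = []
        for i, j in itertools.combinations(range(len(groups)), 2):
            rows.append({
                "level_a": levels[i], "level_b": levels[j],
                "difference": groups[i].mean() - groups[j].mean(),
                "p_adjusted": float(res.pvalue[i, j]),
            })
        tukey = pd.DataFrame(rows)
    return ExposureReport(
        f_statistic=float(f), p_value=float(p), df=df,
        shapiro_statistic=float(sh_stat), shapiro_p=float(sh_p),
        residual_table=table, bonferroni_alpha=alpha,
        significant=significant, tukey=tukey,
    )
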