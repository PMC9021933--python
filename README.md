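# fishmorph

Three complementary characterisations of fish body form — and what each one
sees.

Ecologists quantify the morphology of fishes in three traditions:
**traditional morphometrics (TM)**, unitless ratios of linear and area
measurements with functional interpretations (elongation = SL/BD, caudal
peduncle throttling, eye size, fin aspect ratios, ...); **landmark analysis
(LA)**, geometric morphometrics on homologous point configurations after a
full generalized Procrustes alignment removes position, size and rotation;
and **outline analysis (OA)**, which describes the whole body contour with
an elliptic Fourier transform after a Procrustes standardisation on five
contour anchors. The choice of approach can change ecological conclusions —
which body axes dominate, how distinct taxonomic or feeding-functional
groups appear, and which reef sites count as morphological diversity
hotspots. `fishmorph` implements all three pipelines side by side on the
same individuals, plus the downstream comparative statistics, so that the
congruence (and divergence) of the approaches is itself measurable.

## What it computes

* **Shape ingestion** — binary silhouette masks (PNG) traced to crack-boundary
  polygons whose shoelace area equals the foreground pixel count; TPS/CSV
  landmark files; measurement tables; equal-arc-length outline resampling.
* **Superimposition** — full generalized Procrustes analysis (GPA) for
  12-landmark configurations; anchor-based similarity alignment of whole
  outlines onto a population consensus (reflections disallowed in both).
* **Elliptic Fourier analysis** — Kuhl–Giardina coefficients by exact
  piecewise-linear integration, harmonic power P_h = (a_h²+b_h²+c_h²+d_h²)/2,
  truncation calibrated to 99% cumulative power, inverse reconstruction.
* **Trait ratios** — a declarative 13-trait catalog over 17 lengths + 3 areas;
  editing the catalog is a data change, not a code change.
* **Morphospaces** — one PCA per approach (3 axes retained), shape
  reconstruction along axes, Pearson cross-correlation of the score vectors.
* **Group differentiation** — Rousseeuw silhouette widths per taxonomic or
  feeding-functional grouping, with a species-level permutation null
  (conspecifics always share a null label) and Benjamini–Yekutieli FDR
  adjustment.
* **Community diversity** — species-aggregated scores × site occurrence:
  morphological richness (% of the species pool's convex-hull volume) and
  dispersion (mean distance to the assemblage centroid), Spearman rank
  congruence between approaches, and ANOVA across wave-exposure levels with
  Shapiro–Wilk and Tukey HSD diagnostics.
* **Synthetic fish** — a parametric generator (smooth body profile, forked
  caudal fin, 12 landmarks, 5 anchors, closed-form measurements, masks) with
  species/group random-effect structure of controllable effect size, and
  exposure-stratified occurrence matrices. Every stage of the package is
  testable without any external data.

## Worked example

```python
import numpy as np
import fishmorph as fm
from fishmorph.synthetic import AssemblageDesign, generate_assemblage

ds = generate_assemblage(AssemblageDesign(seed=1))   # 111 fish, 40 species
tm, _ = fm.trait_morphospace(ds.measurements)
la, _ = fm.landmark_morphospace(ds.landmarks)
oa, info = fm.outline_morphospace(ds.outlines)

print("harmonics retained at 99% power:", info.n_harmonics)
for tag, sp in (("TM", tm), ("LA", la), ("OA", oa)):
    print(f"{tag} explained variance (%):", np.round(100 * sp.explained, 1))
comp = fm.cross_correlate([tm, la, oa]).to_frame()
print("r(PC1_TM, PC1_LA) =", round(comp.loc["PC1_TM", "PC1_LA"], 2))

fam = fm.GroupingScheme("family", dict(zip(ds.meta["species"], ds.meta["family"])))
res = fm.permutation_test(tm.scores, ds.species_labels, fam,
                          n_permutations=999, seed=1)
print(f"family silhouette (TM): s = {res.overall_s:.2f}, p = {res.p_raw:.3f}")
```

prints

```
harmonics retained at 99% power: 4
TM explained variance (%): [50.1 14.1 10.7]
LA explained variance (%): [80.   5.   2.3]
OA explained variance (%): [92.8  2.9  1.7]
r(PC1_TM, PC1_LA) = 0.93
family silhouette (TM): s = 0.48, p = 0.001
```

PC1 of every approach is the elongation axis (hence the strong TM–LA
correlation), the synthetic outlines are smooth enough that 4 harmonics carry
99% of the power, and the three families built into the generator separate
with a silhouette width of 0.48 — far beyond what random species-to-family
relabelings produce (p ≈ 1/1000).

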