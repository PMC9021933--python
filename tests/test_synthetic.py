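"""The synthetic fish generator: determinism, internal consistency, designs."""

from __future__ import annotations

import numpy as np
import pytest

from fishmorph import FishParams, ShapeError, generate_fish, polygon_area
from fishmorph.shapes import is_simple_polygon
from fishmorph.synthetic import (
    AssemblageDesign,
    generate_assemblage,
    generate_occurrence,
    rasterize_outline,
)


class TestGenerateFish:
    def test_deterministic_given_seed(self):
        p = FishParams(noise_sd=0.02, seed=11)
        a = generate_fish(p)
        b = generate_fish(p)
        np.testing.assert_array_equal(a[0].points, b[0].points)
        np.testing.assert_array_equal(a[1].coords, b[1].coords)
        assert a[2].values == b[2].values

    def test_parameter_out_of_range_named(self):
        with pytest.raises(ShapeError, match="elongation"):
            FishParams(elongation=9.0)

    def test_noise_free_elongation_exact(self):
        p = FishParams(elongation=3.1, noise_sd=0.0)
        _, _, rec, _ = generate_fish(p)
        assert rec.values["standard_length"] / rec.values["body_depth"] == \
            pytest.approx(3.1, abs=1e-6)

    def test_anchors_lie_on_outline(self):
        shape, *_ = generate_fish(FishParams(noise_sd=0.0, seed=1))
        coords = shape.anchor_coords
        # anchors are vertices of the polygon by construction
        for c in coords:
            d = np.linalg.norm(shape.points - c, axis=1).min()
            assert d < 1e-9

    @pytest.mark.parametrize("elongation", [1.5, 2.6, 4.5])
    @pytest.mark.parametrize("noise", [0.0, 0.02])
    def test_outline_is_simple_polygon(self, elongation, noise):
        p = FishParams(elongation=elongation, noise_sd=noise, seed=4)
        shape, *_ = generate_fish(p)
        assert is_simple_polygon(shape.points)

    def test_measurements_consistent_with_digitised_outline(self):
        # internal consistency: lengths/areas re-measured on the generated
        # noise-free outline agree with the closed-form record within 1%
        p = FishParams(noise_sd=0.0, seed=2)
        shape, lm, rec, _ = generate_fish(p, n_points=2000)
        pts = shape.points
        sl_meas = pts[shape.anchors["caudal_ventral"]][0] - pts[0][0]
        assert sl_meas == pytest.approx(rec.values["standard_length"], rel=0.01)

        def depth_at(x):  # vertical extent of the body at station x <= 1
            body = pts[pts[:, 0] <= 1.0 + 1e-9]
            upper = body[body[:, 1] > 0]
            lower = body[body[:, 1] < 0]
            yu = np.interp(x, *zip(*sorted(zip(upper[:, 0], upper[:, 1]))))
            yl = np.interp(x, *zip(*sorted(zip(lower[:, 0], lower[:, 1]))))
            return yu - yl

        assert depth_at(0.42) == pytest.approx(rec.values["body_depth"], rel=0.01)
        ped = pts[shape.anchors["caudal_dorsal"]][1] - \
            pts[shape.anchors["caudal_ventral"]][1]
        assert ped == pytest.approx(rec.values["caudal_peduncle_depth"], rel=0.01)
        # body + caudal fin area vs polygon area
        total = rec.values["body_area"] + rec.values["caudal_fin_area"]
        assert polygon_area(pts) == pytest.approx(total, rel=0.01)

    def test_mask_rasterization_round_trip(self):
        from fishmorph import extract_outline

        shape, *_ = generate_fish(FishParams(noise_sd=0.0, seed=3))
        mask = rasterize_outline(shape, size=256)
        back = extract_outline(mask)
        # area recovered within rasterisation error (diagonal pinch pixels
        # may fall outside the traced outer boundary)
        assert polygon_area(back.points) == pytest.approx(mask.sum(), rel=1e-3)
        assert mask.sum() > 1000


class TestAssemblage:
    def test_reproducible_per_seed(self):
        a = generate_assemblage(AssemblageDesign(n_species=6, n_individuals=12,
                                                 seed=9))
        b = generate_assemblage(AssemblageDesign(n_species=6, n_individuals=12,
                                                 seed=9))
        np.testing.assert_array_equal(a.outlines[3].points, b.outlines[3].points)
        assert a.measurements.equals(b.measurements)

    def test_counts_and_nesting(self):
        ds = generate_assemblage(AssemblageDesign(seed=0))
        assert len(ds.outlines) == 111
        assert ds.meta["species"].nunique() == 40
        assert ds.meta["genus"].nunique() == 11
        assert ds.meta["family"].nunique() == 3
        # species nest in a single genus and family
        assert (ds.meta.groupby("species")["family"].nunique() == 1).all()

    def test_single_individual_species_valid(self):
        ds = generate_assemblage(AssemblageDesign(n_species=6, n_individuals=6,
                                                  seed=1))
        assert len(ds.outlines) == 6
        assert ds.meta.groupby("species").size().eq(1).all()

    def test_unknown_effect_parameter_rejected(self):
        from fishmorph.synthetic import default_scheme

        design = AssemblageDesign(
            n_species=6, n_individuals=12,
            scheme=default_scheme(6),
            group_effects={"F1": {"wingspan": 1.0}, "F2": {}, "F3": {}},
            seed=0,
        )
        with pytest.raises(ShapeError, match="wingspan"):
            generate_assemblage(design)

    def test_delta_zero_mean_silhouette_near_zero(self):
        from fishmorph import silhouette, trait_morphospace

        vals = []
        for seed in range(1, 21):
            ds = generate_assemblage(
                AssemblageDesign(n_species=30, n_individuals=90,
                                 effect_size=0.0, seed=seed))
            space, _ = trait_morphospace(ds.measurements)
            fam = dict(zip(ds.meta["species"], ds.meta["family"]))
            labels = [fam[s] for s in ds.species_labels]
            vals.append(silhouette(space.scores, labels).overall_s)
        assert abs(np.mean(vals)) < 0.1

    def test_strong_preset_separates_groups_on_all_pipelines(self):
        from fishmorph import (
            landmark_morphospace,
            outline_morphospace,
            silhouette,
            trait_morphospace,
        )

        ds = generate_assemblage(AssemblageDesign(seed=1, effect_size=1.0))
        fam = dict(zip(ds.meta["species"], ds.meta["family"]))
        labels = [fam[s] for s in ds.species_labels]
        tm, _ = trait_morphospace(ds.measurements)
        la, _ = landmark_morphospace(ds.landmarks)
        oa, _ = outline_morphospace(ds.outlines)
        for space in (tm, la, oa):
            assert silhouette(space.scores, labels).overall_s >= 0.4


class TestOccurrence:
    def test_all_ones_when_certain(self):
        species = [f"sp{i}" for i in range(10)]
        asm = generate_occurrence(species, occupancy=(1.0, 1.0, 1.0), seed=0)
        assert asm.occurrence.to_numpy().all()
        assert asm.exposure.value_counts().to_dict() == \
            {"moderate": 5, "low": 4, "high": 3}

    def test_reproducible(self):
        species = [f"sp{i}" for i in range(12)]
        a = generate_occurrence(species, occupancy=(0.5, 0.5, 0.5), seed=7)
        b = generate_occurrence(species, occupancy=(0.5, 0.5, 0.5), seed=7)
        assert a.occurrence.equals(b.occurrence)

    def test_every_site_has_at_least_four_species(self):
        species = [f"sp{i}" for i in range(15)]
        asm = generate_occurrence(species, occupancy=(0.35, 0.35, 0.35), seed=3)
        assert (asm.occurrence.sum(axis=1) >= 4).all()

    def test_stratum_occupancy_ordering(self):
        species = [f"sp{i}" for i in range(30)]
        counts = {"low": [], "moderate": [], "high": []}
        for seed in range(100):
            asm = generate_occurrence(species, occupancy=(0.9, 0.6, 0.3),
                                      seed=seed)
            per_site = asm.occurrence.sum(axis=1)
            for level in counts:
                counts[level].append(
                    per_site[asm.exposure == level].mean())
        assert np.mean(counts["low"]) > np.mean(counts["moderate"]) > \
            np.mean(counts["high"])

    def test_bad_strata_rejected(self):
        with pytest.raises(ShapeError, match="sum"):
            generate_occurrence(["a", "b", "c", "d"], n_sites=10,
                                strata_sizes=(4, 5, 3), seed=0)
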