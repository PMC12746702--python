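"""Closed-form shape features, invariances, and the feature catalog."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from ovomorph.images import LabelMask
from ovomorph.morphometry import FeatureMatrix, extract_features, nc_ratio_summary
from ovomorph.segmentation import CellIndex, CellRecord
from ovomorph.synthetic import simulate_feature_table
from ovomorph import young_population


def masks_to_features(nuc: np.ndarray, cel: np.ndarray, pixel_size=1.0) -> FeatureMatrix:
    index = CellIndex(
        [CellRecord(cell_id=1, nucleus_label=1, cell_label=1)],
        LabelMask(nuc.astype(np.int32), "nucleus", pixel_size),
        LabelMask(cel.astype(np.int32), "cell", pixel_size),
    )
    return extract_features(index, index.nuclei, index.cells)


def disk_masks(radius=20, center=(48, 48), shape=(96, 96), nuc_radius=8):
    cel = np.zeros(shape)
    rr, cc = draw_disk(center, radius, shape=shape)
    cel[rr, cc] = 1
    nuc = np.zeros(shape)
    rr, cc = draw_disk(center, nuc_radius, shape=shape)
    nuc[rr, cc] = 1
    return nuc, cel


class TestClosedForms:
    def test_disk_features(self):
        nuc, cel = disk_masks(radius=20)
        fm = masks_to_features(nuc, cel)
        row = fm.features.iloc[0]
        assert row["cell_area"] == pytest.approx(np.pi * 400, rel=0.03)
        assert 0.92 <= row["cell_circularity"] <= 1.05
        for h in range(2, 8):
            assert row[f"cell_fourier_amp_{h}"] <= 0.02

    def test_ellipse_features(self):
        # semi-axes 40 and 10: aspect ratio 4, eccentricity sqrt(1-1/16)=0.968
        cel = np.zeros((128, 128))
        rr, cc = draw_ellipse(64, 64, 10, 40, shape=(128, 128))
        cel[rr, cc] = 1
        nuc = np.zeros((128, 128))
        rr, cc = draw_ellipse(64, 64, 5, 8, shape=(128, 128))
        nuc[rr, cc] = 1
        fm = masks_to_features(nuc, cel)
        row = fm.features.iloc[0]
        assert row["cell_aspect_ratio"] == pytest.approx(4.0, rel=0.05)
        assert row["cell_eccentricity"] == pytest.approx(0.9682, rel=0.02)

    def test_nc_ratio_exact(self):
        # nucleus 300 px inside a 1200 px cell at 1 um/px: ratio 0.25 exactly
        cel = np.zeros((64, 64))
        cel[10:50, 10:40] = 1  # 40 x 30 = 1200
        nuc = np.zeros((64, 64))
        nuc[20:40, 15:30] = 1  # 20 x 15 = 300
        fm = masks_to_features(nuc, cel)
        assert fm.features.iloc[0]["nc_area_ratio"] == 0.25

    def test_pixel_size_scales_areas(self):
        nuc, cel = disk_masks()
        a1 = masks_to_features(nuc, cel, pixel_size=1.0).features.iloc[0]["cell_area"]
        a2 = masks_to_features(nuc, cel, pixel_size=0.5).features.iloc[0]["cell_area"]
        assert a2 == pytest.approx(a1 / 4.0, rel=1e-9)


class TestInvariances:
    def test_translation_invariance_exact(self):
        nuc1, cel1 = disk_masks(center=(40, 40))
        nuc2, cel2 = disk_masks(center=(52, 47))
        f1 = masks_to_features(nuc1, cel1).features
        f2 = masks_to_features(nuc2, cel2).features
        for col in f1.columns:
            assert f1.iloc[0][col] == pytest.approx(f2.iloc[0][col], abs=1e-12), col

    @pytest.mark.parametrize("angle_deg", [20, 33, 77])
    def test_rotation_invariance(self, angle_deg):
        # area, circularity, solidity and Hu moments stable when the same
        # ellipse is rasterized at a different orientation
        def make(rot):
            cel = np.zeros((128, 128))
            rr, cc = draw_ellipse(64, 64, 18, 30, shape=(128, 128), rotation=rot)
            cel[rr, cc] = 1
            nuc = np.zeros((128, 128))
            rr, cc = draw_ellipse(64, 64, 8, 12, shape=(128, 128), rotation=rot)
            nuc[rr, cc] = 1
            return nuc, cel

        f1 = masks_to_features(*make(0.0)).features.iloc[0]
        f2 = masks_to_features(*make(np.deg2rad(angle_deg))).features.iloc[0]
        for col in ("cell_area", "cell_circularity", "cell_solidity", "cell_hu_1"):
            assert f2[col] == pytest.approx(f1[col], rel=0.03), col

    def test_scaling_behaviour(self):
        f1 = masks_to_features(*disk_masks(radius=15, nuc_radius=6)).features.iloc[0]
        f2 = masks_to_features(*disk_masks(radius=30, nuc_radius=12)).features.iloc[0]
        assert f2["cell_area"] == pytest.approx(4.0 * f1["cell_area"], rel=0.03)
        assert f2["cell_perimeter"] == pytest.approx(2.0 * f1["cell_perimeter"], rel=0.03)

    def test_irregularity_raises_curvature_stats(self):
        # matched synthetic shapes: rougher boundary -> more bending energy
        from ovomorph import LogNormalParam, PopulationSpec, SceneSpec, SubtypeSpec, render_scene, sample_population

        vals = {}
        for irr in (0.0, 0.3):
            st = SubtypeSpec(
                nuclear_radius=LogNormalParam(8.0, 1.0), cell_radius=LogNormalParam(20.0, 1.0),
                elongation=LogNormalParam(1.0, 1.0), boundary_irregularity=irr,
            )
            pop = PopulationSpec(name=f"irr{irr}", subtypes=(st,), subtype_weights=(1.0,))
            params = sample_population(pop, 6, seed=5)
            params["boundary_irregularity"] = irr
            scene = SceneSpec(image_shape=(512, 512), pixel_size=1.0, n_cells=6, seed=5)
            _, truth = render_scene(params, scene)
            index = CellIndex(
                [CellRecord(cell_id=c.label, nucleus_label=c.label, cell_label=c.label) for c in truth.cells],
                LabelMask(truth.nucleus_labels, "nucleus", 1.0),
                LabelMask(truth.cell_labels, "cell", 1.0),
            )
            fm = extract_features(index, index.nuclei, index.cells)
            vals[irr] = fm.features[["cell_curvature_sd", "cell_bending_energy", "cell_curvature_mean_abs"]].mean()
        assert vals[0.3]["cell_curvature_sd"] > vals[0.0]["cell_curvature_sd"]
        assert vals[0.3]["cell_bending_energy"] > vals[0.0]["cell_bending_energy"]


class TestCatalog:
    def test_catalog_size_and_uniqueness(self, segmented_scene):
        import pandas as pd

        from ovomorph.segmentation import CurationParams, curate, quantify_intensity

        image, _, nuclei, cells = segmented_scene
        index, _ = curate(nuclei, cells, CurationParams(max_neighbors=100))
        intensity = quantify_intensity(image, index, ["actin", "vimentin"])
        intensity = intensity.join(quantify_intensity(image, index, ["dna"], compartment="nucleus"))
        fm = extract_features(index, index.nuclei, index.cells, intensity=intensity)
        assert len(fm.catalog) >= 100
        assert len(set(fm.catalog.names)) == len(fm.catalog)
        assert list(fm.features.columns) == fm.catalog.names
        assert not fm.features.isna().any().any()
        assert (fm.features["nucleus_area"] > 0).all()
        assert (fm.features["cell_area"] > 0).all()

    def test_catalog_hash_stable(self):
        f1 = masks_to_features(*disk_masks())
        f2 = masks_to_features(*disk_masks(center=(40, 50)))
        assert f1.catalog.content_hash() == f2.catalog.content_hash()

    def test_degenerate_cell_dropped_and_counted(self):
        nuc = np.zeros((32, 32))
        cel = np.zeros((32, 32))
        nuc[10, 10] = 1  # single-pixel nucleus: degenerate contour
        cel[8:20, 8:20] = 1
        fm = masks_to_features(nuc, cel)
        assert fm.n_cells == 0
        assert fm.n_dropped == 1


class TestNcRatioSummary:
    def test_identical_groups_null(self):
        fm = simulate_feature_table([young_population()], 200, seed=0)
        half = np.arange(fm.n_cells) % 2 == 0
        fm.metadata["group"] = np.where(half, "a", "b")
        res = nc_ratio_summary(fm)
        # random split halves of one population: no real difference
        assert abs(res["tests"]["nc_area_ratio"]["t"]) < 3.0
        assert res["tests"]["nc_area_ratio"]["p"] > 0.001

    def test_ratio_mean_in_unit_interval(self):
        fm = simulate_feature_table([young_population()], 100, seed=1)
        res = nc_ratio_summary(fm)
        means = res["summary"]["nc_area_ratio"]["mean"]
        assert ((means > 0) & (means <= 1)).all()

    def test_single_cell_group_flagged(self):
        fm = simulate_feature_table([young_population()], 3, seed=2)
        fm.metadata["group"] = ["a", "a", "b"]
        res = nc_ratio_summary(fm)
        assert np.isnan(res["summary"].loc["b", ("nc_area_ratio", "std")])
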