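"""Quantification-stage contracts: projection, segmentation, spot
detection and feature extraction on constructed and rendered fields."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from lipotrace import (
    ImageStack,
    SimConfig,
    detect_spots,
    extract_features,
    max_project,
    reference_subject,
    render_image,
    segment_cells,
    simulate_well_cells,
)
from lipotrace.imaging import SpotParams
from lipotrace import io as ltio
from lipotrace import pipeline


def disk(img, cy, cx, r, level):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] += level
    return img


class TestMaxProject:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(max_project(img[None]), img)
        assert np.array_equal(max_project(img), img)

    def test_elementwise_max(self):
        stack = np.array([[[1, 5], [2, 0]], [[3, 1], [0, 4]]], dtype=float)
        assert np.array_equal(max_project(stack), [[3, 5], [2, 4]])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        stack = rng.random((5, 7, 9))
        expected = np.zeros((7, 9))
        for i in range(7):
            for j in range(9):
                expected[i, j] = max(stack[z, i, j] for z in range(5))
        assert np.allclose(max_project(stack), expected)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))

    def test_projected_stack_equals_rendered_single_slice_structures(self):
        cfg = SimConfig(seed=0, n_slices=3, noise="none")
        cells = simulate_well_cells(
            reference_subject(), "CM", cfg, np.random.default_rng(1),
            cells_per_well={"monocyte": 5, "lymphocyte": 10},
        )
        stack, _ = render_image(cells, cfg, np.random.default_rng(1))
        assert stack.is_stack
        proj = max_project(stack)
        assert proj.channels["nuclei"].ndim == 2
        assert proj.channels["nuclei"].max() == stack.channels["nuclei"].max()


class TestSegmentation:
    def test_well_separated_cells_counted_exactly(self, config, small_counts):
        cfg = dataclasses.replace(config, noise="none")
        cells = simulate_well_cells(
            reference_subject(), "CM", cfg, np.random.default_rng(2),
            cells_per_well={"monocyte": 8, "lymphocyte": 12},
        )
        stack, _ = render_image(cells, cfg, np.random.default_rng(2))
        nuc, cyto, status = segment_cells(stack.channels["nuclei"], stack.channels["cytoplasm"])
        assert status == "ok"
        assert nuc.max() == 20
        assert len(np.unique(cyto)) - 1 == 20

    def test_blank_image_yields_no_labels(self):
        rng = np.random.default_rng(3)
        blank = rng.poisson(8.0, (256, 256)).astype(float)
        with pytest.warns(UserWarning, match="no nuclei"):
            nuc, cyto, status = segment_cells(blank, blank)
        assert status == "no-nuclei"
        assert nuc.max() == 0 and cyto.max() == 0

    def test_touching_cells_split_between_nearer_seeds(self):
        img_n = np.zeros((80, 120))
        img_c = np.zeros((80, 120))
        disk(img_n, 40, 40, 6, 120.0)
        disk(img_n, 40, 80, 6, 120.0)
        disk(img_c, 40, 40, 21, 30.0)
        disk(img_c, 40, 80, 21, 30.0)
        nuc, cyto, status = segment_cells(img_n + 8, img_c + 8)
        assert status == "ok"
        labels = set(np.unique(cyto)) - {0}
        assert len(labels) == 2
        # pixels clearly nearer one nucleus carry that nucleus' label
        assert cyto[40, 30] == nuc[40, 40]
        assert cyto[40, 90] == nuc[40, 80]
        assert cyto[40, 30] != cyto[40, 90]


class TestSpotDetection:
    def test_noiseless_puncta_recovered_and_assigned(self, config):
        cfg = dataclasses.replace(config, noise="none")
        cells = pd.DataFrame(
            {
                "cell_id": [1, 2],
                "population_true": ["monocyte", "monocyte"],
                "cytoplasm_area_um2": [230.0, 230.0],
                "mean_dii_intensity": [0.0, 0.0],
                "dii_organelle_count": [0, 0],
                "ld_count": [3, 1],
                "ld_total_area_um2": [1.2, 0.4],
                "ld_droplet_areas_um2": [np.array([0.4] * 3), np.array([0.4])],
            }
        )
        stack, truth = render_image(cells, cfg, np.random.default_rng(4))
        nuc, cyto, _ = segment_cells(stack.channels["nuclei"], stack.channels["cytoplasm"])
        spots = detect_spots(stack.channels["ld"], cyto, pixel_size_um=cfg.pixel_size_um)
        assert len(spots) == 4
        per_cell = spots.groupby("cell_label").size()
        truth_counts = truth.puncta.groupby("cell_id").size()
        # map measured labels to true cells via nucleus centroids
        centers = truth.cells.set_index("cell_id")
        for cid, count in truth_counts.items():
            lab = cyto[int(round(centers.loc[cid, "row"])), int(round(centers.loc[cid, "col"]))]
            assert per_cell[lab] == count

    def test_blank_channel_no_spots(self):
        rng = np.random.default_rng(5)
        blank = rng.poisson(8.0, (512, 512)).astype(float)
        spots = detect_spots(blank, None, pixel_size_um=0.4)
        assert len(spots) == 0

    def test_invalid_params_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            detect_spots(img, params=SpotParams(sigmas=(0.0,)))
        with pytest.raises(ValueError):
            detect_spots(img, params=SpotParams(k_mad=-1.0))

    def test_recall_precision_on_dense_field(self, config):
        """500 planted puncta across 100 cells at SNR >= 5: both recall
        and precision reach 0.95 with matching within 2 px."""
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, 101),
                "population_true": "monocyte",
                "cytoplasm_area_um2": 230.0,
                "mean_dii_intensity": 10.0,
                "dii_organelle_count": 5,
                "ld_count": 0,
                "ld_total_area_um2": 0.0,
                "ld_droplet_areas_um2": [np.empty(0)] * 100,
            }
        )
        stack, truth = render_image(cells, config, np.random.default_rng(6))
        spots = detect_spots(stack.channels["dii"], None, pixel_size_um=config.pixel_size_um)
        true_pts = truth.puncta[["row", "col"]].to_numpy()
        det = spots[["row", "col"]].to_numpy()
        assert len(true_pts) == 500
        from scipy.spatial import cKDTree

        d, idx = cKDTree(true_pts).query(det)
        matched = set()
        tp = 0
        for dist, i in sorted(zip(d, idx)):
            if dist <= 2.0 and i not in matched:
                matched.add(i)
                tp += 1
        recall = tp / len(true_pts)
        precision = tp / len(det)
        assert recall >= 0.95
        assert precision >= 0.95


class TestFeatures:
    def _simple_masks(self):
        cyto = np.zeros((20, 20), dtype=int)
        cyto[5:15, 5:15] = 1  # 100-px cell
        nuc = np.zeros_like(cyto)
        nuc[9:12, 9:12] = 1
        return nuc, cyto

    def test_uniform_intensity_mean(self):
        nuc, cyto = self._simple_masks()
        channels = {"dii": np.full((20, 20), 10.0)}
        rec = extract_features(nuc, cyto, channels, {}, pixel_size_um=1.0)
        assert rec.loc[0, "mean_dii_intensity"] == pytest.approx(10.0)
        assert rec.loc[0, "cytoplasm_area_um2"] == pytest.approx(100.0)

    def test_ld_additivity(self):
        nuc, cyto = self._simple_masks()
        spots = {
            "ld": pd.DataFrame(
                {"row": [7, 12], "col": [7, 12], "sigma_px": [1.2, 1.2],
                 "response": [9.0, 9.0], "area_um2": [0.3, 0.5], "cell_label": [1, 1]}
            )
        }
        rec = extract_features(nuc, cyto, {"dii": np.zeros((20, 20))}, spots, 1.0)
        assert rec.loc[0, "ld_count"] == 2
        assert rec.loc[0, "ld_total_area_um2"] == pytest.approx(0.8)

    def test_surface_background_subtraction(self):
        nuc, cyto = self._simple_masks()
        rec = extract_features(
            nuc, cyto, {"dii": np.zeros((20, 20))}, {}, 1.0,
            surface_channel=np.full((20, 20), 50.0),
            background_channel=np.full((20, 20), 8.0),
        )
        assert rec.loc[0, "ldlr_surface_intensity"] == pytest.approx(42.0)

    def test_negative_surface_floored_at_zero(self):
        nuc, cyto = self._simple_masks()
        rec = extract_features(
            nuc, cyto, {"dii": np.zeros((20, 20))}, {}, 1.0,
            surface_channel=np.full((20, 20), 5.0),
            background_channel=np.full((20, 20), 8.0),
        )
        assert rec.loc[0, "ldlr_surface_intensity"] == 0.0

    def test_unknown_spot_label_rejected(self):
        nuc, cyto = self._simple_masks()
        spots = {"ld": pd.DataFrame(
            {"row": [7], "col": [7], "sigma_px": [1.2], "response": [9.0],
             "area_um2": [0.3], "cell_label": [99]}
        )}
        with pytest.raises(ValueError, match="absent"):
            extract_features(nuc, cyto, {"dii": np.zeros((20, 20))}, spots, 1.0)

    def test_pixel_size_scales_areas_not_counts(self):
        nuc, cyto = self._simple_masks()
        chans = {"dii": np.zeros((20, 20))}
        r1 = extract_features(nuc, cyto, chans, {}, pixel_size_um=0.4)
        r2 = extract_features(nuc, cyto, chans, {}, pixel_size_um=0.8)
        assert r2.loc[0, "cytoplasm_area_um2"] == pytest.approx(
            4 * r1.loc[0, "cytoplasm_area_um2"]
        )
        assert r1.loc[0, "ld_count"] == r2.loc[0, "ld_count"]

    def test_translation_invariance(self, config):
        cfg = dataclasses.replace(config, noise="none")
        cells = pd.DataFrame(
            {
                "cell_id": [1],
                "population_true": ["monocyte"],
                "cytoplasm_area_um2": [230.0],
                "mean_dii_intensity": [12.0],
                "dii_organelle_count": [4],
                "ld_count": [2],
                "ld_total_area_um2": [0.8],
                "ld_droplet_areas_um2": [np.array([0.4, 0.4])],
            }
        )
        stack, _ = render_image(cells, cfg, np.random.default_rng(9), field_shape=(160, 160))
        shifted = ImageStack(
            channels={k: np.roll(v, (7, 11), axis=(0, 1)) for k, v in stack.channels.items()},
            pixel_size_um=stack.pixel_size_um,
        )
        rec0 = pipeline.quantify_stack(stack)
        rec1 = pipeline.quantify_stack(shifted)
        for col in ("cytoplasm_area_um2", "dii_organelle_count", "ld_count"):
            assert rec0.loc[0, col] == pytest.approx(rec1.loc[0, col])
        assert rec1.loc[0, "nucleus_row"] == pytest.approx(rec0.loc[0, "nucleus_row"] + 7, abs=0.2)


class TestIO:
    def test_tiff_roundtrip(self, tmp_path, config):
        cfg = dataclasses.replace(config, noise="none")
        cells = simulate_well_cells(
            reference_subject(), "CM", cfg, np.random.default_rng(1),
            cells_per_well={"monocyte": 3, "lymphocyte": 5},
        )
        stack, _ = render_image(cells, cfg, np.random.default_rng(1))
        ltio.write_image_stack(tmp_path / "field", stack)
        back = ltio.read_image_stack(tmp_path / "field")
        assert back.pixel_size_um == stack.pixel_size_um
        for name, arr in stack.channels.items():
            assert np.allclose(back.channels[name], arr.astype(np.float32))

    def test_cells_csv_roundtrip(self, tmp_path):
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "cytoplasm_area_um2": [60.0, 200.0],
             "mean_dii_intensity": [5.0, 9.0], "dii_organelle_count": [1, 7],
             "ld_count": [0, 2], "ld_total_area_um2": [0.0, 0.9],
             "ldlr_surface_intensity": [np.nan, 4.0],
             "nucleus_row": [3.0, 9.0], "nucleus_col": [4.0, 2.0]}
        )
        path = ltio.write_cells_csv(tmp_path / "cells.csv", cells)
        back = ltio.read_cells_csv(path)
        pd.testing.assert_frame_equal(back, cells)
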