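"""Forward-simulator contracts: constructed intensities, determinism,
scene validation, and the polarized-cell stack ground truth."""

import numpy as np
import pytest

from guvquant import simulate_cell_stack, simulate_guv_image
from guvquant.errors import SceneError
from guvquant.synthetic import (CellSceneSpec, GroundTruthRecord, GuvSpec,
                                NoiseSpec, SceneSpec)

from conftest import make_scene, half_and_half_arcs


class TestGuvScene:
    def test_zero_contrast_rim_equals_solution(self):
        """With no binding the lectin channel is flat at the solution level
        everywhere outside the lumen."""
        scene = make_scene(contrast={"lectin_1": {"ld": 0.0}})
        image, _ = simulate_guv_image(scene)
        lectin = image.channel("lectin_1")
        yy, xx = np.indices(lectin.shape)
        r = np.hypot(xx - 64, yy - 64)
        outside = r >= 20
        assert np.all(lectin[outside] == 100.0)

    def test_rim_centerline_intensity_is_one_plus_contrast_times_solution(self):
        """Pixels exactly on the rim centerline carry (1+contrast)*S."""
        scene = make_scene(contrast={"lectin_1": {"ld": 1.0}})
        image, _ = simulate_guv_image(scene)
        lectin = image.channel("lectin_1")
        # pixels at exactly radius 20 from center (64, 64)
        on_rim = [(64, 84), (64, 44), (84, 64), (44, 64)]
        values = [lectin[y, x] for y, x in on_rim]
        assert np.allclose(values, 200.0)

    def test_seeded_noise_is_bit_identical(self):
        scene = make_scene(noise=NoiseSpec(), psf_sigma=1.0, seed=11)
        img_a, _ = simulate_guv_image(scene)
        img_b, _ = simulate_guv_image(scene)
        assert np.array_equal(img_a.data, img_b.data)

    def test_marker_outside_rim_matches_background(self):
        """Marker signal away from every rim band is just the configured
        background (conservation of the marker)."""
        scene = make_scene(noise=NoiseSpec(gaussian_sigma=1.0, poisson_scale=0.0))
        scene.background_offset = 10.0
        image, _ = simulate_guv_image(scene)
        marker = image.channel("marker")
        yy, xx = np.indices(marker.shape)
        r = np.hypot(xx - 64, yy - 64)
        away = np.abs(r - 20) > 3 * 2.0 + 2
        assert abs(marker[away].mean() - 10.0) < 0.1

    def test_overlapping_rims_rejected(self):
        guvs = [GuvSpec(center_xy=(50.0, 64.0), radius=20.0,
                        lectin_contrast={"lectin_1": {"ld": 1.0}}),
                GuvSpec(center_xy=(80.0, 64.0), radius=20.0,
                        lectin_contrast={"lectin_1": {"ld": 1.0}})]
        scene = SceneSpec(guvs=guvs, image_shape=(128, 128),
                          solution_intensity={"lectin_1": 100.0}, noise=None)
        with pytest.raises(SceneError, match="overlap"):
            simulate_guv_image(scene)

    def test_border_guv_flagged_in_ground_truth(self):
        scene = make_scene(center=(10.0, 64.0))
        _, truth = simulate_guv_image(scene)
        assert truth.guvs[0].border_touching

    @pytest.mark.parametrize("arcs", [
        [(0.0, np.pi, "ld")],                                  # gap
        [(0.0, 4.0, "ld"), (3.0, 2 * np.pi, "lo")],            # overlap
        [(0.0, 2 * np.pi, "solid")],                           # bad label
    ])
    def test_invalid_phase_arcs_rejected(self, arcs):
        with pytest.raises(SceneError):
            GuvSpec(center_xy=(64.0, 64.0), radius=20.0, phase_arcs=arcs)

    def test_contrast_below_minus_one_rejected(self):
        with pytest.raises(SceneError, match="-1"):
            GuvSpec(center_xy=(64.0, 64.0), radius=20.0,
                    lectin_contrast={"lectin_1": {"ld": -1.5}})

    def test_ground_truth_roundtrips_through_json(self, tmp_path):
        scene = make_scene(phase_arcs=half_and_half_arcs(),
                           contrast={"lectin_1": {"ld": 0.0, "lo": 7.0}})
        _, truth = simulate_guv_image(scene)
        path = tmp_path / "gt.json"
        truth.to_json(path)
        back = GroundTruthRecord.from_json(path)
        assert back == truth


class TestCellStack:
    def test_equal_membranes_give_unit_ratio_truth(self):
        spec = CellSceneSpec(ap_intensity={"lectin_1": 50.0},
                             bl_intensity={"lectin_1": 50.0},
                             noise=None, seed=3)
        _, truth = simulate_cell_stack(spec)
        for cell in truth.cells:
            if cell.labeled:
                assert cell.ap_intensity["lectin_1"] == cell.bl_intensity["lectin_1"]

    def test_constructed_polarity_is_exact_without_noise(self):
        spec = CellSceneSpec(noise=None, seed=3)  # defaults: ap 70, bl 10
        image, truth = simulate_cell_stack(spec)
        labeled = [c for c in truth.cells if c.labeled]
        assert labeled
        for cell in labeled:
            ap = image.channel("lectin_1")[truth.ap_labels == cell.cell_id + 1]
            bl = image.channel("lectin_1")[truth.bl_labels == cell.cell_id + 1]
            assert ap.mean() == 70.0 and bl.mean() == 10.0

    def test_labeled_count_matches_seeded_draw(self):
        """The number of receptor-positive cells equals the draw of the
        scene's seeded generator (labels are drawn first)."""
        spec = CellSceneSpec(n_cells=100, labeled_fraction=0.1, seed=42)
        _, truth = simulate_cell_stack(spec)
        expected = np.random.default_rng(42).random(100) < 0.1
        assert truth.n_labeled == int(expected.sum())
        assert [c.labeled for c in truth.cells] == expected.tolist()

    def test_overfull_grid_rejected(self):
        with pytest.raises(SceneError, match="fit"):
            CellSceneSpec(stack_shape=(16, 64, 64), n_cells=100)
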