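import numpy as np
import pytest

from oednet.detection import (WindowScores, froc_from_scores,
                              regions_at_threshold, scan_image)
from oednet.network import build_network, make_architecture

STRAT = "irregular_stratification"
BULB = "bulbous_rete_ridge"


def make_scores(grid, stride, window_size, image_shape, class_index=2):
    """WindowScores with the given per-window score for one class; the
    remaining probability mass goes to 'others'."""
    grid = np.asarray(grid, dtype=np.float64)
    scores = np.zeros(grid.shape + (3,))
    scores[..., class_index] = grid
    scores[..., 0] = 1.0 - grid
    return WindowScores(scores=scores, stride=stride,
                        window_size=window_size, image_shape=image_shape)


@pytest.fixture(scope="module")
def tiny_model():
    return build_network(make_architecture(channels=(4,), h1=8,
                                           input_side=32), seed=0)


class TestScan:
    def test_single_window_grid(self, tiny_model, rng):
        scores = scan_image(tiny_model, rng.random((32, 32, 3)), stride=10)
        assert scores.grid_shape == (1, 1)

    def test_grid_dimensions(self, tiny_model, rng):
        # floor((122-32)/10)+1 = 10 per side
        scores = scan_image(tiny_model, rng.random((122, 122, 3)), stride=10)
        assert scores.grid_shape == (10, 10)

    def test_scores_are_probabilities(self, tiny_model, rng):
        scores = scan_image(tiny_model, rng.random((52, 52, 3)), stride=10)
        np.testing.assert_allclose(scores.scores.sum(axis=2), 1.0, atol=1e-6)

    def test_undersized_image_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="smaller"):
            scan_image(tiny_model, rng.random((20, 40, 3)))


class TestRegions:
    def test_threshold_zero_unions_all_windows(self):
        scores = make_scores(np.zeros((3, 3)), stride=10, window_size=350,
                             image_shape=(370, 370))
        regions = regions_at_threshold(scores, BULB, 0.0)
        assert len(regions) == 1
        assert regions[0].num_pixels == 370 * 370

    def test_threshold_above_one_is_empty(self):
        scores = make_scores(np.ones((2, 2)), stride=10, window_size=350,
                             image_shape=(360, 360))
        assert regions_at_threshold(scores, BULB, 1.5) == []

    def test_separated_windows_make_two_regions(self):
        """Two firing windows 400 px apart horizontally (stride 10, size
        350) paint extents 0-349 and 400-749, which do not touch."""
        grid = np.zeros((1, 41))
        grid[0, 0] = 1.0
        grid[0, 40] = 1.0
        scores = make_scores(grid, stride=10, window_size=350,
                             image_shape=(350, 750))
        regions = regions_at_threshold(scores, BULB, 0.5)
        assert len(regions) == 2
        cols = sorted(np.nonzero(r.mask.any(axis=0))[0][[0, -1]].tolist()
                      for r in regions)
        assert cols == [[0, 349], [400, 749]]

    def test_coverage_monotone_in_threshold(self, rng):
        grid = rng.random((5, 5))
        scores = make_scores(grid, stride=8, window_size=16,
                             image_shape=(48, 48))
        prev = None
        for t in np.linspace(0, 1, 11):
            mask = np.zeros((48, 48), dtype=bool)
            for region in regions_at_threshold(scores, BULB, float(t)):
                mask |= region.mask
            if prev is not None:
                assert not (mask & ~prev).any()  # shrinks as t rises
            prev = mask

    def test_peak_score_is_max_of_component(self):
        grid = np.array([[0.9, 0.6]])
        scores = make_scores(grid, stride=8, window_size=16,
                             image_shape=(16, 24))
        regions = regions_at_threshold(scores, BULB, 0.5)
        assert len(regions) == 1
        assert regions[0].peak_score == pytest.approx(0.9)


class TestFroc:
    def test_direct_counting_example(self):
        """1 image, 2 ground-truth regions; 3 predicted regions of which 1
        overlaps one GT region: detection probability 1/2, 2 FP/image."""
        grid = np.zeros((1, 9))
        grid[0, [0, 4, 8]] = 1.0  # three windows, extents 8 px, 32 apart
        scores = make_scores(grid, stride=8, window_size=8,
                             image_shape=(8, 72))
        gt = np.zeros((8, 72), dtype=bool)
        gt[:, 0:4] = True      # overlaps the first predicted region
        gt[:, 50:54] = True    # overlaps nothing predicted
        curves = froc_from_scores([scores], [{BULB: gt}], thresholds=[0.5])
        t, fp, pd = curves[BULB].points[0]
        assert pd == pytest.approx(0.5)
        assert fp == pytest.approx(2.0)

    def test_perfect_scorer_detects_all_without_false_positives(self):
        """Window scores aligned with the ground truth yield detection
        probability 1.0 at 0 FP/image for any threshold below the scores."""
        gt = np.zeros((24, 24), dtype=bool)
        gt[0:8, 0:8] = True
        gt[16:24, 16:24] = True
        grid = np.zeros((3, 3))
        # windows overlapping GT fire with probability 1
        for i in range(3):
            for j in range(3):
                window = np.zeros((24, 24), dtype=bool)
                window[i * 8:i * 8 + 8, j * 8:j * 8 + 8] = True
                if (window & gt).any():
                    grid[i, j] = 1.0
        scores = make_scores(grid, stride=8, window_size=8,
                             image_shape=(24, 24))
        curves = froc_from_scores([scores], [{BULB: gt}],
                                  thresholds=[0.25, 0.5, 0.75])
        for _, fp, pd in curves[BULB].points:
            assert pd == pytest.approx(1.0)
            assert fp == pytest.approx(0.0)

    def test_detection_probability_monotone_in_threshold(self, rng):
        grid = rng.random((6, 6))
        scores = make_scores(grid, stride=8, window_size=16,
                             image_shape=(56, 56))
        gt = np.zeros((56, 56), dtype=bool)
        gt[10:20, 10:20] = True
        gt[40:50, 5:15] = True
        curves = froc_from_scores([scores], [{BULB: gt}],
                                  thresholds=np.linspace(0, 1, 21))
        pds = [p[2] for p in curves[BULB].points]
        assert all(a >= b - 1e-12 for a, b in zip(pds, pds[1:]))

    def test_class_without_ground_truth_warns_and_is_omitted(self):
        scores = make_scores(np.zeros((2, 2)), stride=8, window_size=8,
                             image_shape=(16, 16))
        gt = np.zeros((16, 16), dtype=bool)
        gt[0:4, 0:4] = True
        with pytest.warns(UserWarning, match=STRAT):
            curves = froc_from_scores([scores], [{BULB: gt}],
                                      thresholds=[0.5])
        assert STRAT not in curves
        assert BULB in curves

    def test_center_painting_and_iou_matching_run(self, rng):
        grid = rng.random((4, 4))
        scores = make_scores(grid, stride=8, window_size=16,
                             image_shape=(40, 40))
        gt = np.zeros((40, 40), dtype=bool)
        gt[8:24, 8:24] = True
        curves = froc_from_scores([scores], [{BULB: gt}], thresholds=[0.3],
                                  painting="center", matching="iou")
        assert BULB in curves
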