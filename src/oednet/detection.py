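"""Sliding-window whole-image detection and FROC-style evaluation.

A trained classifier is slid over a blind image on a regular grid (stride
10 by default); every window is scored with the three class probabilities.
For a class and a probability threshold, firing windows paint their full
extent onto a coverage mask whose 8-connected components become countable
detection regions.  Sweeping the threshold yields, per class, a curve of
(false positives per image, probability of detection):

  * probability of detection = detected ground-truth regions / all
    ground-truth regions, a region counting as detected when any predicted
    region of its class overlaps it by at least one pixel;
  * false positives per image = predicted regions overlapping no
    ground-truth region of their class, divided by the number of images.

The painting rule ("extent" or "center") and the matching rule
("any_overlap" or "iou") are configurable.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import rgb_to_ycbcr
from .network import LABELS, Network

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class WindowScores:
    """Per-class probability grid indexed by window origin."""

    scores: np.ndarray  # (Gh, Gw, C)
    stride: int
    window_size: int
    image_shape: tuple[int, int]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.scores.shape[:2]


@dataclasses.dataclass
class DetectionRegion:
    """One 8-connected component of the thresholded coverage mask."""

    feature_class: str
    mask: np.ndarray  # boolean, image-sized
    peak_score: float

    @property
    def num_pixels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class FrocCurve:
    """(threshold, FP per image, probability of detection) triples."""

    feature_class: str
    points: list[tuple[float, float, float]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            columns=["threshold", "fp_per_image", "prob_detection"])


def scan_image(model: Network, image: np.ndarray,
               stride: int = 10, batch_size: int = 64) -> WindowScores:
    """Score every window of a full image on a regular grid.

    The window side is the model's configured input side; each window is
    converted to the model's color space and standardized exactly as during
    training.
    """
    image = np.asarray(image, dtype=np.float64)
    size = model.config.input_side
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(
            f"image of size {h}x{w} is smaller than the {size}x{size} "
            "window; partial windows would lose information"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if model.config.color_space == "YCbCr":
        image = rgb_to_ycbcr(image)
    rows = range(0, h - size + 1, stride)
    cols = range(0, w - size + 1, stride)
    gh, gw = len(rows), len(cols)
    scores = np.empty((gh, gw, model.config.num_classes), dtype=np.float64)
    origins = [(i, j, r, c) for i, r in enumerate(rows)
               for j, c in enumerate(cols)]
    for start in range(0, len(origins), batch_size):
        chunk = origins[start:start + batch_size]
        batch = np.stack([
            image[r:r + size, c:c + size] for (_, _, r, c) in chunk
        ]).astype(np.float32)
        probs = model.predict_proba(model.preprocess(batch))
        for (i, j, _, _), p in zip(chunk, probs):
            scores[i, j] = p
    return WindowScores(scores=scores, stride=stride, window_size=size,
                        image_shape=(h, w))


def coverage_mask(scores: WindowScores, class_index: int, threshold: float,
                  painting: str = "extent") -> np.ndarray:
    """Boolean mask of pixels covered by windows whose class score passes
    the threshold; "extent" paints the full window, "center" its center
    pixel only."""
    h, w = scores.image_shape
    firing = scores.scores[:, :, class_index] >= threshold
    mask = np.zeros((h + 1, w + 1), dtype=np.int64)
    size, stride = scores.window_size, scores.stride
    ii, jj = np.nonzero(firing)
    if painting == "extent":
        r0, c0 = ii * stride, jj * stride
        np.add.at(mask, (r0, c0), 1)
        np.add.at(mask, (r0 + size, c0), -1)
        np.add.at(mask, (r0, c0 + size), -1)
        np.add.at(mask, (r0 + size, c0 + size), 1)
        painted = mask.cumsum(axis=0).cumsum(axis=1)[:h, :w] > 0
    elif painting == "center":
        painted = np.zeros((h, w), dtype=bool)
        painted[ii * stride + size // 2, jj * stride + size // 2] = True
    else:
        raise ValueError(f"unknown painting rule {painting!r}")
    return painted


def regions_at_threshold(scores: WindowScores, feature_class: str,
                         threshold: float,
                         painting: str = "extent") -> list[DetectionRegion]:
    """Threshold the window scores for one class and merge firing windows
    into 8-connected detection regions."""
    if feature_class not in LABELS:
        raise ValueError(f"unknown feature class {feature_class!r}")
    if threshold < 0.0:
        raise ValueError("threshold must be >= 0")
    if threshold > 1.0:
        return []
    ci = LABELS.index(feature_class)
    painted = coverage_mask(scores, ci, threshold, painting)
    labeled, n = ndimage.label(painted, structure=EIGHT_CONNECTED)
    if n == 0:
        return []
    # peak score per component: windows are attributed by their origin pixel
    # (always inside the painted extent)
    size, stride = scores.window_size, scores.stride
    firing = scores.scores[:, :, ci] >= threshold
    ii, jj = np.nonzero(firing)
    anchor = size // 2 if painting == "center" else 0
    comp_of_window = labeled[ii * stride + anchor, jj * stride + anchor]
    peaks = np.zeros(n + 1)
    np.maximum.at(peaks, comp_of_window, scores.scores[ii, jj, ci])
    return [
        DetectionRegion(feature_class=feature_class,
                        mask=(labeled == k), peak_score=float(peaks[k]))
        for k in range(1, n + 1)
    ]


def _count_matches(regions: Sequence[DetectionRegion],
                   gt_labeled: np.ndarray, n_gt: int,
                   matching: str = "any_overlap",
                   iou_threshold: float = 0.25) -> tuple[int, int]:
    """(detected GT components, false-positive predicted regions)."""
    detected = np.zeros(n_gt + 1, dtype=bool)
    false_pos = 0
    for region in regions:
        overlap_ids = np.unique(gt_labeled[region.mask])
        overlap_ids = overlap_ids[overlap_ids > 0]
        if matching == "iou":
            kept = []
            for gid in overlap_ids:
                gt_mask = gt_labeled == gid
                inter = (gt_mask & region.mask).sum()
                union = (gt_mask | region.mask).sum()
                if inter / union >= iou_threshold:
                    kept.append(gid)
            overlap_ids = np.array(kept, dtype=int)
        elif matching != "any_overlap":
            raise ValueError(f"unknown matching rule {matching!r}")
        if overlap_ids.size == 0:
            false_pos += 1
        else:
            detected[overlap_ids] = True
    return int(detected.sum()), false_pos


def froc_from_scores(
    scores_list: Sequence[WindowScores],
    gt_masks_list: Sequence[dict[str, np.ndarray]],
    thresholds: Optional[Sequence[float]] = None,
    painting: str = "extent",
    matching: str = "any_overlap",
) -> dict[str, FrocCurve]:
    """FROC curves from precomputed window scores and per-class GT masks.

    ``gt_masks_list[i]`` maps a feature class to its boolean mask for image
    i; classes with no ground-truth region anywhere are omitted (with a
    warning) since their detection probability is undefined.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    n_images = len(scores_list)
    if n_images == 0 or n_images != len(gt_masks_list):
        raise ValueError("need matching, non-empty scores and masks lists")
    curves: dict[str, FrocCurve] = {}
    for cls in LABELS[1:]:
        gt_components = []
        total_gt = 0
        for masks in gt_masks_list:
            mask = masks.get(cls)
            if mask is None:
                mask = np.zeros(scores_list[0].image_shape, dtype=bool)
            labeled, n = ndimage.label(np.asarray(mask, dtype=bool),
                                       structure=EIGHT_CONNECTED)
            gt_components.append((labeled, n))
            total_gt += n
        if total_gt == 0:
            import warnings
            warnings.warn(
                f"no ground-truth regions for class {cls!r}; curve omitted")
            continue
        points = []
        for t in thresholds:
            detected = 0
            false_pos = 0
            for scores, (labeled, n) in zip(scores_list, gt_components):
                regions = regions_at_threshold(scores, cls, float(t),
                                               painting)
                d, fp = _count_matches(regions, labeled, n, matching)
                detected += d
                false_pos += fp
            points.append((float(t), false_pos / n_images,
                           detected / total_gt))
        curves[cls] = FrocCurve(feature_class=cls, points=points)
    return curves


def froc_evaluate(
    images: Sequence[tuple[np.ndarray, dict[str, np.ndarray]]],
    model: Network,
    thresholds: Optional[Sequence[float]] = None,
    stride: int = 10,
    painting: str = "extent",
    matching: str = "any_overlap",
) -> dict[str, FrocCurve]:
    """Scan each (image, ground-truth masks) pair and sweep thresholds into
    per-class FROC curves."""
    scores_list = [scan_image(model, img, stride=stride)
                   for img, _ in images]
    gt_masks_list = [masks for _, masks in images]
    return froc_from_scores(scores_list, gt_masks_list, thresholds,
                            painting, matching)
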