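"""Signature-library construction: grid extraction of labeled patches from
annotated images, minority-class augmentation, and stratified K-fold splits.

A *signature* is a fixed-size square patch (350x350 pixels at full scale)
carrying one of three labels: ``others``, ``irregular_stratification`` or
``bulbous_rete_ridge``.  A patch inherits a feature label when the class's
region mask covers at least ``positive_fraction`` of its area, ties going to
the rarer bulbous class.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import AugmentationKind, apply_augmentation, load_mask
from .network import LABELS

FEATURE_LABELS = ("irregular_stratification", "bulbous_rete_ridge")


@dataclasses.dataclass
class RegionAnnotation:
    """Expert-delineated region of one feature class on one source image."""

    image_id: str
    feature_class: str
    mask: np.ndarray  # boolean, source-image dimensions

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_LABELS:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(
                f"annotation for {self.image_id!r}/{self.feature_class} has "
                "no foreground pixels"
            )


@dataclasses.dataclass
class Signature:
    """One labeled patch with provenance back to its source image."""

    patch: np.ndarray  # (S, S, 3)
    label: str
    image_id: str
    origin: tuple[int, int]  # (row, col) of the top-left corner
    augmentation: Optional[AugmentationKind] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        p = np.asarray(self.patch)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("patch must be a square (S, S, 3) array")


class SignatureLibrary:
    """Train/test collections of signatures, disjoint by source image."""

    def __init__(self, train_signatures: Sequence[Signature],
                 test_signatures: Sequence[Signature] = ()):
        self.train_signatures = list(train_signatures)
        self.test_signatures = list(test_signatures)
        train_ids = {s.image_id for s in self.train_signatures}
        test_ids = {s.image_id for s in self.test_signatures}
        if train_ids & test_ids:
            raise ValueError(
                f"train and test share source images: {train_ids & test_ids}"
            )

    @property
    def class_counts(self) -> dict[str, int]:
        """Per-label tallies of the training signatures (the n_c feeding the
        loss weights)."""
        counts = {label: 0 for label in LABELS}
        for s in self.train_signatures:
            counts[s.label] += 1
        return counts

    @property
    def test_class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for s in self.test_signatures:
            counts[s.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.train_signatures) + len(self.test_signatures)


def extract_signatures(
    image: np.ndarray,
    annotations: Sequence[RegionAnnotation],
    image_id: str = "image",
    patch_size: int = 350,
    stride: int = 50,
    positive_fraction: float = 0.5,
) -> list[Signature]:
    """Slide a regular grid over the image and label each patch.

    The grid origins are ``range(0, H - patch_size + 1, stride)`` crossed
    with the same in x.  A patch is labeled with the feature class whose
    mask covers >= ``positive_fraction`` of its area; when both classes
    qualify the better-covered wins, exact ties going to the rarer
    ``bulbous_rete_ridge``; otherwise the patch is ``others``.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(
            f"image {image_id!r} of size {h}x{w} is smaller than the "
            f"{patch_size}x{patch_size} patch size"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0.0 < positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in (0, 1]")
    for ann in annotations:
        if ann.mask.shape != (h, w):
            raise ValueError(
                f"annotation mask shape {ann.mask.shape} does not match "
                f"image {image_id!r} of size {h}x{w}"
            )
    # summed-area tables make per-patch coverage O(1)
    integrals = {
        ann.feature_class: np.pad(
            np.cumsum(np.cumsum(ann.mask, axis=0), axis=1), ((1, 0), (1, 0))
        )
        for ann in annotations
    }
    area = patch_size * patch_size
    out: list[Signature] = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            coverages = {}
            for cls, sat in integrals.items():
                r2, c2 = r + patch_size, c + patch_size
                covered = (sat[r2, c2] - sat[r, c2] - sat[r2, c]
                           + sat[r, c])
                coverages[cls] = covered / area
            label = "others"
            qualified = {cls: f for cls, f in coverages.items()
                         if f >= positive_fraction}
            if qualified:
                best = max(qualified.values())
                winners = [cls for cls, f in qualified.items() if f == best]
                label = ("bulbous_rete_ridge"
                         if "bulbous_rete_ridge" in winners else winners[0])
            out.append(Signature(
                patch=image[r:r + patch_size, c:c + patch_size].copy(),
                label=label, image_id=image_id, origin=(r, c),
            ))
    return out


def augment_minority(
    library: SignatureLibrary,
    target_label: str = "bulbous_rete_ridge",
    kinds: Sequence[AugmentationKind] = tuple(AugmentationKind),
) -> SignatureLibrary:
    """Add one flipped/rotated copy per transform of every *training*
    signature with ``target_label``; the test set and other labels are left
    untouched, so the target count is multiplied by ``1 + len(kinds)``."""
    if target_label not in LABELS:
        raise ValueError(f"unknown label {target_label!r}")
    kinds = [AugmentationKind(k) for k in kinds]
    if not kinds:
        raise ValueError("kinds must be non-empty")
    if len(set(kinds)) != len(kinds):
        raise ValueError("kinds must be distinct")
    augmented = list(library.train_signatures)
    for sig in library.train_signatures:
        if sig.label != target_label:
            continue
        for kind in kinds:
            augmented.append(Signature(
                patch=apply_augmentation(sig.patch, kind),
                label=sig.label, image_id=sig.image_id, origin=sig.origin,
                augmentation=kind,
            ))
    return SignatureLibrary(augmented, library.test_signatures)


def kfold_split(
    library: SignatureLibrary, K: int, seed: int
) -> list[tuple[list[Signature], list[Signature]]]:
    """Stratified K-fold partition of the training signatures.

    Each signature lands in exactly one test part; within every label the
    signatures are shuffled (deterministically from ``seed``) and dealt
    round-robin so per-fold label proportions match the library's to within
    one signature.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    sigs = library.train_signatures
    by_label: dict[str, list[int]] = {}
    for i, s in enumerate(sigs):
        by_label.setdefault(s.label, []).append(i)
    smallest = min(len(v) for v in by_label.values())
    if K > smallest:
        raise ValueError(
            f"K={K} exceeds the smallest class count ({smallest}); every "
            "fold must contain all classes"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(sigs), dtype=int)
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % K
    folds = []
    for k in range(K):
        test = [s for i, s in enumerate(sigs) if fold_of[i] == k]
        train = [s for i, s in enumerate(sigs) if fold_of[i] != k]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# Manifest / annotation I/O
# ---------------------------------------------------------------------------

def library_manifest(library: SignatureLibrary) -> pd.DataFrame:
    """Tabular provenance of every signature (no pixel data)."""
    rows = []
    for split, sigs in (("train", library.train_signatures),
                        ("test", library.test_signatures)):
        for s in sigs:
            rows.append({
                "image_id": s.image_id,
                "origin_row": s.origin[0],
                "origin_col": s.origin[1],
                "label": s.label,
                "augmentation": (s.augmentation.value
                                 if s.augmentation else "none"),
                "split": split,
            })
    return pd.DataFrame(
        rows, columns=["image_id", "origin_row", "origin_col", "label",
                       "augmentation", "split"])


def write_manifest(library: SignatureLibrary, path: str | Path) -> None:
    library_manifest(library).to_csv(path, index=False)


def load_annotations(directory: str | Path, image_id: str
                     ) -> list[RegionAnnotation]:
    """Read ``<image_id>.<class>.png`` binary masks from a directory; classes
    with no mask file are simply absent."""
    directory = Path(directory)
    out = []
    for cls in FEATURE_LABELS:
        path = directory / f"{image_id}.{cls}.png"
        if path.exists():
            mask = load_mask(path)
            if mask.any():
                out.append(RegionAnnotation(image_id, cls, mask))
    return out
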