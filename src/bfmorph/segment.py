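"""Nucleus detection and bright-field cell cropping.

Nuclei are found in the fluorescent (nuclear-stain) channel with a
classical pipeline — global Otsu threshold, 8-connected components, area
filter — and each detection's bounding box, expanded by a configurable
margin, crops the corresponding cellular region out of the paired
bright-field image. Boxes whose expanded region would leave the image are
dropped so that no crop contains truncated morphology.

Coordinates are 0-based, row-major; boxes are half-open
``[r0, r1) x [c0, c1)`` throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "BoundingBox",
    "CellCrop",
    "detect_nuclei",
    "crop_cells",
    "match_to_truth",
    "MatchResult",
]


@dataclass(frozen=True)
class BoundingBox:
    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r1 > self.r0 and self.c1 > self.c0):
            raise ValueError("box must have positive height and width")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.r0 + self.r1 - 1) / 2, (self.c0 + self.c1 - 1) / 2)

    def expand(self, frac: float) -> "BoundingBox":
        dr = int(round(frac * self.height))
        dc = int(round(frac * self.width))
        return BoundingBox(self.r0 - dr, self.c0 - dc, self.r1 + dr, self.c1 + dc)


@dataclass
class CellCrop:
    """One cell's bright-field sub-image with provenance."""

    image: np.ndarray
    source_field: str
    box: BoundingBox
    cell_id: str

    def __post_init__(self) -> None:
        if self.image.shape != (self.box.height, self.box.width):
            raise ValueError("crop image shape must equal its box shape")


def detect_nuclei(
    nuclear_image: np.ndarray,
    min_area: int = 20,
    max_area: int | None = None,
) -> list[BoundingBox]:
    """Detect nuclei as bright connected components above the Otsu threshold.

    Returns tight bounding boxes sorted by (r0, c0). A constant image has
    no nuclei and yields an empty list.
    """
    img = np.asarray(nuclear_image)
    if img.ndim != 2:
        raise ValueError("nuclear image must be 2-D")
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    lab = label(img > thr, connectivity=2)
    boxes = []
    for rp in regionprops(lab):
        if rp.area < min_area:
            continue
        if max_area is not None and rp.area > max_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        boxes.append(BoundingBox(r0, c0, r1, c1))
    boxes.sort(key=lambda b: (b.r0, b.c0))
    return boxes


def crop_cells(
    bf_image: np.ndarray,
    boxes: list[BoundingBox],
    expand_frac: float = 0.5,
    field_id: str = "field_000",
) -> list[CellCrop]:
    """Crop one bright-field region per nucleus box.

    Each box grows by ``expand_frac`` of its own height/width on every
    side; a box whose expanded region reaches beyond the image border is
    dropped (border cells carry truncated cells).
    """
    img = np.asarray(bf_image)
    if img.ndim != 2:
        raise ValueError("bright-field image must be 2-D")
    H, W = img.shape
    crops = []
    for i, box in enumerate(boxes):
        ebox = box.expand(expand_frac)
        if ebox.r0 < 0 or ebox.c0 < 0 or ebox.r1 > H or ebox.c1 > W:
            continue
        crops.append(
            CellCrop(
                image=img[ebox.r0 : ebox.r1, ebox.c0 : ebox.c1],
                source_field=field_id,
                box=ebox,
                cell_id=f"{field_id}:{i:03d}",
            )
        )
    return crops


@dataclass
class MatchResult:
    assignment: list[tuple[int, int]]  # (box index, truth index)
    precision: float
    recall: float


def match_to_truth(
    boxes: list[BoundingBox],
    truth_centers: list[tuple[float, float]],
    max_dist: float = 15.0,
) -> MatchResult:
    """Greedy one-to-one nearest-center matching of detections to truth.

    Candidate pairs within ``max_dist`` are taken in order of increasing
    distance (ties broken by indices); precision and recall follow.
    """
    pairs = []
    for i, b in enumerate(boxes):
        br, bc = b.center
        for j, (tr, tc) in enumerate(truth_centers):
            d = math.hypot(br - tr, bc - tc)
            if d <= max_dist:
                pairs.append((d, i, j))
    pairs.sort()
    used_b: set[int] = set()
    used_t: set[int] = set()
    assignment = []
    for d, i, j in pairs:
        if i in used_b or j in used_t:
            continue
        used_b.add(i)
        used_t.add(j)
        assignment.append((i, j))
    m = len(assignment)
    precision = m / len(boxes) if boxes else 0.0
    recall = m / len(truth_centers) if truth_centers else 0.0
    return MatchResult(sorted(assignment), precision, recall)
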