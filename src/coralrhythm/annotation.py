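"""Region tags, labeled-pixel sampling, and patch dataset construction.

Manual supervision enters the pipeline as rectangular region tags carrying
one of the three activity statuses.  Within each tagged rectangle, foreground
pixels (per the segmentation mask) are sampled and labeled with the region's
status and background pixels with the background class; each labeled pixel is
then expanded into a 30x30 crop centered on it — the "patches" dataset the
classifier trains on.  The expansion assumes local label homogeneity: the
immediate neighborhood of a labeled pixel shares its status.

Rectangles are half-open, 0-based, (row0, col0, row1, col1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import CLASS_IDS, STATUS_NAMES

__all__ = [
    "RegionTag",
    "PixelLabel",
    "LabeledPatchSet",
    "sample_region_pixels",
    "extract_patch",
    "build_patch_dataset",
    "augment",
    "read_region_tags",
    "write_region_tags",
    "read_pixel_labels",
    "write_pixel_labels",
]

LABEL_NAMES = ("background",) + STATUS_NAMES  # index == class id is NOT implied; use CLASS_IDS


@dataclass(frozen=True)
class RegionTag:
    image_id: str
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    status: str

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        r0, c0, r1, c1 = self.rect
        if self.status not in STATUS_NAMES:
            raise ValueError(f"unknown status {self.status!r}")
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate rect {self.rect}")
        if image_shape is not None:
            h, w = image_shape[:2]
            if not (0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w):
                raise ValueError(f"rect {self.rect} outside {h}x{w} image")


@dataclass(frozen=True)
class PixelLabel:
    image_id: str
    row: int
    col: int
    label: str  # one of background/bloated/semi_bloated/non_bloated


@dataclass
class LabeledPatchSet:
    """The classifier's train/test currency: N patches of 30x30x3 + class ids."""

    patches: np.ndarray  # N x size x size x 3, uint8
    labels: np.ndarray  # N class ids per CLASS_IDS
    sources: list[tuple[str, int, int]]  # (image_id, row, col) per patch

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 4 or self.patches.shape[3] != 3:
            raise ValueError("patches must be N x size x size x 3")
        if len(self.labels) != len(self.patches):
            raise ValueError("labels and patches disagree in length")
        if self.labels.size and not np.isin(self.labels, list(CLASS_IDS.values())).all():
            raise ValueError("labels must be class ids 0..3")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]

    def class_histogram(self) -> dict[str, int]:
        return {name: int((self.labels == cid).sum()) for name, cid in CLASS_IDS.items()}

    def subset(self, idx) -> "LabeledPatchSet":
        idx = np.asarray(idx)
        return LabeledPatchSet(self.patches[idx], self.labels[idx], [self.sources[i] for i in idx])


def sample_region_pixels(
    region: RegionTag,
    mask: np.ndarray,
    n_fg: int = 120,
    n_bg: int = 40,
    seed: int | np.random.Generator = 0,
) -> list[PixelLabel]:
    """Sample labeled pixels inside one tagged rectangle.

    ``n_fg`` foreground pixels (mask == 1) get the region's status, ``n_bg``
    background pixels (mask == 0) the background label; sampling is uniform
    without replacement.  Raises if the rectangle does not contain enough
    pixels of either kind.
    """
    region.validate(mask.shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r0, c0, r1, c1 = region.rect
    sub = np.asarray(mask)[r0:r1, c0:c1]

    fg_r, fg_c = np.nonzero(sub == 1)
    bg_r, bg_c = np.nonzero(sub == 0)
    if len(fg_r) < n_fg:
        raise ValueError(
            f"region {region.rect} has only {len(fg_r)} foreground pixels, need {n_fg}"
        )
    if len(bg_r) < n_bg:
        raise ValueError(
            f"region {region.rect} has only {len(bg_r)} background pixels, need {n_bg}"
        )

    out: list[PixelLabel] = []
    pick_fg = rng.choice(len(fg_r), size=n_fg, replace=False)
    for i in pick_fg:
        out.append(PixelLabel(region.image_id, int(fg_r[i] + r0), int(fg_c[i] + c0), region.status))
    pick_bg = rng.choice(len(bg_r), size=n_bg, replace=False)
    for i in pick_bg:
        out.append(PixelLabel(region.image_id, int(bg_r[i] + r0), int(bg_c[i] + c0), "background"))
    return out


def extract_patch(img: np.ndarray, center: tuple[int, int], size: int = 30) -> np.ndarray:
    """Crop ``size x size`` centered on ``center`` with reflect padding.

    For even ``size`` the center pixel sits at index ``size // 2`` of the
    crop.  Reflect padding guarantees every labeled pixel yields a patch,
    including those at frame borders.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image extent {h}x{w}")
    row, col = center
    off = size // 2
    r0, c0 = row - off, col - off
    r1, c1 = r0 + size, c0 + size
    pad_top, pad_left = max(0, -r0), max(0, -c0)
    pad_bot, pad_right = max(0, r1 - h), max(0, c1 - w)
    if pad_top or pad_left or pad_bot or pad_right:
        pad = [(pad_top, pad_bot), (pad_left, pad_right)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="reflect")
        r0 += pad_top
        c0 += pad_left
    return img[r0 : r0 + size, c0 : c0 + size]


def build_patch_dataset(
    labels: Iterable[PixelLabel],
    images: Mapping[str, np.ndarray],
    size: int = 30,
) -> LabeledPatchSet:
    """Expand labeled pixels into a LabeledPatchSet (one patch per label, stable order)."""
    patches, ids, sources = [], [], []
    for lab in labels:
        if lab.image_id not in images:
            raise KeyError(f"no image with id {lab.image_id!r}")
        img = images[lab.image_id]
        patches.append(extract_patch(img, (lab.row, lab.col), size))
        ids.append(CLASS_IDS[lab.label])
        sources.append((lab.image_id, lab.row, lab.col))
    if not patches:
        return LabeledPatchSet(np.empty((0, size, size, 3), np.uint8), np.empty(0, np.int64), [])
    return LabeledPatchSet(np.stack(patches), np.asarray(ids), sources)


def augment(
    patchset: LabeledPatchSet,
    flips: bool = True,
    shift_frac: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> Iterator[tuple[np.ndarray, int]]:
    """On-the-fly augmentation stream: random flips and sub-patch translations.

    Yields ``(patch, label)`` pairs in dataset order; each patch is
    independently flipped horizontally/vertically with probability 1/2 (when
    ``flips``) and translated by up to ``±shift_frac * size`` pixels with
    reflect fill.  With ``flips=False, shift_frac=0`` this is the identity
    stream.
    """
    if not 0 <= shift_frac < 0.5:
        raise ValueError("shift_frac must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = patchset.patch_size
    max_shift = int(round(shift_frac * size))
    for patch, label in zip(patchset.patches, patchset.labels):
        p = patch
        if flips:
            if rng.random() < 0.5:
                p = p[:, ::-1]
            if rng.random() < 0.5:
                p = p[::-1, :]
        if max_shift:
            dr = int(rng.integers(-max_shift, max_shift + 1))
            dc = int(rng.integers(-max_shift, max_shift + 1))
            if dr or dc:
                pad = ((max_shift, max_shift), (max_shift, max_shift), (0, 0))
                padded = np.pad(p, pad, mode="reflect")
                p = padded[max_shift + dr : max_shift + dr + size, max_shift + dc : max_shift + dc + size]
        yield p.copy(), int(label)


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------


def write_region_tags(tags: Sequence[RegionTag], path) -> None:
    rows = [
        {"image_id": t.image_id, "row0": t.rect[0], "col0": t.rect[1],
         "row1": t.rect[2], "col1": t.rect[3], "status": t.status}
        for t in tags
    ]
    pd.DataFrame(rows, columns=["image_id", "row0", "col0", "row1", "col1", "status"]).to_csv(
        path, index=False
    )


def read_region_tags(path) -> list[RegionTag]:
    df = pd.read_csv(path)
    return [
        RegionTag(str(r.image_id), (int(r.row0), int(r.col0), int(r.row1), int(r.col1)), str(r.status))
        for r in df.itertuples()
    ]


def write_pixel_labels(labels: Sequence[PixelLabel], path) -> None:
    rows = [{"image_id": l.image_id, "row": l.row, "col": l.col, "label": l.label} for l in labels]
    pd.DataFrame(rows, columns=["image_id", "row", "col", "label"]).to_csv(path, index=False)


def read_pixel_labels(path) -> list[PixelLabel]:
    df = pd.read_csv(path)
    return [PixelLabel(str(r.image_id), int(r.row), int(r.col), str(r.label)) for r in df.itertuples()]
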