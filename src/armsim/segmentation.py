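"""Gray-threshold segmentation via layer-by-layer Boolean stripping.

The splitting method: threshold the whole stack to a total-body mask, then
strip tissues outer→inner (skin first, marrow last) with Boolean differences.
Each stage keeps the largest connected component (26-connectivity) and fills
internal holes (6-connected background) to avoid singular points and sharp
faces.  Works on the full 3-D stack, not slice-by-slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from .phantom import BACKGROUND, GrayIndex, LabelVolume, SliceStack, TISSUE_NAMES

__all__ = [
    "GrayInterval",
    "ThresholdSpec",
    "PointCloud",
    "threshold_segment",
    "extract_point_cloud",
    "SegmentationError",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class GrayInterval:
    """Half-open gray interval [lo, hi) assigned to one tissue label."""

    label: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SegmentationError(
                f"interval for label {self.label} is empty: [{self.lo}, {self.hi})"
            )

    def contains(self, gray: np.ndarray) -> np.ndarray:
        return (gray >= self.lo) & (gray < self.hi)


@dataclass(frozen=True)
class ThresholdSpec:
    """Ordered (outer→inner) tissue gray intervals plus a background interval.

    Order must match the anatomical nesting used for stripping: skin first,
    marrow last.
    """

    intervals: tuple[GrayInterval, ...]
    background: GrayInterval = GrayInterval(BACKGROUND, -np.inf, np.inf)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise SegmentationError("at least one tissue interval is required")
        labels = [iv.label for iv in self.intervals]
        if len(set(labels)) != len(labels):
            raise SegmentationError("duplicate tissue label in threshold spec")

    @property
    def labels(self) -> list[int]:
        return [iv.label for iv in self.intervals]

    @classmethod
    def from_gray_index(
        cls, gi: GrayIndex, order: Sequence[int] | None = None
    ) -> "ThresholdSpec":
        """Midpoint intervals between adjacent gray means.

        ``order`` is the stripping order (outer→inner); defaults to descending
        label number, i.e. skin(5) → marrow(1) for the standard phantom.
        """
        entries = sorted(
            [(gi.background, BACKGROUND)] + [(m, l) for l, m in gi.means.items()]
        )
        grays = [g for g, _ in entries]
        cuts = [-np.inf] + [
            (a + b) / 2.0 for a, b in zip(grays, grays[1:])
        ] + [np.inf]
        by_label = {
            lab: (cuts[i], cuts[i + 1]) for i, (_, lab) in enumerate(entries)
        }
        if order is None:
            order = sorted(gi.means, reverse=True)
        intervals = tuple(
            GrayInterval(lab, *by_label[lab]) for lab in order
        )
        bg = GrayInterval(BACKGROUND, *by_label[BACKGROUND])
        return cls(intervals=intervals, background=bg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSpec":
        raw = yaml.safe_load(Path(path).read_text())
        intervals = tuple(
            GrayInterval(int(e["label"]), float(e["lo"]), float(e["hi"]))
            for e in raw["intervals"]
        )
        bg = raw.get("background")
        if bg is not None:
            background = GrayInterval(
                BACKGROUND, float(bg["lo"]), float(bg["hi"])
            )
        else:
            background = GrayInterval(BACKGROUND, -np.inf, np.inf)
        return cls(intervals=intervals, background=background)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "intervals": [
                {"label": iv.label, "lo": float(iv.lo), "hi": float(iv.hi)}
                for iv in self.intervals
            ],
            "background": {
                "lo": float(self.background.lo),
                "hi": float(self.background.hi),
            },
        }
        Path(path).write_text(yaml.safe_dump(raw))


@dataclass
class PointCloud:
    """Boundary-shell points of one tissue, in physical mm."""

    points: np.ndarray  # (n, 3) columns (x, y, z) mm
    tissue: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    def save_xyz(self, path: str | Path) -> None:
        header = f"x_mm,y_mm,z_mm  # tissue={self.tissue}"
        np.savetxt(path, self.points, delimiter=",", header=header)

    @classmethod
    def load_xyz(cls, path: str | Path, tissue: int) -> "PointCloud":
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(points=pts, tissue=tissue)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    lab, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 1:
        return mask
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def _clean(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component, internal holes filled (6-conn bg)."""
    mask = _largest_component(mask)
    if mask.any():
        mask = ndimage.binary_fill_holes(mask, structure=_STRUCT_6)
    return mask


def threshold_segment(stack: SliceStack, spec: ThresholdSpec) -> LabelVolume:
    """Segment a grayscale stack by the splitting method.

    1. Total-body mask = union of all tissue intervals (background removed),
       cleaned (largest component + hole fill).
    2. Strip tissues outer→inner: at each stage the inner mask collects the
       voxels matching any *strictly inner* tissue interval; the current
       tissue is the Boolean difference.  Voxels matching no inner interval
       stay with the current (outer) tissue.
    3. The last (innermost) tissue receives the remaining mask.
    """
    gray = stack.as_array().astype(np.float64)
    interval_masks = [iv.contains(gray) for iv in spec.intervals]
    # total body = union of tissue intervals plus anything outside the
    # background interval (so unmatched in-body grays are not dropped; they are
    # absorbed by the outermost enclosing tissue during stripping)
    total = np.logical_or.reduce(interval_masks) | ~spec.background.contains(gray)
    if not total.any():
        raise SegmentationError("no tissue found: total-body mask is empty")
    total = _clean(total)

    out = np.zeros(gray.shape, dtype=np.int16)
    remaining = total
    n = len(spec.intervals)
    for i, iv in enumerate(spec.intervals):
        if i == n - 1:
            tissue_mask = remaining
        else:
            inner = remaining & np.logical_or.reduce(interval_masks[i + 1 :])
            if inner.any():
                inner = _largest_component(inner)
                inner = ndimage.binary_fill_holes(inner, structure=_STRUCT_6)
                inner &= remaining
            tissue_mask = remaining & ~inner
            remaining = inner
        if not tissue_mask.any():
            warnings.warn(
                f"stripping stage for label {iv.label} "
                f"({TISSUE_NAMES.get(iv.label, '?')}) yielded an empty tissue",
                stacklevel=2,
            )
        out[tissue_mask] = iv.label

    return LabelVolume(
        labels=out,
        spacing=(stack.slice_spacing, stack.pixel_spacing, stack.pixel_spacing),
        origin=stack.origin,
    )


def boundary_shell(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with at least one face-neighbor outside the mask."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~eroded


def extract_point_cloud(vol: LabelVolume, tissue: int) -> PointCloud:
    """Centers (mm) of tissue voxels with a face-neighbor of another label."""
    mask = vol.labels == tissue
    if not mask.any():
        warnings.warn(f"tissue {tissue} absent from volume", stacklevel=2)
        return PointCloud(points=np.empty((0, 3)), tissue=tissue)
    shell = boundary_shell(mask)
    zc, yc, xc = vol.voxel_centers_1d()
    iz, iy, ix = np.nonzero(shell)
    pts = np.column_stack([xc[ix], yc[iy], zc[iz]])
    return PointCloud(points=pts, tissue=tissue)
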