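"""Spheroid mask detection and concentric ring partition by iterated erosion.

The assay quantifies how deep transfection reaches into a spheroid by
partitioning the central optical section into four concentric segments —
outer ring, mid ring, inner ring and core — obtained by repeatedly eroding
the spheroid mask with a disk of fixed radius (the "wall thickness").  The
wall thickness is set from the group-average spheroid size so that the four
segments span border to core on an average spheroid of that group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import erosion as _erosion

from .image_io import Micrograph

SEGMENT_LABELS = {"outer": 1, "mid": 2, "inner": 3, "core": 4}
SEGMENT_NAMES = {v: k for k, v in SEGMENT_LABELS.items()}


class NoSpheroidError(ValueError):
    """No spheroid detected (empty mask after thresholding)."""


@dataclass
class SpheroidMask:
    """Binary mask of the analyzed optical plane.

    ``plane_index`` is the stack index of the chosen central plane (0 for 2D
    input); ``mask`` is a filled single connected component, or the full
    field in whole-field (monolayer) mode.
    """

    plane_index: int
    mask: np.ndarray
    whole_field: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise NoSpheroidError("mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_radius_px(self) -> float:
        """Radius of the disk with the same area, sqrt(area/pi)."""
        return math.sqrt(self.area_px / math.pi)


@dataclass
class RingPartition:
    """Concentric segment labeling over a spheroid mask.

    ``labels`` holds 0 outside the mask and SEGMENT_LABELS values inside;
    the four segments are pairwise disjoint and tile the mask exactly.
    ``empty_segments`` lists segments consumed by over-erosion (allowed on
    small masks).
    """

    labels: np.ndarray
    wall_thickness_px: int
    empty_segments: tuple = ()

    def segment_mask(self, name: str) -> np.ndarray:
        return self.labels == SEGMENT_LABELS[name]

    def areas(self) -> dict:
        return {name: int((self.labels == lab).sum()) for name, lab in SEGMENT_LABELS.items()}


def find_spheroid_mask(
    micrograph: Micrograph,
    sigma: float = 2.0,
    whole_field: bool = False,
) -> SpheroidMask:
    """Detect the spheroid mask and pick the central optical plane.

    Recipe: Gaussian smoothing (``sigma`` px) of the nuclei channel, global
    Otsu threshold over the smoothed stack, per-plane morphological closing
    and hole filling, largest connected component.  The central plane is the
    one whose mask area is largest (ties broken toward the lowest index) —
    i.e. the plane of largest spheroid diameter.

    With ``whole_field=True`` (monolayer mode) the mask is the entire field
    of plane 0 and no detection is performed.
    """
    nuc = micrograph.nuclei.astype(float)
    if whole_field:
        plane0 = nuc[0] if micrograph.is_3d else nuc
        return SpheroidMask(plane_index=0, mask=np.ones(plane0.shape, bool),
                            whole_field=True)

    stack = nuc[None] if nuc.ndim == 2 else nuc
    smoothed = np.stack([gaussian(p, sigma=sigma, preserve_range=True) for p in stack])
    if smoothed.max() == smoothed.min():
        raise NoSpheroidError("no spheroid detected: constant-intensity image")
    tau = threshold_otsu(smoothed)
    binary = smoothed > tau
    if not binary.any():
        raise NoSpheroidError("no spheroid detected: empty Otsu foreground")

    footprint = disk(3)
    best_plane, best_mask, best_area = 0, None, -1
    for z in range(binary.shape[0]):
        m = _closing(binary[z], footprint)
        m = ndimage.binary_fill_holes(m)
        if not m.any():
            continue
        lab, n = cc_label(m, return_num=True)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            m = lab == (int(np.argmax(sizes)) + 1)
        area = int(m.sum())
        if area > best_area:
            best_plane, best_mask, best_area = z, m, area
    if best_mask is None:
        raise NoSpheroidError("no spheroid detected in any plane")
    return SpheroidMask(plane_index=best_plane, mask=best_mask)


def ring_width_from_group(
    masks: Sequence[SpheroidMask], n_segments: int = 4
) -> int:
    """Wall thickness from the group-average spheroid size.

    Returns round(mean equivalent radius / n_segments), half away from zero,
    with a floor of 1 px, so that ``n_segments`` segments span border to
    core on the average spheroid of the group.
    """
    if not masks:
        raise ValueError("empty mask collection")
    if n_segments < 2:
        raise ValueError(f"n_segments must be >= 2, got {n_segments}")
    mean_radius = float(np.mean([m.equivalent_radius_px for m in masks]))
    width = math.floor(mean_radius / n_segments + 0.5)  # half away from zero
    return max(1, int(width))


def partition_rings(
    mask: SpheroidMask, wall_thickness_px: int, n_segments: int = 4
) -> RingPartition:
    """Partition a mask into concentric segments by iterated disk erosion.

    S0 = mask; S_i = erode(S_{i-1}, disk(wall)); segment i = S_{i-1} \\ S_i
    for i = 1..n_segments-1, and the core is the final support S_{n-1}
    (everything left, possibly empty).  The segments are disjoint and tile
    the mask exactly, by construction.
    """
    if wall_thickness_px < 1:
        raise ValueError(f"wall_thickness_px must be >= 1, got {wall_thickness_px}")
    if n_segments < 2:
        raise ValueError(f"n_segments must be >= 2, got {n_segments}")

    footprint = disk(wall_thickness_px)
    labels = np.zeros(mask.mask.shape, dtype=np.int32)
    support = mask.mask
    empty = []
    for i in range(1, n_segments):
        eroded = _erosion(support, footprint)
        ring = support & ~eroded
        labels[ring] = i
        if not ring.any():
            empty.append(SEGMENT_NAMES.get(i, str(i)))
        support = eroded
    labels[support] = n_segments
    if not support.any():
        empty.append(SEGMENT_NAMES.get(n_segments, str(n_segments)))
    return RingPartition(
        labels=labels,
        wall_thickness_px=int(wall_thickness_px),
        empty_segments=tuple(empty),
    )


def edt_ring_partition(
    mask: SpheroidMask, wall_thickness_px: int, n_segments: int = 4
) -> RingPartition:
    """Rings by Euclidean-distance-transform binning (oracle partition).

    Pixels are binned by their Euclidean distance to the mask border at cuts
    wall, 2*wall, ..., independent of the erosion path.  Used to validate
    the erosion partition on convex masks.
    """
    if wall_thickness_px < 1:
        raise ValueError("wall_thickness_px must be >= 1")
    dist = ndimage.distance_transform_edt(mask.mask)
    labels = np.zeros(mask.mask.shape, dtype=np.int32)
    empty = []
    for i in range(1, n_segments + 1):
        if i < n_segments:
            sel = mask.mask & (dist > (i - 1) * wall_thickness_px) & (
                dist <= i * wall_thickness_px
            )
        else:
            sel = mask.mask & (dist > (i - 1) * wall_thickness_px)
        labels[sel] = i
        if not sel.any():
            empty.append(SEGMENT_NAMES.get(i, str(i)))
    return RingPartition(labels=labels, wall_thickness_px=int(wall_thickness_px),
                         empty_segments=tuple(empty))


def segment_iou(a: RingPartition, b: RingPartition, label: int) -> float:
    """Intersection-over-union of one segment between two partitions."""
    ma, mb = a.labels == label, b.labels == label
    union = int((ma | mb).sum())
    if union == 0:
        return 1.0
    return int((ma & mb).sum()) / union
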