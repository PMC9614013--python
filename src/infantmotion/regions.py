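"""Body-region partitioning from the binary silhouette.

For every frame the trunk is summarised by its moment-equivalent ellipse
(centroid from first moments, axes and orientation from second central
moments of the largest connected foreground component).  A rectangle
aligned with the ellipse axes and enlarged by a margin fraction is then
split by its two midlines into four quadrants A1..A4 (upper-right,
upper-left, lower-right, lower-left in the infant's egocentric frame),
from which the composite regions follow: A5 = A1 u A2 (upper body),
A6 = A3 u A4 (lower body), A7 = A5 u A6 (whole body).

Image coordinates follow the recording convention: the first array axis
(rows) is the head-foot direction of the crib, the second (columns) is the
infant's left-right axis.  Which end of the image holds the head cannot be
inferred from a silhouette, so it is a per-recording configuration field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig, DEFAULTS

_HEAD_VECTORS = {
    "top": np.array([-1.0, 0.0]),
    "bottom": np.array([1.0, 0.0]),
    "left": np.array([0.0, -1.0]),
    "right": np.array([0.0, 1.0]),
}


@dataclass
class Ellipse:
    center: np.ndarray       # (row, col)
    semi_axes: np.ndarray    # (major, minor), pixels
    major_dir: np.ndarray    # unit vector (row, col) along the major axis

    @property
    def minor_dir(self) -> np.ndarray:
        r, c = self.major_dir
        return np.array([-c, r])


@dataclass
class Rectangle:
    center: np.ndarray
    half_widths: np.ndarray  # along (major, minor) directions
    major_dir: np.ndarray    # points toward the head
    minor_dir: np.ndarray    # points toward the infant's right


def fit_trunk_ellipse(fg: np.ndarray,
                      min_foreground_px: int = DEFAULTS.min_foreground_px) -> Ellipse:
    """Moment-equivalent ellipse of the largest foreground component.

    A solid ellipse with semi-axes (a, b) has second central moments
    (a^2/4, b^2/4) along its axes, so the equivalent semi-axes are twice
    the square roots of the covariance eigenvalues.
    """
    fg = np.asarray(fg, dtype=bool)
    if fg.sum() < max(min_foreground_px, 1):
        raise ValueError("body not detected: foreground below minimum pixel count")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    coords = np.argwhere(fg).astype(float)
    center = coords.mean(axis=0)
    d = coords - center
    cov = d.T @ d / len(coords)
    vals, vecs = np.linalg.eigh(cov)       # ascending eigenvalues
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.isclose(vals[0], vals[1]):
        # orientation undefined for a circular body: report the row axis
        major = np.array([1.0, 0.0])
    else:
        major = vecs[:, 0]
    semi = 2.0 * np.sqrt(np.maximum(vals, 0.0))
    return Ellipse(center=center, semi_axes=semi, major_dir=major)


def bounding_rectangle(ellipse: Ellipse, margin: float = DEFAULTS.rect_margin,
                       head_side: str = DEFAULTS.head_side) -> Rectangle:
    """Axis-aligned (to the ellipse) rectangle with a margin fraction.

    The major direction is flipped if needed so that it points toward the
    configured head side; the minor direction then points toward the
    infant's right (the image-left side for a supine infant with the head
    at the top of the frame).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if head_side not in _HEAD_VECTORS:
        raise ValueError(f"invalid head_side {head_side!r}")
    major = ellipse.major_dir.astype(float).copy()
    head_vec = _HEAD_VECTORS[head_side]
    if major @ head_vec < 0:
        major = -major
    r, c = major
    minor = np.array([-c, r])  # rotation taking head direction to infant-right
    return Rectangle(center=ellipse.center.copy(),
                     half_widths=(1.0 + margin) * ellipse.semi_axes,
                     major_dir=major, minor_dir=minor)


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    if shape not in _GRID_CACHE:
        _GRID_CACHE[shape] = np.meshgrid(np.arange(shape[0]),
                                         np.arange(shape[1]), indexing="ij")
    return _GRID_CACHE[shape]


def partition_regions(rect: Rectangle, shape: tuple[int, int]) -> np.ndarray:
    """Quadrant label image for one frame.

    Returns an int8 array of the frame shape: 0 outside the rectangle,
    1..4 for A1 (upper-right), A2 (upper-left), A3 (lower-right),
    A4 (lower-left).  The rectangle is implicitly clipped to the frame.
    """
    rr, cc = _grids(shape)
    dr = rr - rect.center[0]
    dc = cc - rect.center[1]
    u = dr * rect.major_dir[0] + dc * rect.major_dir[1]   # toward head
    v = dr * rect.minor_dir[0] + dc * rect.minor_dir[1]   # toward infant right
    inside = (np.abs(u) <= rect.half_widths[0]) & (np.abs(v) <= rect.half_widths[1])
    upper = u >= 0
    right = v >= 0
    labels = np.zeros(shape, dtype=np.int8)
    labels[inside & upper & right] = 1
    labels[inside & upper & ~right] = 2
    labels[inside & ~upper & right] = 3
    labels[inside & ~upper & ~right] = 4
    return labels


def region_mask(labels: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of region A_k (k = 1..7) from a quadrant label image."""
    if k in (1, 2, 3, 4):
        return labels == k
    if k == 5:
        return (labels == 1) | (labels == 2)
    if k == 6:
        return (labels == 3) | (labels == 4)
    if k == 7:
        return labels > 0
    raise ValueError(f"invalid region index {k}")


@dataclass
class RegionSet:
    """Per-frame rectangles for each sub-segment of a recording."""

    rectangles: list[list[Rectangle]]   # [subsegment][frame]
    frame_shape: tuple[int, int]

    def labels(self, seg: int, frame: int) -> np.ndarray:
        return partition_regions(self.rectangles[seg][frame], self.frame_shape)


def compute_regions(mask_stack, config: RunConfig = DEFAULTS) -> RegionSet:
    """Fit the trunk ellipse and rectangle on every retained frame."""
    rects: list[list[Rectangle]] = []
    for fg_seg in mask_stack.fg:
        seg_rects = []
        for i in range(fg_seg.shape[0]):
            ell = fit_trunk_ellipse(fg_seg[i], config.min_foreground_px)
            seg_rects.append(bounding_rectangle(ell, config.rect_margin,
                                                config.head_side))
        rects.append(seg_rects)
    return RegionSet(rectangles=rects, frame_shape=mask_stack.fg[0].shape[1:])
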