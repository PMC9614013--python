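"""Foreground extraction and interframe-difference computation.

The raw recording is a stack of brightness frames plus one background image
of the empty crib.  Processing follows the classic background-subtraction
scheme: threshold the absolute frame/background difference to get a binary
body silhouette, subtract consecutive silhouettes to localise movement, and
clean salt-and-pepper artifacts by iterated erosion followed by iterated
dilation.  Frames annotated as sleep/cry/caregiver interaction are removed
first, splitting the recording into analysis sub-segments; the difference
signal restarts (first frame all-zero) at every sub-segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RunConfig, DEFAULTS

_ELEMENTS = {
    "square3": np.ones((3, 3), dtype=bool),
    "cross3": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass
class FrameStack:
    """One recording: brightness frames, background, exclusion annotation."""

    frames: np.ndarray          # (n_frames, H, W) uint8 or float brightness
    fps: float
    background: np.ndarray      # (H, W)
    exclusion: list[tuple[int, int]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.background = np.asarray(self.background)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if self.frames.shape[1:] != self.background.shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} != "
                f"background shape {self.background.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = self.frames.shape[0]
        ivals = sorted(tuple(map(int, iv)) for iv in self.exclusion)
        prev_end = 0
        for s, e in ivals:
            if not (0 <= s < e <= n):
                raise ValueError(f"exclusion interval [{s},{e}) outside [0,{n})")
            if s < prev_end:
                raise ValueError("exclusion intervals overlap")
            prev_end = e
        self.exclusion = ivals

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def retained_intervals(self) -> list[tuple[int, int]]:
        """Maximal runs of frames not covered by the exclusion annotation."""
        keep = np.ones(self.n_frames, dtype=bool)
        for s, e in self.exclusion:
            keep[s:e] = False
        return _runs(keep)


@dataclass
class MaskStack:
    """Per-sub-segment foreground and denoised difference masks."""

    fg: list[np.ndarray]        # one (L_s, H, W) bool stack per sub-segment
    diff: list[np.ndarray]      # same shapes; first frame of each all-zero
    subsegment_bounds: list[tuple[int, int]]  # original-frame half-open bounds
    fps: float
    source_id: str = ""

    @property
    def n_subsegments(self) -> int:
        return len(self.fg)

    @property
    def segment_lengths(self) -> list[int]:
        return [m.shape[0] for m in self.fg]

    @property
    def total_frames(self) -> int:
        return sum(self.segment_lengths)

    @property
    def duration_s(self) -> float:
        return self.total_frames / self.fps


def _runs(keep: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], keep, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def luma(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 brightness of an (..., 3) colour image."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def binarize_foreground(frame: np.ndarray, background: np.ndarray,
                        threshold: int = DEFAULTS.threshold_T) -> np.ndarray:
    """Binary body mask: 1 where |frame - background| >= threshold.

    The comparison is inclusive, so a pixel differing by exactly the
    threshold counts as foreground.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.abs(frame - background) >= threshold


def frame_difference(fg: np.ndarray) -> np.ndarray:
    """Interframe difference of a (L, H, W) binary stack.

    Output frame l is |f_l - f_{l-1}| for l >= 2; the first output frame is
    all-zero because no predecessor exists within the sub-segment.
    """
    fg = np.asarray(fg, dtype=bool)
    if fg.ndim != 3 or fg.shape[0] < 1:
        raise ValueError("need a (L, H, W) stack with L >= 1")
    diff = np.zeros_like(fg)
    diff[1:] = fg[1:] ^ fg[:-1]
    return diff


def denoise(mask: np.ndarray, iterations: int = DEFAULTS.morph_iterations,
            element: str | np.ndarray = DEFAULTS.morph_element) -> np.ndarray:
    """Iterated erosion then iterated dilation of a binary mask.

    With equal iteration counts this is a morphological opening by the
    ``iterations``-fold dilated structuring element, so it is idempotent and
    never adds pixels.  Pixels outside the image are treated as background.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("denoise expects a binary mask")
    mask = mask.astype(bool)
    se = _ELEMENTS[element] if isinstance(element, str) else np.asarray(element, bool)
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=se, iterations=iterations,
                                 border_value=0)
    return ndimage.binary_dilation(out, structure=se, iterations=iterations,
                                   border_value=0)


def split_subsegments(stack: FrameStack, config: RunConfig = DEFAULTS) -> MaskStack:
    """Binarise, split on the exclusion annotation, difference, and denoise.

    Returns a :class:`MaskStack` whose difference masks are reset (all-zero
    first frame) at every sub-segment start.
    """
    intervals = stack.retained_intervals()
    if not intervals:
        raise ValueError("no analyzable frames: exclusion covers the recording")
    fg_all = (np.abs(stack.frames.astype(float)
                     - stack.background.astype(float)[None, ...])
              >= config.threshold_T)
    se = _ELEMENTS[config.morph_element][None, :, :]  # no coupling across time
    fg_segs, diff_segs = [], []
    for s, e in intervals:
        seg = fg_all[s:e]
        raw = frame_difference(seg)
        if config.morph_iterations > 0:
            den = ndimage.binary_erosion(raw, structure=se, border_value=0,
                                         iterations=config.morph_iterations)
            den = ndimage.binary_dilation(den, structure=se, border_value=0,
                                          iterations=config.morph_iterations)
        else:
            den = raw.copy()
        den[0] = False
        fg_segs.append(seg)
        diff_segs.append(den)
    return MaskStack(fg=fg_segs, diff=diff_segs, subsegment_bounds=intervals,
                     fps=stack.fps, source_id=stack.source_id)
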