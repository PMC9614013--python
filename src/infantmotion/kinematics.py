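"""Per-frame movement quantities derived from the binary masks.

For each body region A_k the pipeline tracks

* posture ``P_l``: the number of silhouette pixels in the region;
* movement ``M_l``: the number of changed pixels (interframe difference)
  in the region, normalised by a reference posture ``P_avg``;
* the image center of gravity (iCOG) ``G_l``: the silhouette centroid in
  the whole-body region, whose scaled first difference is the body-center
  velocity ``Gv`` and whose deviation from an early-recording mean is the
  body-center fluctuation ``Gd``.

``P_avg`` is the mean of the running maxima of whole-body posture over the
first E frames of the reference window (the first Le frames of the first
sub-segment); dividing by ``P_avg`` (or its square root for the iCOG
signals) makes the quantities comparable across infants of different body
sizes.  Movement and velocity series are smoothed with zero-phase
second-order Butterworth low-pass filters before movement frames are
flagged by a strict threshold on the smoothed movement signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import RunConfig, DEFAULTS
from .preprocessing import MaskStack
from .regions import RegionSet, region_mask

REGION_KEYS = (1, 2, 3, 4, 5, 6, 7)
ANALYSIS_REGIONS = (5, 6, 7)


def posture(fg: np.ndarray, region: np.ndarray) -> int:
    """Foreground pixel count within a region mask."""
    return int(np.count_nonzero(np.asarray(fg, bool) & np.asarray(region, bool)))


def reference_posture(p_whole: np.ndarray, E: int = DEFAULTS.E_frames,
                      Le: int = DEFAULTS.Le_frames) -> float:
    """Reference posture: mean of running maxima of whole-body P.

    The running maximum max(P_1..P_e) is averaged over e = 1..E inside the
    first Le frames of the first sub-segment.
    """
    p_whole = np.asarray(p_whole, dtype=float)
    if not 1 <= E <= Le:
        raise ValueError("need 1 <= E <= Le")
    if len(p_whole) < Le:
        raise ValueError(
            f"first sub-segment has {len(p_whole)} frames but the reference "
            f"window needs {Le}; lower Le_frames or exclude the recording")
    running_max = np.maximum.accumulate(p_whole[:Le])
    return float(running_max[:E].mean())


def movement(diff: np.ndarray, region: np.ndarray, p_avg: float) -> float:
    """Normalised movement: changed-pixel count in the region over P_avg."""
    if p_avg <= 0:
        raise ValueError("P_avg must be positive")
    return posture(diff, region) / p_avg


def icog(fg_whole: np.ndarray) -> np.ndarray:
    """Centroid (row, col) of the whole-body silhouette."""
    coords = np.argwhere(np.asarray(fg_whole, bool))
    if coords.size == 0:
        raise ValueError("body not detected: empty whole-body foreground")
    return coords.mean(axis=0)


def icog_velocity(G: np.ndarray, fps: float, p_avg: float) -> np.ndarray:
    """Scaled first difference of the iCOG: fps * dG / sqrt(P_avg).

    The first frame has no predecessor and is set to (0, 0).
    """
    if p_avg <= 0:
        raise ValueError("P_avg must be positive")
    G = np.asarray(G, dtype=float)
    Gv = np.zeros_like(G)
    Gv[1:] = fps * np.diff(G, axis=0) / np.sqrt(p_avg)
    return Gv


def icog_fluctuation(G: np.ndarray, g_avg: np.ndarray, p_avg: float) -> np.ndarray:
    """Normalised deviation of the iCOG from its early-recording mean."""
    if p_avg <= 0:
        raise ValueError("P_avg must be positive")
    return (np.asarray(G, dtype=float) - np.asarray(g_avg, float)) / np.sqrt(p_avg)


def lowpass(x: np.ndarray, cutoff_hz: float, fps: float) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass filter (DC gain 1).

    Applied forward and backward, so the effective magnitude response is
    the squared single-pass response and the phase is zero.
    """
    if not 0 < cutoff_hz < fps / 2:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    x = np.asarray(x, dtype=float)
    b, a = sps.butter(2, cutoff_hz / (fps / 2.0), btype="low")
    padlen = min(3 * max(len(a), len(b)), x.shape[0] - 1)
    return sps.filtfilt(b, a, x, axis=0, padlen=max(padlen, 0))


def detect_movement_frames(m_smooth: np.ndarray,
                           m_th: float = DEFAULTS.movement_threshold) -> np.ndarray:
    """Movement flags: frames whose smoothed M strictly exceeds M_th."""
    if m_th <= 0:
        raise ValueError("movement threshold must be positive")
    return np.asarray(m_smooth, float) > m_th


@dataclass
class MotionSeries:
    """All per-frame series for one recording, organised per sub-segment."""

    P: dict[int, list[np.ndarray]]          # region -> per-segment posture
    M: dict[int, list[np.ndarray]]          # raw normalised movement
    M_smooth: dict[int, list[np.ndarray]]
    G: list[np.ndarray]                     # (L, 2) iCOG per segment
    Gv: list[np.ndarray]                    # raw body-center velocity
    Gv_smooth: list[np.ndarray]
    Gd: list[np.ndarray]                    # body-center fluctuation
    movement_flags: dict[int, list[np.ndarray]]
    p_avg: float
    g_avg: np.ndarray
    fps: float
    config: RunConfig = field(default_factory=lambda: DEFAULTS)

    @property
    def n_subsegments(self) -> int:
        return len(self.G)

    @property
    def segment_lengths(self) -> list[int]:
        return [g.shape[0] for g in self.G]


def compute_motion_series(masks: MaskStack, regions: RegionSet,
                          config: RunConfig = DEFAULTS) -> MotionSeries:
    """Evaluate every per-frame quantity for a preprocessed recording."""
    P: dict[int, list[np.ndarray]] = {k: [] for k in REGION_KEYS}
    diff_counts: dict[int, list[np.ndarray]] = {k: [] for k in ANALYSIS_REGIONS}
    G: list[np.ndarray] = []
    for s, (fg_seg, diff_seg) in enumerate(zip(masks.fg, masks.diff)):
        L = fg_seg.shape[0]
        p_seg = {k: np.zeros(L) for k in REGION_KEYS}
        d_seg = {k: np.zeros(L) for k in ANALYSIS_REGIONS}
        g_seg = np.zeros((L, 2))
        for i in range(L):
            labels = regions.labels(s, i)
            cf = np.bincount(labels[fg_seg[i]], minlength=5)
            cd = np.bincount(labels[diff_seg[i]], minlength=5)
            for k in (1, 2, 3, 4):
                p_seg[k][i] = cf[k]
            p_seg[5][i] = cf[1] + cf[2]
            p_seg[6][i] = cf[3] + cf[4]
            p_seg[7][i] = cf[1:].sum()
            d_seg[5][i] = cd[1] + cd[2]
            d_seg[6][i] = cd[3] + cd[4]
            d_seg[7][i] = cd[1:].sum()
            g_seg[i] = icog(fg_seg[i] & (labels > 0))
        for k in REGION_KEYS:
            P[k].append(p_seg[k])
        for k in ANALYSIS_REGIONS:
            diff_counts[k].append(d_seg[k])
        G.append(g_seg)

    p_avg = reference_posture(P[7][0], config.E_frames, config.Le_frames)
    g_avg = G[0][:config.Le_frames].mean(axis=0)

    M = {k: [d / p_avg for d in diff_counts[k]] for k in ANALYSIS_REGIONS}
    M_smooth = {k: [lowpass(m, config.cutoff_M_hz, masks.fps) for m in M[k]]
                for k in ANALYSIS_REGIONS}
    flags = {k: [detect_movement_frames(m, config.movement_threshold)
                 for m in M_smooth[k]]
             for k in ANALYSIS_REGIONS}
    Gv = [icog_velocity(g, masks.fps, p_avg) for g in G]
    Gv_smooth = [lowpass(gv, config.cutoff_Gv_hz, masks.fps) for gv in Gv]
    Gd = [icog_fluctuation(g, g_avg, p_avg) for g in G]
    return MotionSeries(P=P, M=M, M_smooth=M_smooth, G=G, Gv=Gv,
                        Gv_smooth=Gv_smooth, Gd=Gd, movement_flags=flags,
                        p_avg=p_avg, g_avg=g_avg, fps=masks.fps, config=config)
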