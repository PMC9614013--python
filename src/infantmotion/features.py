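"""Per-infant movement features from the motion series.

The 26 features summarise one recording in four groups:

* magnitude — fraction of frames with movement (I1), mean movement
  amplitude over those frames (I2) and movement episodes per minute (I3),
  each for the upper (A5) and lower (A6) body;
* balance — upper/lower ratios of I1 and I2 (I4, I5) and the zero-lag
  correlation of the upper- and lower-body movement signals (I6);
* rhythm — power-weighted central frequency and the second spectral moment
  about it, for the movement signals (I7, I8 on A5/A6), the body-center
  velocity (I9, I10 per axis) and the body-center fluctuation (I11, I12
  per axis);
* body-center movement — per-axis standard deviations of velocity (I13)
  and fluctuation (I14), and the convex-hull area of the fluctuation
  excursion (I15).

Power spectra are estimated with Welch's method (Hann window, 50% overlap)
and integrated over an analysis band that excludes DC.  Frame-count
statistics pool all retained frames; spectral statistics average the
per-sub-segment spectra weighted by sub-segment duration, so a recording
made of identical sub-segments yields the single-segment features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import ConvexHull, QhullError

from .config import RunConfig, DEFAULTS
from .kinematics import MotionSeries

#: Canonical column order of the 26-feature vector.
FEATURE_NAMES = (
    "I1_A5", "I1_A6", "I2_A5", "I2_A6", "I3_A5", "I3_A6",
    "I4", "I5", "I6",
    "I7_A5", "I7_A6", "I8_A5", "I8_A6",
    "I9x", "I9y", "I10x", "I10y",
    "I11x", "I11y", "I12x", "I12y",
    "I13x", "I13y", "I14x", "I14y",
    "I15",
)


@dataclass
class FeatureVector:
    values: dict[str, float]
    i1_a7: float
    source_id: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def to_series(self) -> pd.Series:
        s = pd.Series({name: self.values[name] for name in FEATURE_NAMES})
        s["I1_A7"] = self.i1_a7
        return s


def _runs(flags: np.ndarray) -> int:
    padded = np.concatenate(([False], np.asarray(flags, bool), [False]))
    return int(np.count_nonzero(np.diff(padded.astype(np.int8)) == 1))


def magnitude_features(flags: list[np.ndarray], m_smooth: list[np.ndarray],
                       fps: float) -> tuple[float, float, float]:
    """I1 (movement frequency), I2 (strength), I3 (episodes per minute)."""
    flag_cat = np.concatenate(flags)
    m_cat = np.concatenate(m_smooth)
    n = len(flag_cat)
    if n == 0:
        raise ValueError("empty series")
    i1 = float(np.count_nonzero(flag_cat)) / n
    i2 = float(m_cat[flag_cat].mean()) if flag_cat.any() else 0.0
    episodes = sum(_runs(f) for f in flags)
    i3 = episodes / (n / fps / 60.0)
    return i1, i2, i3


def _ratio(num: float, den: float, ceiling: float) -> float:
    if den == 0:
        if num == 0:
            return 1.0
        warnings.warn("zero denominator in balance ratio; capped at ceiling")
        return ceiling
    return num / den


def balance_features(i1_a5: float, i1_a6: float, i2_a5: float, i2_a6: float,
                     m5: list[np.ndarray], m6: list[np.ndarray],
                     config: RunConfig = DEFAULTS) -> tuple[float, float, float]:
    """I4, I5 (upper/lower ratios) and I6 (upper-lower coordination)."""
    i4 = _ratio(i1_a5, i1_a6, config.ratio_ceiling)
    i5 = _ratio(i2_a5, i2_a6, config.ratio_ceiling)
    weights, corrs = [], []
    for a, b in zip(m5, m6):
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            continue
        if config.coordination_mode == "pearson":
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
        else:  # co-occurrence: Jaccard overlap of movement flags
            fa = a > config.movement_threshold
            fb = b > config.movement_threshold
            union = np.count_nonzero(fa | fb)
            corrs.append(np.count_nonzero(fa & fb) / union if union else 0.0)
        weights.append(len(a))
    if not corrs:
        warnings.warn("coordination undefined (constant movement signals); I6 = 0")
        return i4, i5, 0.0
    return i4, i5, float(np.average(corrs, weights=weights))


def welch_psd(x: np.ndarray, fps: float,
              nperseg: int = DEFAULTS.welch_nperseg) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram with Hann window and 50% overlap."""
    x = np.asarray(x, dtype=float)
    nperseg = int(min(nperseg, len(x)))
    return sps.welch(x, fs=fps, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")


def moments_from_psd(f: np.ndarray, S: np.ndarray,
                     band: tuple[float, float]) -> tuple[float, float]:
    """Central frequency and second moment of a PSD restricted to a band."""
    sel = (f >= band[0]) & (f <= band[1])
    power = S[sel]
    total = power.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("no power in band")
    fc = float((f[sel] * power).sum() / total)
    sm = float((((f[sel] - fc) ** 2) * power).sum() / total)
    return fc, sm


def spectral_moments(x: np.ndarray, fps: float, band: tuple[float, float],
                     nperseg: int = DEFAULTS.welch_nperseg) -> tuple[float, float]:
    """Central frequency (Hz) and second moment (Hz^2) of one signal."""
    if not 0 <= band[0] < band[1] <= fps / 2:
        raise ValueError("band must lie within (0, Nyquist)")
    f, S = welch_psd(x, fps, nperseg)
    return moments_from_psd(f, S, band)


def _multiseg_moments(segments: list[np.ndarray], fps: float,
                      band: tuple[float, float], nperseg: int) -> tuple[float, float]:
    """Duration-weighted average of per-segment Welch spectra, then moments."""
    nps = int(min(nperseg, min(len(s) for s in segments)))
    psds, weights, freqs = [], [], None
    for seg in segments:
        f, S = welch_psd(seg, fps, nps)
        freqs = f
        psds.append(S)
        weights.append(len(seg))
    S_avg = np.average(np.stack(psds), axis=0, weights=weights)
    return moments_from_psd(freqs, S_avg, band)


def body_center_features(gv: np.ndarray, gd: np.ndarray
                         ) -> tuple[float, float, float, float, float]:
    """I13 (SD of velocity), I14 (SD of fluctuation) per axis, I15 (hull area)."""
    gv = np.asarray(gv, float)
    gd = np.asarray(gd, float)
    i13x, i13y = np.std(gv[:, 0]), np.std(gv[:, 1])
    i14x, i14y = np.std(gd[:, 0]), np.std(gd[:, 1])
    try:
        i15 = float(ConvexHull(gd).volume)  # 2-D "volume" is the area
    except (QhullError, ValueError):
        warnings.warn("degenerate body-center excursion; hull area set to 0")
        i15 = 0.0
    return float(i13x), float(i13y), float(i14x), float(i14y), i15


def extract_all(motion: MotionSeries, config: RunConfig = DEFAULTS,
                source_id: str = "") -> FeatureVector:
    """Compute the full 26-feature vector (plus whole-body I1 for QC)."""
    fps = motion.fps
    notes: list[str] = []
    vals: dict[str, float] = {}

    i1 = {}
    for k, tag in ((5, "A5"), (6, "A6")):
        i1_k, i2_k, i3_k = magnitude_features(motion.movement_flags[k],
                                              motion.M_smooth[k], fps)
        vals[f"I1_{tag}"], vals[f"I2_{tag}"], vals[f"I3_{tag}"] = i1_k, i2_k, i3_k
        i1[k] = i1_k
    i1_a7, _, _ = magnitude_features(motion.movement_flags[7],
                                     motion.M_smooth[7], fps)

    vals["I4"], vals["I5"], vals["I6"] = balance_features(
        vals["I1_A5"], vals["I1_A6"], vals["I2_A5"], vals["I2_A6"],
        motion.M_smooth[5], motion.M_smooth[6], config)

    band = (config.band_lo_hz, config.band_hi_hz)
    nps = config.welch_nperseg

    def safe_moments(segments: list[np.ndarray], cf_name: str, sm_name: str) -> None:
        try:
            cf, sm = _multiseg_moments(segments, fps, band, nps)
        except ValueError:
            notes.append(f"{cf_name}: no power in band")
            warnings.warn(f"{cf_name}: no power in band; set to NaN")
            cf, sm = np.nan, np.nan
        vals[cf_name], vals[sm_name] = cf, sm

    safe_moments(motion.M_smooth[5], "I7_A5", "I8_A5")
    safe_moments(motion.M_smooth[6], "I7_A6", "I8_A6")
    for axis, tag in ((0, "x"), (1, "y")):
        safe_moments([gv[:, axis] for gv in motion.Gv_smooth],
                     f"I9{tag}", f"I10{tag}")
        safe_moments([gd[:, axis] for gd in motion.Gd],
                     f"I11{tag}", f"I12{tag}")

    gv_cat = np.concatenate(motion.Gv_smooth, axis=0)
    gd_cat = np.concatenate(motion.Gd, axis=0)
    (vals["I13x"], vals["I13y"], vals["I14x"], vals["I14y"],
     vals["I15"]) = body_center_features(gv_cat, gd_cat)

    return FeatureVector(values=vals, i1_a7=i1_a7, source_id=source_id,
                         notes=notes)


def qc_filter(duration_s: float, i1_a7: float,
              config: RunConfig = DEFAULTS) -> tuple[bool, str | None]:
    """Recording-level quality control.

    Recordings are discarded when the analysable duration is at most the
    minimum (3 min by default) or when the whole-body movement fraction is
    at or below the activity cutoff (10% by default); both bounds are
    inclusive.
    """
    if duration_s <= config.qc_min_duration_s:
        return False, "short length"
    if i1_a7 <= config.qc_min_activity:
        return False, "low frequency"
    return True, None
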