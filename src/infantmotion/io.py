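"""Reading and writing recordings and tabular artifacts.

A recording on disk is a directory with ``frames/frame_%06d.png`` (PNG is
lossless, keeping analyses bit-exact), ``background.png``, and an optional
``exclusion.json`` holding half-open 0-based frame intervals
``[{"start": int, "end": int}, ...]`` to delete (sleep/cry/interaction).
Colour frames are converted to brightness with the Rec. 601 luma weights.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocessing import FrameStack, luma


def _to_brightness(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return luma(img[..., :3])
    return np.asarray(img, dtype=float)


def write_recording(path: str | Path, frames: np.ndarray, background: np.ndarray,
                    exclusion: list[tuple[int, int]] | None = None) -> Path:
    path = Path(path)
    (path / "frames").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(path / "frames" / f"frame_{i:06d}.png",
                    np.asarray(frame, dtype=np.uint8))
    iio.imwrite(path / "background.png", np.asarray(background, dtype=np.uint8))
    if exclusion:
        with open(path / "exclusion.json", "w") as fh:
            json.dump([{"start": int(s), "end": int(e)} for s, e in exclusion], fh)
    return path


def read_exclusion(path: str | Path) -> list[tuple[int, int]]:
    with open(path) as fh:
        data = json.load(fh)
    return [(int(d["start"]), int(d["end"])) for d in data]


def read_recording(path: str | Path, fps: float = 30.0,
                   source_id: str | None = None) -> FrameStack:
    path = Path(path)
    frame_files = sorted((path / "frames").glob("frame_*.png"))
    if not frame_files:
        raise FileNotFoundError(f"no frames found under {path / 'frames'}")
    frames = np.stack([_to_brightness(iio.imread(f)) for f in frame_files])
    background = _to_brightness(iio.imread(path / "background.png"))
    excl_path = path / "exclusion.json"
    exclusion = read_exclusion(excl_path) if excl_path.exists() else []
    return FrameStack(frames=frames, fps=fps, background=background,
                      exclusion=exclusion,
                      source_id=source_id or path.name)
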