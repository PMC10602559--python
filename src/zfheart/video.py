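"""Core video container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HeartVideo:
    """A fluorescence intensity stack (T, H, W) in [0, 1] with its frame rate.

    This is the raw observable of the pipeline: a short time-lapse of a
    fluorescently labelled larval heart (typically 2 s at 50 frames/s).
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=np.float32)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ValueError("frames must be a nonempty (T, H, W) stack")
        if not np.all(np.isfinite(f)):
            raise ValueError("frames must be finite")
        object.__setattr__(self, "frames", f)
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps
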