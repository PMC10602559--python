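"""Cardiac function parameters from ventricular mask sequences.

Converts a per-frame binary ventricle mask sequence into the standard larval
zebrafish cardiac readouts: the time-varying ventricular area, end-diastole /
end-systole (ED/ES) frames per cardiac cycle, the rotated minimum-area
rectangle axes, and the derived parameters

    FAC = (EDA - ESA) / EDA x 100%          (fractional area change)
    FS  = (EDa - ESa) / EDa x 100%          (fractional shortening)
    SV  = 4/3 pi (EDa EDb^2 - ESa ESb^2)    (stroke volume, axis convention
                                             selectable, see `sv`)
    HR  = n_cycles / duration_s x 60        (heart rate, beats per minute)

Conventions: 0-based frame indices, (row, col) pixel coordinates, pixels
treated as unit squares (a single pixel has a 1x1 bounding rectangle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from shapely import MultiPoint

logger = logging.getLogger(__name__)

NO_HEARTBEAT = "no heartbeat detected"
OK = "ok"


@dataclass(frozen=True)
class AreaTrace:
    """Per-frame ventricular area (pixel counts) with the acquisition rate."""

    areas: np.ndarray
    fps: float

    def __post_init__(self):
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        if self.areas.ndim != 1 or len(self.areas) < 1:
            raise ValueError("areas must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(self.areas)) or np.any(self.areas < 0):
            raise ValueError("areas must be finite and nonnegative")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def duration_seconds(self) -> float:
        return len(self.areas) / self.fps


@dataclass(frozen=True)
class AxisPair:
    """Long axis a, short axis b (pixels) and orientation of the long side."""

    a: float
    b: float
    angle: float = 0.0

    def __post_init__(self):
        if not (self.a >= self.b >= 0):
            raise ValueError("requires a >= b >= 0")


@dataclass(frozen=True)
class CycleMarkers:
    """Detected cardiac cycles.

    `cycles` holds matched (ed_frame, es_frame) index pairs used to sample
    EDA/ESA and the rectangle axes. `n_cycles` is the contraction count used
    for heart rate: the larger of the ED-peak and ES-trough counts, which is
    what counting beats by eye gives regardless of where in the cycle the
    video starts and ends (a trailing systole without a following trough is
    still one beat).
    """

    cycles: tuple
    ed_frames: tuple
    es_frames: tuple
    n_cycles: int = 0
    status: str = OK


@dataclass
class CardiacParams:
    """The six cardiac parameters plus the pericardial-edema flag.

    `edema` uses the screening Boolean coding: 1 = normal, 0 = edema.
    Unavailable values (no detectable heartbeat) are NaN with status set.
    """

    EDA: float = math.nan
    ESA: float = math.nan
    ED_axes: AxisPair | None = None
    ES_axes: AxisPair | None = None
    FAC: float = math.nan
    FS: float = math.nan
    SV: float = math.nan
    HR: float = math.nan
    edema: int = 1
    n_cycles: int = 0
    status: str = OK

    def as_dict(self) -> dict:
        ed = self.ED_axes or AxisPair(math.nan, math.nan)
        es = self.ES_axes or AxisPair(math.nan, math.nan)
        return {
            "EDA": self.EDA, "ESA": self.ESA,
            "EDa": ed.a, "EDb": ed.b, "ESa": es.a, "ESb": es.b,
            "FAC": self.FAC, "FS": self.FS, "SV": self.SV, "HR": self.HR,
            "edema": self.edema, "n_cycles": self.n_cycles,
            "status": self.status,
        }


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def mask_area(mask: np.ndarray) -> int:
    """Number of foreground pixels in a binary mask."""
    m = np.asarray(mask)
    return int(np.count_nonzero(m))


def min_area_rect(mask: np.ndarray) -> AxisPair:
    """Rotated minimum-area rectangle enclosing the mask foreground.

    Pixels are unit squares: the rectangle encloses the four corners of every
    foreground pixel, so a single pixel yields a 1x1 rectangle. Returns the
    longer side as `a`, the shorter as `b`, and the long-side orientation in
    degrees (counter-clockwise from the +col axis, in [0, 180)).
    """
    m = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(m)
    if len(rows) == 0:
        raise ValueError("empty mask: no ventricle to enclose")
    # corners of each unit-square pixel, (x, y) = (col, row)
    x = np.concatenate([cols, cols + 1, cols, cols + 1]).astype(float)
    y = np.concatenate([rows, rows, rows + 1, rows + 1]).astype(float)
    rect = MultiPoint(np.column_stack([x, y])).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]  # 4 corners
    s1 = coords[1] - coords[0]
    s2 = coords[2] - coords[1]
    l1, l2 = float(np.hypot(*s1)), float(np.hypot(*s2))
    if l1 >= l2:
        a, b, v = l1, l2, s1
    else:
        a, b, v = l2, l1, s2
    angle = math.degrees(math.atan2(v[1], v[0])) % 180.0
    return AxisPair(a=a, b=b, angle=angle)


def area_trace(masks: np.ndarray, fps: float) -> AreaTrace:
    """Per-frame foreground pixel counts of a (T, H, W) mask sequence."""
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("masks must be a (T, H, W) sequence")
    return AreaTrace(areas=np.count_nonzero(masks, axis=(1, 2)), fps=fps)


# --------------------------------------------------------------------------
# Cycle detection
# --------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def detect_cycles(trace: AreaTrace, smooth_window: int | None = None,
                  prominence_frac: float = 0.05) -> CycleMarkers:
    """Detect cardiac cycles as paired area maxima (ED) and minima (ES).

    The trace is smoothed with a moving average (window defaults to
    max(3, fps/20) frames) and extrema are found with a prominence threshold
    of `prominence_frac` of the trace's dynamic range. Each ED peak is paired
    with the first ES trough that follows it before the next ED; the
    contraction count `n_cycles` is the larger of the ED and ES event counts,
    so a beat whose trough falls past the end of the video is still counted.
    A flat or monotone trace yields zero cycles and the "no heartbeat
    detected" status.
    """
    x = trace.areas
    if smooth_window is None:
        smooth_window = max(3, int(round(trace.fps / 20.0)))
    xs = _smooth(x, smooth_window)
    rng_ = float(xs.max() - xs.min())
    if rng_ <= 0:
        return CycleMarkers((), (), (), status=NO_HEARTBEAT)
    prom = prominence_frac * rng_
    ed, _ = find_peaks(xs, prominence=prom)
    es, _ = find_peaks(-xs, prominence=prom)
    if len(ed) == 0 or len(es) == 0:
        return CycleMarkers((), (), (), status=NO_HEARTBEAT)
    cycles = []
    for i, e in enumerate(ed):
        nxt = ed[i + 1] if i + 1 < len(ed) else len(x)
        cand = es[(es > e) & (es < nxt)]
        if len(cand) == 0:
            continue
        s = int(cand[0])
        if x[e] < x[s]:
            logger.warning("rejected cycle (ED area < ES area) at frames "
                           "%d -> %d", e, s)
            continue
        cycles.append((int(e), s))
    status = OK if cycles else NO_HEARTBEAT
    return CycleMarkers(tuple(cycles), tuple(int(i) for i in ed),
                        tuple(int(i) for i in es),
                        n_cycles=max(len(ed), len(es)) if cycles else 0,
                        status=status)


# --------------------------------------------------------------------------
# Closed-form parameters
# --------------------------------------------------------------------------

def fac(EDA: float, ESA: float) -> float:
    """Fractional area change, (EDA - ESA)/EDA x 100 (percent)."""
    if not EDA > 0:
        raise ValueError("EDA must be positive")
    return (EDA - ESA) / EDA * 100.0


def fs(EDa: float, ESa: float) -> float:
    """Fractional shortening, (EDa - ESa)/EDa x 100 (percent)."""
    if not EDa > 0:
        raise ValueError("EDa must be positive")
    return (EDa - ESa) / EDa * 100.0


def sv(ED_axes: AxisPair, ES_axes: AxisPair,
       convention: str = "as-printed") -> float:
    """Stroke volume from ED/ES rectangle axes (ellipsoid volume difference).

    convention="as-printed" uses the axis lengths directly:
    4/3 pi (EDa EDb^2 - ESa ESb^2). convention="semi-axis" halves every axis
    first (prolate-spheroid volumes), which divides the result by 8. A
    negative result is allowed but logged: it indicates ES/ED mis-detection.
    """
    if convention not in ("as-printed", "semi-axis"):
        raise ValueError(f"unknown SV convention: {convention!r}")
    v = (4.0 / 3.0) * math.pi * (ED_axes.a * ED_axes.b ** 2
                                 - ES_axes.a * ES_axes.b ** 2)
    if convention == "semi-axis":
        v /= 8.0
    if v < 0:
        logger.warning("negative stroke volume (%g): ES larger than ED", v)
    return v


def hr_from_cycles(n_cycles: int, duration_seconds: float) -> float:
    """Heart rate in bpm: contraction cycles over video length, times 60."""
    if not duration_seconds > 0:
        raise ValueError("duration must be positive")
    return n_cycles / duration_seconds * 60.0


# --------------------------------------------------------------------------
# Full per-larva analysis
# --------------------------------------------------------------------------

def analyze_video(masks: np.ndarray, fps: float, edema: int = 1,
                  sv_convention: str = "as-printed",
                  ed_es_mode: str = "mean",
                  hr_mode: str = "video",
                  smooth_window: int | None = None,
                  prominence_frac: float = 0.05) -> CardiacParams:
    """Full cardiac parameter extraction for one larva's mask sequence.

    Detects cycles on the area trace, measures EDA/ESA and the rectangle axes
    at the selected ED/ES frames, and evaluates FAC, FS, SV and HR.

    ed_es_mode="mean" averages per-cycle ED/ES values (robust to a slightly
    irregular beat); "extremum" uses the global trace maximum/minimum.
    hr_mode="video" counts cycles over the full video length; "spanned"
    divides the between-ED cycle count by the first-to-last-ED time span.
    When no cycle is detectable a partial result is returned with HR, FAC,
    FS and SV marked unavailable (NaN) and status set.
    """
    if ed_es_mode not in ("mean", "extremum"):
        raise ValueError(f"unknown ed_es_mode: {ed_es_mode!r}")
    if hr_mode not in ("video", "spanned"):
        raise ValueError(f"unknown hr_mode: {hr_mode!r}")
    trace = area_trace(masks, fps)
    markers = detect_cycles(trace, smooth_window=smooth_window,
                            prominence_frac=prominence_frac)
    if markers.n_cycles == 0:
        return CardiacParams(edema=edema, n_cycles=0, status=markers.status)

    if ed_es_mode == "mean":
        ed_frames = [c[0] for c in markers.cycles]
        es_frames = [c[1] for c in markers.cycles]
    else:
        ed_frames = [int(np.argmax(trace.areas))]
        es_frames = [int(np.argmin(trace.areas))]

    EDA = float(np.mean([trace.areas[i] for i in ed_frames]))
    ESA = float(np.mean([trace.areas[i] for i in es_frames]))
    ed_rects = [min_area_rect(masks[i]) for i in ed_frames]
    es_rects = [min_area_rect(masks[i]) for i in es_frames]
    ED_axes = AxisPair(a=float(np.mean([r.a for r in ed_rects])),
                       b=float(np.mean([r.b for r in ed_rects])),
                       angle=float(np.mean([r.angle for r in ed_rects])))
    ES_axes = AxisPair(a=float(np.mean([r.a for r in es_rects])),
                       b=float(np.mean([r.b for r in es_rects])),
                       angle=float(np.mean([r.angle for r in es_rects])))

    if hr_mode == "video" or len(markers.ed_frames) < 2:
        HR = hr_from_cycles(markers.n_cycles, trace.duration_seconds)
    else:
        span = (markers.ed_frames[-1] - markers.ed_frames[0]) / fps
        HR = hr_from_cycles(len(markers.ed_frames) - 1, span)

    return CardiacParams(
        EDA=EDA, ESA=ESA, ED_axes=ED_axes, ES_axes=ES_axes,
        FAC=fac(EDA, ESA), FS=fs(ED_axes.a, ES_axes.a),
        SV=sv(ED_axes, ES_axes, convention=sv_convention), HR=HR,
        edema=edema, n_cycles=markers.n_cycles, status=OK,
    )
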