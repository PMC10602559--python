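"""File formats: TIFF video stacks, PNG masks, CSV tables, JSON sidecars.

Conventions: videos are multi-page TIFF (16-bit on export, any bit depth on
import, normalized to [0, 1] by the dtype range); masks are per-frame 8-bit
PNGs with values 0/255; tables are CSV with a fixed column order and floats
at 6 significant digits, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cardiometrics import CardiacParams
from .video import HeartVideo

PARAMS_COLUMNS = ["id", "EDA", "ESA", "EDa", "EDb", "ESa", "ESb", "FAC",
                  "FS", "SV", "HR", "edema", "n_cycles", "status"]
SCREEN_COLUMNS = ["rank", "compound", "efficacy_score", "is_hit",
                  "n_parameters", "RI_EDA", "RI_ESA", "RI_FAC", "RI_FS",
                  "RI_SV", "RI_HR", "RI_edema"]
FLOAT_FORMAT = "%.6g"


# --------------------------------------------------------------------------
# Videos
# --------------------------------------------------------------------------

def read_video(path, fps: float | None = None) -> HeartVideo:
    """Read a multi-page TIFF (or any imageio-readable stack) as a HeartVideo.

    Intensities are normalized to [0, 1] by the dtype range (255 for uint8,
    65535 for uint16; floats are used as-is). TIFF carries no standard frame
    rate, so `fps` is required unless a JSON sidecar written by this package
    sits next to the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fps is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fps = meta.get("fps")
    if fps is None:
        raise ValueError(f"missing field 'fps' for {path.name}: pass fps "
                         "explicitly (TIFF stores no frame rate)")
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
    else:
        stack = iio.imread(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path.name}: expected a (T, H, W) stack, got "
                         f"shape {stack.shape}")
    if stack.shape[0] == 0:
        raise ValueError(f"{path.name}: zero frames")
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.float32) / np.iinfo(stack.dtype).max
    else:
        stack = np.clip(stack.astype(np.float32), 0.0, 1.0)
    return HeartVideo(frames=stack, fps=float(fps))


def write_video_tiff(video: HeartVideo, path, sidecar: dict | None = None):
    """Write a 16-bit multi-page TIFF plus a JSON sidecar carrying fps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(video.frames, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535.0 + 0.5).astype(np.uint16))
    meta = {"fps": video.fps, "n_frames": video.n_frames}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2,
                                                    sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Masks
# --------------------------------------------------------------------------

def write_masks_png(masks: np.ndarray, out_dir, prefix: str = "mask"):
    """One 8-bit PNG (0/255) per frame: <prefix>_<frame:04d>.png."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(np.asarray(masks).astype(bool)):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (m * np.uint8(255)))
        paths.append(p)
    return paths


def read_masks_png(paths_or_dir, prefix: str = "mask") -> np.ndarray:
    """Read a PNG mask sequence back to a (T, H, W) bool array."""
    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, Path)) else None
    files = (sorted(p.glob(f"{prefix}_*.png")) if p is not None
             else [Path(f) for f in paths_or_dir])
    if not files:
        raise FileNotFoundError("no mask PNGs found")
    return np.stack([iio.imread(f) > 127 for f in files])


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def ground_truth_table(spec, masks: np.ndarray) -> pd.DataFrame:
    """Per-frame ground truth of a simulation: frame_index, area_px, a_px,
    b_px (full axis lengths of the generating ellipse)."""
    from .simdata import analytic_trace
    a, b, _ = analytic_trace(spec)
    areas = np.count_nonzero(np.asarray(masks), axis=(1, 2))
    return pd.DataFrame({"frame_index": np.arange(len(areas)),
                         "area_px": areas, "a_px": 2 * a, "b_px": 2 * b})


def write_ground_truth(spec, masks: np.ndarray, path) -> Path:
    """Ground-truth CSV plus a JSON sidecar holding the spec and true HR."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ground_truth_table(spec, masks).to_csv(path, index=False,
                                           float_format=FLOAT_FORMAT)
    meta = dataclasses.asdict(spec)
    meta["true_hr_bpm"] = spec.hr_bpm
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2,
                                                    sort_keys=True))
    return path


def params_table(records: dict[str, CardiacParams]) -> pd.DataFrame:
    """One row per larva in the fixed column order."""
    rows = []
    for larva_id, p in records.items():
        row = {"id": larva_id}
        row.update(p.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=PARAMS_COLUMNS)


def write_params_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_params_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def screen_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"rank": r.rank, "compound": r.compound,
               "efficacy_score": r.efficacy_score, "is_hit": r.is_hit,
               "n_parameters": r.n_parameters}
        for p, v in r.rescue_indices.items():
            row[f"RI_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def write_screen_report(results, csv_path, txt_path=None) -> Path:
    """Ranked screen results as CSV and an optional plain-text report."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    screen_table(results).to_csv(csv_path, index=False,
                                 float_format=FLOAT_FORMAT)
    if txt_path is not None:
        lines = ["Phenotypic screen report", "========================", ""]
        for r in results:
            flag = "HIT" if r.is_hit else "   "
            lines.append(f"{r.rank:3d}. {flag} {r.compound:<20s} "
                         f"score={r.efficacy_score:+.4f} "
                         f"(n_params={r.n_parameters})")
        n_hits = sum(r.is_hit for r in results)
        lines += ["", f"{n_hits} hit(s) out of {len(results)} compound(s)."]
        Path(txt_path).write_text("\n".join(lines) + "\n")
    return csv_path
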