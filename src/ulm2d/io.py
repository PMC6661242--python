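"""Reading and writing loops, ground truth, events and tracks.

Frames travel as multi-page TIFF (16-bit) with a JSON sidecar carrying
pixel pitch, frame rate, seeds and the generator config, or as DICOM
multiframe from a scanner.  Tabular artifacts (ground truth, events,
tracks) are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .sequence import FrameSequence

__all__ = ["load_sequence", "save_sequence", "write_ground_truth_csv",
           "read_ground_truth_csv", "FormatError", "MetadataError"]


class FormatError(ValueError):
    """Unsupported or malformed image content."""


class MetadataError(ValueError):
    """Pixel pitch or frame rate unavailable from file and arguments."""


def _apply_crop(frames: np.ndarray, crop: tuple[int, int, int, int] | None) -> np.ndarray:
    if crop is None:
        return frames
    x, y, w, h = crop
    if w <= 0 or h <= 0:
        raise ValueError("crop width and height must be positive")
    return frames[:, y:y + h, x:x + w]


def load_sequence(path: str | Path,
                  format: str | None = None,
                  crop: tuple[int, int, int, int] | None = None,
                  pixel_pitch_um: float | None = None,
                  frame_rate_hz: float | None = None,
                  allow_color_mean: bool = False) -> FrameSequence:
    """Load a grayscale loop from multi-page TIFF or multiframe DICOM.

    Pixel pitch and frame rate come from file metadata (DICOM tags, TIFF
    JSON sidecar) when present, else from the explicit arguments; a
    :class:`MetadataError` is raised if neither source provides them.
    ``crop`` is (x, y, w, h) in pixels.  Color content is refused unless
    ``allow_color_mean`` documents the grayscale conversion (channel mean).
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.suffix.lower() in {".dcm", ".dicom"} else "tiff"

    meta: dict = {}
    if format == "tiff":
        frames = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    elif format == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        frames = ds.pixel_array
        # PixelSpacing is mm; FrameTime is ms per frame.
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            meta["pixel_pitch_um"] = float(spacing[0]) * 1000.0
        ft = getattr(ds, "FrameTime", None)
        if ft:
            meta["frame_rate_hz"] = 1000.0 / float(ft)
        elif getattr(ds, "CineRate", None):
            meta["frame_rate_hz"] = float(ds.CineRate)
    else:
        raise FormatError(f"unknown format {format!r}")

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:
        if not allow_color_mean:
            raise FormatError(
                "color content: pass allow_color_mean=True to average channels")
        frames = frames.mean(axis=-1)
    if frames.ndim != 3:
        raise FormatError(f"expected a frame stack, got shape {frames.shape}")

    frames = _apply_crop(frames, crop)

    pitch = pixel_pitch_um if pixel_pitch_um is not None else meta.get("pixel_pitch_um")
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if pitch is None or rate is None:
        raise MetadataError(
            "pixel pitch / frame rate missing from file metadata; pass "
            "pixel_pitch_um and frame_rate_hz explicitly")
    return FrameSequence(frames=[f.astype(float) for f in frames],
                         pixel_pitch_um=float(pitch), frame_rate_hz=float(rate),
                         metadata={"source": str(path), **meta})


def save_sequence(sequence: FrameSequence, path: str | Path) -> Path:
    """Write a loop as 16-bit multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack([np.clip(np.round(f), 0, 65535).astype(np.uint16)
                      for f in sequence.frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {"pixel_pitch_um": sequence.pixel_pitch_um,
               "frame_rate_hz": sequence.frame_rate_hz,
               **{k: v for k, v in sequence.metadata.items()
                  if isinstance(v, (int, float, str, bool, list, dict))}}
    sidecar.write_text(json.dumps(payload, indent=1, default=str))
    return path


def write_ground_truth_csv(records, appearances, path: str | Path) -> Path:
    """Ground truth as CSV: frame, particle_id, x_um, y_um, merged_label, peak."""
    rows = []
    for rec in records:
        for pid, (x, y), lab in zip(rec.particle_ids, rec.xy_um, rec.merged_labels):
            rows.append((rec.frame_index, int(pid), float(x), float(y), int(lab),
                         float(appearances[int(pid)].peak_intensity)
                         if appearances else np.nan))
    df = pd.DataFrame(rows, columns=["frame", "particle_id", "x_um", "y_um",
                                     "merged_label", "peak_intensity"])
    df.to_csv(path, index=False)
    return Path(path)


def read_ground_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
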