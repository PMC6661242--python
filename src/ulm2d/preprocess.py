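"""Pre-injection artifact masking and rigid in-plane motion compensation.

Clinical contrast loops carry two nuisances the detector must not see:
static bright echoes already present before contrast arrival (reverberant
tissue interfaces) and breathing-periodic in-plane translation.  The mask
excludes the former from all downstream processing; translation-only
phase correlation against a reference frame removes the latter (the
motion is in-plane and rigid by experimental design, so no rotation is
fitted by default).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .sequence import FrameSequence

__all__ = ["build_artifact_mask", "rigid_register", "apply_mask"]


def build_artifact_mask(preinjection_frames,
                        intensity_quantile: float = 0.98) -> np.ndarray:
    """Mask pixels persistently bright across all pre-injection frames.

    A pixel is masked when, in *every* pre-injection frame, its value
    exceeds that frame's ``intensity_quantile`` level.  Transient speckle
    fails the persistence requirement; static artifacts do not.
    Constant (all-equal) frames yield an empty mask.
    """
    frames = [np.asarray(f, float) for f in preinjection_frames]
    if not frames:
        raise ValueError("need at least one pre-injection frame")
    mask = np.ones_like(frames[0], dtype=bool)
    for f in frames:
        thresh = np.quantile(f, intensity_quantile)
        if thresh <= f.min():      # flat frame: nothing stands out
            return np.zeros_like(mask)
        mask &= f > thresh
    return mask


def apply_mask(frame: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Zero out masked pixels (True = excluded)."""
    if mask is None:
        return frame
    out = frame.copy()
    out[mask] = 0.0
    return out


def rigid_register(sequence: FrameSequence,
                   reference_index: int = 0,
                   upsample_factor: int = 10
                   ) -> tuple[FrameSequence, np.ndarray]:
    """Translate every frame onto the reference frame.

    Sub-pixel shifts are estimated by phase correlation and applied by
    linear interpolation with zero fill outside the field of view; frame
    count and intensities are otherwise untouched.  Returns the aligned
    sequence and the per-frame (row, col) shifts that were applied.
    Degenerate flat frames register with a warning and zero shift.
    """
    if len(sequence) < 2:
        raise ValueError("registration needs at least two frames")
    ref = np.asarray(sequence[reference_index], float)
    shifts = np.zeros((len(sequence), 2))
    aligned = []
    for i, frame in enumerate(sequence.frames):
        frame = np.asarray(frame, float)
        if i == reference_index:
            aligned.append(frame.copy())
            continue
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"flat frame at index {i}: zero shift assumed")
            aligned.append(frame.copy())
            continue
        # window both images so the field-of-view edges (zero fill after
        # shifting) do not dominate the correlation
        win = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
        shift, _, _ = phase_cross_correlation(ref * win, frame * win,
                                              upsample_factor=upsample_factor)
        shifts[i] = shift
        aligned.append(ndimage.shift(frame, shift, order=1, mode="constant",
                                     cval=0.0))
    out = FrameSequence(frames=aligned,
                        pixel_pitch_um=sequence.pixel_pitch_um,
                        frame_rate_hz=sequence.frame_rate_hz,
                        metadata={**sequence.metadata,
                                  "registered_to": reference_index})
    return out, shifts
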