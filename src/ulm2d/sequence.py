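"""Frame-sequence container shared by the simulator and the analysis pipeline.

Physical coordinates are continuous, in micrometers, with the origin at the
top-left corner of the image.  Pixel (i, j) (row i, column j) is a square of
side ``pixel_pitch`` whose center sits at ``((j + 0.5) * pitch, (i + 0.5) * pitch)``
in (x, y).  All ground-truth positions and localizations are reported in this
frame, so simulator output and detector output are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reference pixel pitch of the clinical contrast loops, micrometers.
DEFAULT_PIXEL_PITCH_UM = 132.0


@dataclass
class FrameSequence:
    """An ordered stack of 2D grayscale frames with physical metadata.

    Parameters
    ----------
    frames : list of ndarray
        Non-negative 2D grayscale arrays, all of one shape, row-major,
        origin top-left.
    pixel_pitch_um : float
        Side of a pixel in micrometers (reference value 132).
    frame_rate_hz : float
        Acquisition rate in frames per second.
    metadata : dict
        Free-form provenance (seeds, generator config, source file).
    """

    frames: list[np.ndarray]
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_rate_hz: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames do not share one shape: {shapes}")
        for f in self.frames:
            if f.ndim != 2:
                raise ValueError("frames must be 2D grayscale arrays")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, index: int) -> np.ndarray:
        return self.frames[index]

    @property
    def shape(self) -> tuple[int, int]:
        if not self.frames:
            return (0, 0)
        return self.frames[0].shape

    @property
    def duration_s(self) -> float:
        """Loop duration in seconds (n_frames / frame_rate)."""
        return len(self.frames) / self.frame_rate_hz

    def pixel_center_um(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical center of pixel (row, col) in micrometers."""
        p = self.pixel_pitch_um
        return (np.asarray(col) + 0.5) * p, (np.asarray(row) + 0.5) * p


def pixel_centers_um(shape: tuple[int, int], pitch_um: float):
    """Coordinate grids (x, y) of the pixel centers of an image of `shape`."""
    rows = np.arange(shape[0])
    cols = np.arange(shape[1])
    x = (cols + 0.5) * pitch_um
    y = (rows + 0.5) * pitch_um
    return np.meshgrid(x, y)
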