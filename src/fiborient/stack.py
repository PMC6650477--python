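"""In-memory z-stack container with physical calibration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A 3D grayscale raster (z, y, x) with physical calibration.

    Attributes
    ----------
    data:
        ``(n_z, n_y, n_x)`` 8-bit intensity array. Axis 1 is the image
        y-axis, axis 2 the x-axis; orientation 0° points along +x and
        increases counter-clockwise toward +y.
    pixel_pitch:
        In-plane sampling, µm per pixel (square pixels).
    z_interval:
        Spacing between consecutive slices, µm.
    channel:
        Label of the imaging channel, e.g. ``"collagen"`` (SHG contrast)
        or ``"elastic"`` (TPAF contrast).
    """

    data: np.ndarray
    pixel_pitch: float
    z_interval: float
    channel: str = "collagen"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (z, y, x)")
        if self.pixel_pitch <= 0 or self.z_interval <= 0:
            raise ValueError("pixel_pitch and z_interval must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, z_index: int) -> np.ndarray:
        return self.data[z_index]
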