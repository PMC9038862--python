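"""2-D perfusion images (rendered phantoms or single DCE timepoints)."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PerfusionImage", "downsample"]


@dataclass
class PerfusionImage:
    """A single-timepoint grayscale perfusion image with physical pixel spacing.

    ``pixels`` is a 2-D float array indexed [row, col]; ``pixel_spacing`` is the
    isotropic in-plane spacing in mm; ``origin`` is the physical (x, y) position
    of the center of pixel [0, 0] in mm.
    """

    pixels: np.ndarray
    pixel_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: str = "phantom"  # "phantom" | "dce_timepoint"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.provenance not in ("phantom", "dce_timepoint"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "PerfusionImage":
        return replace(self, pixels=np.asarray(pixels, dtype=float))

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of all pixel centers, each shaped like pixels.

        Columns advance along x, rows along y.
        """
        nr, nc = self.pixels.shape
        x = self.origin[0] + np.arange(nc) * self.pixel_spacing
        y = self.origin[1] + np.arange(nr) * self.pixel_spacing
        return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]


def downsample(image: PerfusionImage, target_spacing: float) -> PerfusionImage:
    """Block-average resampling to a coarser grid.

    The target spacing must be an integer multiple of the native spacing and at
    least as coarse; the image shape must be divisible by the block factor.
    Mean intensity is preserved exactly up to floating-point rounding.
    """
    if target_spacing < image.pixel_spacing - 1e-9:
        raise ValueError("downsample cannot refine the grid (upsampling requested)")
    factor_f = target_spacing / image.pixel_spacing
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6:
        raise ValueError(
            f"target spacing {target_spacing} is not an integer multiple of "
            f"native spacing {image.pixel_spacing}")
    if factor == 1:
        return replace(image, pixels=image.pixels.copy())
    nr, nc = image.pixels.shape
    if nr % factor or nc % factor:
        raise ValueError(f"image shape {image.pixels.shape} not divisible by block factor {factor}")
    blocks = image.pixels.reshape(nr // factor, factor, nc // factor, factor)
    out = blocks.mean(axis=(1, 3))
    # Pixel centers shift by half the block growth.
    shift = (factor - 1) / 2.0 * image.pixel_spacing
    origin = (image.origin[0] + shift, image.origin[1] + shift)
    return PerfusionImage(out, target_spacing, origin, image.provenance)
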