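"""File I/O for phantom images, FD maps and ROI masks."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fractal_core import FdMap
from .image import PerfusionImage
from .roi import MarginRoi

__all__ = ["write_phantom_tiff", "write_image_nifti", "read_image_nifti",
           "write_roi_rle", "read_roi_rle", "write_roi_overlay_png",
           "write_fd_map_nifti", "write_fd_overlay_png"]


def write_phantom_tiff(image: PerfusionImage, path) -> None:
    """16-bit grayscale TIFF with the pixel spacing in the resolution tags."""
    import tifffile

    g = image.pixels
    lo, hi = float(g.min()), float(g.max())
    scaled = np.zeros_like(g) if hi - lo < 1e-12 else (g - lo) / (hi - lo)
    data = (scaled * 65535).round().astype(np.uint16)
    # TIFF resolution is pixels per unit; use centimeters
    res = 10.0 / image.pixel_spacing
    tifffile.imwrite(str(path), data, resolution=(res, res),
                     resolutionunit="CENTIMETER",
                     metadata={"pixel_spacing_mm": image.pixel_spacing,
                               "intensity_range": [lo, hi]})


def write_image_nifti(image: PerfusionImage, path) -> None:
    """Float NIfTI with the in-plane spacing in the header zooms."""
    import nibabel as nib

    data = image.pixels.astype(np.float32)[:, :, None]
    affine = np.diag([image.pixel_spacing, image.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((image.pixel_spacing, image.pixel_spacing, 1.0))
    nib.save(img, str(path))


def read_image_nifti(path, provenance: str = "phantom") -> PerfusionImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"expected a single 2-D slice in {path}")
    return PerfusionImage(data.astype(float), float(img.header.get_zooms()[0]),
                          provenance=provenance)


def write_roi_rle(roi: MarginRoi, path) -> None:
    Path(path).write_text(json.dumps(roi.to_rle(), indent=1))


def read_roi_rle(path) -> MarginRoi:
    return MarginRoi.from_rle(json.loads(Path(path).read_text()))


def write_roi_overlay_png(image: PerfusionImage, roi: MarginRoi, path) -> None:
    """Grayscale image with the ROI painted red, for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = image.pixels
    lo, hi = float(g.min()), float(g.max())
    norm = np.zeros_like(g) if hi - lo < 1e-12 else (g - lo) / (hi - lo)
    rgb = np.stack([norm] * 3, axis=-1)
    m = roi.mask(g.shape)
    rgb[m] = [1.0, 0.1, 0.1]
    plt.imsave(str(path), rgb)


def write_fd_map_nifti(fdm: FdMap, pixel_spacing: float, path) -> None:
    """FD map as float NIfTI; invalid pixels carry NaN."""
    import nibabel as nib

    data = np.where(fdm.valid_mask, fdm.fd, np.nan).astype(np.float32)[:, :, None]
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_fd_overlay_png(fdm: FdMap, background: PerfusionImage, path,
                         *, alpha: float = 0.6) -> None:
    """Color-mapped FD overlay on an anatomical background image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = background.pixels
    lo, hi = float(g.min()), float(g.max())
    norm = np.zeros_like(g) if hi - lo < 1e-12 else (g - lo) / (hi - lo)
    rgb = np.stack([norm] * 3, axis=-1)
    fd_norm = np.clip((fdm.fd - 2.0), 0, 1)
    colored = plt.get_cmap("turbo")(fd_norm)[..., :3]
    m = fdm.valid_mask
    rgb[m] = (1 - alpha) * rgb[m] + alpha * colored[m]
    plt.imsave(str(path), np.clip(rgb, 0, 1))
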