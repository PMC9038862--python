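"""Standardization of perfusion images before fractal analysis.

Blanket-method fractal dimension compares intensity steps (in gray levels)
against spatial steps (in pixels), so it is only comparable across scanners,
doses and timepoints after the images share a common dynamic range. This
module provides noise-adapted denoising and robust affine intensity
calibration to a fixed gray-level range, applied per 2-D frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from skimage.restoration import denoise_bilateral

from .image import PerfusionImage

__all__ = ["DceSeries", "estimate_noise", "denoise", "calibrate_intensity",
           "preprocess_frame", "read_dce_nifti", "read_dicom_series",
           "read_lesion_table"]


@dataclass
class DceSeries:
    """An ordered dynamic contrast-enhanced series of 2-D frames.

    Frames share grid and spacing; ``frame_times`` are acquisition times in
    seconds, strictly increasing (clinical temporal resolution is ~3.5 s).
    """

    frames: list[PerfusionImage]
    frame_times: np.ndarray
    slice_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a DCE series needs at least one frame")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        shape = self.frames[0].shape
        sp = self.frames[0].pixel_spacing
        for f in self.frames[1:]:
            if f.shape != shape or abs(f.pixel_spacing - sp) > 1e-9:
                raise ValueError("all frames must share grid and spacing")

    def __len__(self) -> int:
        return len(self.frames)


def estimate_noise(image: PerfusionImage | np.ndarray) -> float:
    """Robust noise sigma from the finest diagonal wavelet detail band.

    The HH band of a single-level Haar decomposition carries (for white noise)
    the same sigma as the image; the Donoho-Johnstone estimator
    sigma = median(|HH|) / 0.6745 is insensitive to edges and to any constant
    offset. A constant image yields exactly 0.
    """
    g = np.asarray(image.pixels if isinstance(image, PerfusionImage) else image,
                   dtype=float)
    if g.shape[0] < 16 or g.shape[1] < 16:
        raise ValueError("noise estimation needs at least 16x16 pixels")
    _, (_, _, hh) = pywt.dwt2(g, "haar")
    return float(np.median(np.abs(hh)) / 0.6745)


def denoise(image: PerfusionImage, noise_sigma: float, *,
            range_factor: float = 2.0, spatial_sigma: float = 2.0) -> PerfusionImage:
    """Edge-preserving bilateral smoothing with strength tied to the noise level.

    The bilateral range parameter is ``range_factor * noise_sigma`` (intensity
    units) and the spatial kernel has ``spatial_sigma`` pixels; with
    ``noise_sigma = 0`` the operation is the identity.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return image.with_pixels(image.pixels.copy())
    g = image.pixels
    lo, hi = float(g.min()), float(g.max())
    if hi - lo < 1e-12:
        return image.with_pixels(g.copy())
    # run the bilateral filter on a [0, 1]-normalized copy with the range
    # parameter expressed in the same normalized units
    norm = (g - lo) / (hi - lo)
    sigma_color = range_factor * noise_sigma / (hi - lo)
    out = denoise_bilateral(norm, sigma_color=sigma_color,
                            sigma_spatial=spatial_sigma,
                            mode="edge") * (hi - lo) + lo
    return image.with_pixels(out)


def calibrate_intensity(image: PerfusionImage, *, p_lo: float = 1.0,
                        p_hi: float = 99.0, dynamic_range: float = 255.0
                        ) -> PerfusionImage:
    """Affine rescale of the robust percentile range onto [0, dynamic_range].

    The [p_lo, p_hi] percentiles map to [0, G] and values beyond are clipped,
    making downstream fractal dimension invariant to any positive affine
    intensity transform (scanner gain, contrast dose). A constant image maps
    to G/2.
    """
    g = image.pixels
    lo, hi = np.percentile(g, [p_lo, p_hi])
    if hi - lo < 1e-12:
        return image.with_pixels(np.full_like(g, dynamic_range / 2.0))
    out = np.clip((g - lo) / (hi - lo), 0.0, 1.0) * dynamic_range
    return image.with_pixels(out)


def preprocess_frame(image: PerfusionImage, *, denoise_image: bool = True,
                     p_lo: float = 1.0, p_hi: float = 99.0,
                     dynamic_range: float = 255.0) -> PerfusionImage:
    """Full standardization of one frame: noise-adapted denoising + calibration."""
    out = image
    if denoise_image:
        out = denoise(out, estimate_noise(out))
    return calibrate_intensity(out, p_lo=p_lo, p_hi=p_hi,
                               dynamic_range=dynamic_range)


# -- readers -----------------------------------------------------------------

def read_dce_nifti(path, slice_index: int, *, frame_dt: float = 3.5) -> DceSeries:
    """Load a 4-D NIfTI DCE volume (x, y, z, t) as a per-slice 2-D series."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) NIfTI volume")
    spacing = float(img.header.get_zooms()[0])
    frames = [PerfusionImage(data[:, :, slice_index, t].astype(float), spacing,
                             provenance="dce_timepoint")
              for t in range(data.shape[3])]
    times = np.arange(data.shape[3], dtype=float) * frame_dt
    return DceSeries(frames, times, slice_index,
                     metadata={"path": str(path)})


def read_dicom_series(directory, *, frame_dt: float = 3.5) -> DceSeries:
    """Load a directory of single-slice DICOM files, ordered by instance number."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    dsets = sorted((pydicom.dcmread(str(f)) for f in files),
                   key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    spacing = float(dsets[0].PixelSpacing[0])
    frames = [PerfusionImage(d.pixel_array.astype(float), spacing,
                             provenance="dce_timepoint") for d in dsets]
    times = np.arange(len(frames), dtype=float) * frame_dt
    return DceSeries(frames, times, metadata={"path": str(directory)})


def read_lesion_table(path) -> pd.DataFrame:
    """Lesion centroid table: patient_id, lesion_id, i, j, k, ISUP_group.

    Coordinates follow the PROSTATEx findings-table convention of 0-based
    voxel indices.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "lesion_id", "i", "j", "k", "ISUP_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    return df
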