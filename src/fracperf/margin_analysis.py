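"""Tumor-margin ROI delineation and lesion-level summary statistics.

Angiogenesis concentrates at the tumor margin while vessels stabilize in the
core, so the lesion statistic is the mean local fractal dimension over a
serpentine band at the contrast-enhancing lesion periphery, maximized over
DCE timepoints. The comparator biomarker is a low percentile of the apparent
diffusion coefficient (ADC) in the lowest-ADC tumor region.
"""
from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import binary_dilation, binary_erosion, disk

from .fractal_core import FdMap
from .image import PerfusionImage
from .roi import MarginRoi

__all__ = ["delineate_margin", "lesion_fd", "adc_percentile", "MarginRoi"]


def _seeded_component(region_mask: np.ndarray, seed_rc: tuple[int, int]) -> np.ndarray:
    """Connected component of ``region_mask`` containing the seed pixel."""
    lab = cc_label(region_mask, connectivity=2)
    lid = lab[seed_rc]
    if lid == 0:
        return np.zeros_like(region_mask)
    return lab == lid


def _lesion_mask(image: np.ndarray, centroid_rc: tuple[int, int],
                 box_radius_px: int, *, bright: bool = True) -> np.ndarray:
    """Seeded Otsu segmentation of the (hyper- or hypo-intense) lesion.

    Thresholds within a box around the centroid and keeps the connected
    component containing the centroid.
    """
    r0, c0 = centroid_rc
    if not (0 <= r0 < image.shape[0] and 0 <= c0 < image.shape[1]):
        raise ValueError("centroid outside the image")
    rs = slice(max(r0 - box_radius_px, 0), min(r0 + box_radius_px + 1, image.shape[0]))
    cs = slice(max(c0 - box_radius_px, 0), min(c0 + box_radius_px + 1, image.shape[1]))
    box = image[rs, cs]
    if np.ptp(box) < 1e-12:
        raise ValueError("no contrast around the centroid: cannot segment a lesion")
    thr = threshold_otsu(box)
    region = np.zeros(image.shape, dtype=bool)
    region[rs, cs] = box >= thr if bright else box <= thr
    comp = _seeded_component(region, centroid_rc)
    if not comp[r0, c0] or comp.sum() < 4:
        raise ValueError("no enhancing lesion found at the centroid")
    return comp


def delineate_margin(frame: PerfusionImage, centroid: tuple[int, int],
                     band_width: int = 2, *, box_mm: float = 30.0) -> MarginRoi:
    """Serpentine margin band at the periphery of the enhancing lesion.

    The lesion mask comes from seeded region growing: Otsu threshold within a
    ``box_mm``-sized box around the centroid, keeping the enhancing connected
    component that contains the centroid. The band is the morphological
    boundary zone — dilation minus erosion of the mask by ``band_width``
    pixels — i.e. the lesion periphery plus immediately adjacent tissue.
    Fully automatic; in interactive use the band can be edited afterwards.
    """
    box_radius_px = max(int(round(box_mm / 2.0 / frame.pixel_spacing)), 2)
    mask = _lesion_mask(frame.pixels, tuple(centroid), box_radius_px, bright=True)
    se = disk(band_width)
    band = binary_dilation(mask, se) & ~binary_erosion(mask, se)
    rows, cols = np.nonzero(band)
    return MarginRoi(np.column_stack([rows, cols]), band_width=band_width,
                     source_frame=0)


def lesion_fd(fd_maps: list[FdMap] | FdMap, roi: MarginRoi,
              *, min_valid: int = 10) -> tuple[float, int]:
    """Lesion FD statistic: max over timepoints of the margin-mean local FD.

    For each timepoint's FD map, the mean FD over valid ROI pixels is taken;
    the maximum of these means (and its timepoint index) is returned. This is
    monotone: adding a timepoint can never decrease the statistic. Timepoints
    with fewer than ``min_valid`` valid ROI pixels are skipped; if no
    timepoint qualifies, an error is raised.
    """
    maps = [fd_maps] if isinstance(fd_maps, FdMap) else list(fd_maps)
    if not maps:
        raise ValueError("need at least one FD map")
    best: tuple[float, int] | None = None
    for t, fdm in enumerate(maps):
        m = roi.mask(fdm.fd.shape) & fdm.valid_mask
        if int(m.sum()) < min_valid:
            continue
        mean_fd = float(fdm.fd[m].mean())
        if best is None or mean_fd > best[0]:
            best = (mean_fd, t)
    if best is None:
        raise ValueError(
            f"fewer than {min_valid} valid ROI pixels at every timepoint")
    return best


def adc_percentile(adc_map: np.ndarray, centroid: tuple[int, int],
                   percentile: float = 25.0, *, box_radius_px: int = 10,
                   region_mask: np.ndarray | None = None) -> float:
    """Low-percentile ADC in the lowest-ADC tumor region at the centroid.

    The region is segmented by seeded growing on low ADC (Otsu within a box
    around the centroid, keeping the hypo-intense component containing it),
    unless an explicit ``region_mask`` is supplied; the requested percentile
    (default 25th, 10th also in use) is computed with linear interpolation.
    """
    adc = np.asarray(adc_map, dtype=float)
    if region_mask is None:
        region = _lesion_mask(adc, tuple(centroid), box_radius_px, bright=False)
    else:
        region = np.asarray(region_mask, dtype=bool)
    vals = adc[region]
    if vals.size == 0:
        raise ValueError("empty low-ADC region")
    return float(np.percentile(vals, percentile))
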