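"""Blanket-method fractal dimension of grayscale textures.

A grayscale image is treated as a surface in 3-D (intensity as height, the
"crumpled sheet" picture): topological dimension 2, embedding dimension 3.
Peleg's blanket method grows an upper and a lower blanket around the surface,

    u_0 = b_0 = g
    u_eps(p) = max(u_{eps-1}(p) + 1, max over 4-neighbors of u_{eps-1})
    b_eps(p) = min(b_{eps-1}(p) - 1, min over 4-neighbors of b_{eps-1})

with blanket volume v_eps = sum(u_eps - b_eps) and scale-dependent surface
area A(eps) = (v_eps - v_{eps-1}) / 2. The fractal dimension follows from a
bi-logarithmic regression: FD = 2 - slope of log A against log eps, clipped
to the admissible range [2, 3].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import PerfusionImage

__all__ = ["FdMap", "blanket_surface_area", "blanket_stack", "fd_from_areas",
           "local_fd_map", "fit_territory_power_law"]

log = logging.getLogger(__name__)

_CROSS = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)  # 4-neighbors
_BOX = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)  # 8-neighbors


@dataclass
class FdMap:
    """Per-pixel local fractal dimension with validity mask and fit quality.

    ``fd`` is clipped to [2, 3]; ``clip_fraction`` records how many valid
    pixels hit the clip. Pixels within ``window_radius + max(scales)`` of the
    image border are invalid (their windows or blankets would need padding,
    which fabricates texture).
    """

    fd: np.ndarray
    valid_mask: np.ndarray
    window_radius: int
    scales: tuple[int, ...]
    fit_quality: np.ndarray
    clip_fraction: float = 0.0

    def masked_fd(self) -> np.ndarray:
        out = np.where(self.valid_mask, self.fd, np.nan)
        return out


def _check_scales(scales) -> tuple[int, ...]:
    scales = tuple(int(s) for s in scales)
    if len(scales) < 1 or scales[0] != 1 or any(
            b - a != 1 for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be consecutive integers starting at 1")
    return scales


def blanket_stack(image: np.ndarray, scales, neighborhood: str = "4"):
    """Run the blanket recursion; yields (eps, u_eps, b_eps, v_eps).

    Border pixels take the max/min over their available neighbors only (no
    padding values are invented).
    """
    scales = _check_scales(scales)
    fp = _CROSS if neighborhood == "4" else _BOX
    g = np.asarray(image, dtype=float)
    u = g.copy()
    b = g.copy()
    for eps in scales:
        u = np.maximum(u + 1.0, ndimage.maximum_filter(u, footprint=fp,
                                                       mode="constant", cval=-np.inf))
        b = np.minimum(b - 1.0, ndimage.minimum_filter(b, footprint=fp,
                                                       mode="constant", cval=np.inf))
        yield eps, u, b, float(np.sum(u - b))


def blanket_surface_area(image: np.ndarray, scales,
                         neighborhood: str = "4") -> list[tuple[int, float]]:
    """Scale-dependent blanket surface areas A(eps) of a grayscale image."""
    g = np.asarray(image, dtype=float)
    scales = _check_scales(scales)
    if g.shape[0] < 2 * max(scales) + 1 or g.shape[1] < 2 * max(scales) + 1:
        raise ValueError("image too small for the requested scale range")
    out = []
    v_prev = 0.0
    for eps, _, _, v in blanket_stack(g, scales, neighborhood):
        out.append((eps, (v - v_prev) / 2.0))
        v_prev = v
    return out


def fd_from_areas(areas) -> tuple[float, float]:
    """Fractal dimension from (eps, A(eps)) pairs: FD = 2 - slope of log-log fit.

    Returns (fd, r_squared). Requires at least 3 scales with positive areas.
    """
    areas = list(areas)
    if len(areas) < 3:
        raise ValueError("need at least 3 scales for the log-log regression")
    eps = np.array([a[0] for a in areas], dtype=float)
    A = np.array([a[1] for a in areas], dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive blanket area: fd undefined")
    x, y = np.log(eps), np.log(A)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = (y - y.mean()) - slope * xc
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - float((resid**2).sum()) / ss_tot
    return 2.0 - slope, r2


def local_fd_map(image: PerfusionImage | np.ndarray, window_radius: int = 7,
                 scales=(1, 2, 3, 4, 5, 6), neighborhood: str = "4") -> FdMap:
    """Local fractal dimension at every pixel from windowed blanket areas.

    The blanket recursion runs once over the whole image; at each pixel the
    blanket volume is summed over the (2*window_radius+1)^2 window centered
    there and the per-pixel log-log regression uses those local areas. Since
    u grows and b shrinks by at least 1 per scale step, local areas are
    strictly positive and the fit is defined everywhere.
    """
    g = np.asarray(image.pixels if isinstance(image, PerfusionImage) else image,
                   dtype=float)
    scales = _check_scales(scales)
    w = 2 * window_radius + 1
    if w < max(scales) + 1:
        raise ValueError("window smaller than the blanket scale support")
    margin = window_radius + max(scales)
    if g.shape[0] <= 2 * margin or g.shape[1] <= 2 * margin:
        raise ValueError("image too small for local fd at this window/scale")

    logA = []
    v_prev = np.zeros_like(g)
    for eps, u, b, _ in blanket_stack(g, scales, neighborhood):
        v_local = ndimage.uniform_filter(u - b, size=w, mode="constant") * w * w
        A_local = (v_local - v_prev) / 2.0
        v_prev = v_local
        logA.append(np.log(A_local))
    logA = np.stack(logA)  # (n_scales, H, W)

    x = np.log(np.asarray(scales, dtype=float))
    xc = (x - x.mean())[:, None, None]
    ym = logA.mean(axis=0)
    slope = (xc * (logA - ym)).sum(axis=0) / float((xc**2).sum())
    resid = (logA - ym) - slope * xc
    ss_tot = ((logA - ym) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 1e-30, 1.0 - (resid**2).sum(axis=0) / ss_tot, 1.0)

    fd = 2.0 - slope
    valid = np.zeros_like(fd, dtype=bool)
    valid[margin:-margin, margin:-margin] = True
    clipped = ((fd < 2.0) | (fd > 3.0)) & valid
    clip_fraction = float(clipped.sum()) / max(int(valid.sum()), 1)
    if clip_fraction > 0.05:
        log.warning("local_fd_map: %.1f%% of valid pixels clipped to [2, 3]",
                    100 * clip_fraction)
    fd = np.clip(fd, 2.0, 3.0)
    return FdMap(fd=fd, valid_mask=valid, window_radius=window_radius,
                 scales=scales, fit_quality=r2, clip_fraction=clip_fraction)


def fit_territory_power_law(territories, scale_level: int) -> tuple[float, float]:
    """Fit the territory power law A_perf**(-FD) ∝ Q_perf at one scale level.

    Least-squares regression of ln Q_perf on ln A_perf over the territories of
    the given vascular scale; returns (-slope, r_squared), the anatomical FD
    estimate. Requires at least 3 territories with distinct areas.
    """
    tab: pd.DataFrame = territories.per_territory
    sub = tab[tab["scale"] == scale_level]
    if len(sub) < 3 or sub["area_mm2"].nunique() < 3:
        raise ValueError("need >= 3 territories with distinct areas at this scale")
    x = np.log(sub["area_mm2"].to_numpy(dtype=float))
    y = np.log(sub["flow"].to_numpy(dtype=float))
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom < 1e-30:
        raise ValueError("territory areas are degenerate")
    slope = float(xc @ (y - y.mean())) / denom
    resid = (y - y.mean()) - slope * xc
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - float((resid**2).sum()) / ss_tot
    return -slope, r2
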