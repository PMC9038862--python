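"""Render grayscale perfusion phantoms from territory maps.

The gray value at a pixel accumulates, over vascular scale levels, the
log-quotient of the containing territory's flow fraction and area fraction,
weighted by a per-scale perfusion rate:

    g(p) = sum_s  rate(s) * ln Q_frac(s, p) / ln a_frac(s, p)

``Q_frac`` is the territory flow as a fraction of the root flow and ``a_frac``
its area as a fraction of the perfused domain area. For a territory obeying
the power law A^(-FD) ∝ Q the quotient is constant over scales, so texture in
the rendered image reflects local deviations of the vascular hierarchy from a
single global scaling exponent.
"""
from __future__ import annotations

import numpy as np

from ..image import PerfusionImage
from .territory import TerritoryMap

__all__ = ["render_phantom"]

_EPS = 1e-9


def render_phantom(tree, territories: TerritoryMap, *, perfusion_rates=None,
                   dynamic_range: float = 255.0, rescale: bool = True,
                   fraction_base: str = "root", max_scales: int | None = None,
                   terminal_mode: str = "stop",
                   scale_aggregate: str = "sum",
                   baseline: float = 0.0,
                   rate_mode: str = "uniform") -> PerfusionImage:
    """Render the perfusion phantom for ``tree`` from its ``territories``.

    Parameters
    ----------
    perfusion_rates
        Per-scale weights ``rate(s)``; a scalar or a vector of length
        ``n_scales``. Default: 1.0 at every scale.
    dynamic_range
        Output range [0, G] of the min-max rescaled image.
    rescale
        If False, return the raw accumulated log-quotient values.
    fraction_base
        "root": fractions of root flow / whole-domain area (default);
        "parent": fractions of the parent territory's flow / area.
    max_scales
        Truncate the accumulation to the first ``max_scales`` vascular scale
        levels (None: all levels present in the territory map).
    terminal_mode
        "stop": a pixel accumulates only over the scales that exist on its
        root-to-terminal path — once the regulating hierarchy reaches the
        terminal there are no further sub-territories to contribute (default).
        "clamp": the terminal territory keeps contributing at deeper scales.
    scale_aggregate
        "sum": plain rate-weighted sum over scales; "mean": normalize each
        pixel by the rate-weighted number of scales that contributed there,
        which removes brightness offsets between regions of different
        vascular path depth.
    baseline
        Constant subtracted from every per-scale quotient before summation.
        ``baseline=1`` accumulates deviations from the ideal single-exponent
        fractal (whose quotient is 1 at every scale), suppressing brightness
        offsets between regions of different vascular path depth.
    rate_mode
        "uniform": rate(s) is the configured per-scale constant;
        "territory-density": the quotient at each scale is additionally
        multiplied by the containing territory's own perfusion rate, its
        areal flow density Q/A normalized by the whole-domain density — the
        hyperperfused lesion then renders bright, as in contrast-enhanced
        imaging.

    Whole-domain territories (fractions of 1, where the log-quotient is the
    0/0 limit) contribute the limit value 1; all fractions are clipped to
    [eps, 1-eps] with eps = 1e-9.
    """
    if fraction_base not in ("root", "parent"):
        raise ValueError("fraction_base must be 'root' or 'parent'")
    if terminal_mode not in ("stop", "clamp"):
        raise ValueError("terminal_mode must be 'stop' or 'clamp'")
    if scale_aggregate not in ("sum", "mean"):
        raise ValueError("scale_aggregate must be 'sum' or 'mean'")
    if rate_mode not in ("uniform", "territory-density"):
        raise ValueError("rate_mode must be 'uniform' or 'territory-density'")
    labels = territories.label_images
    n_scales, nr, nc = labels.shape
    if max_scales is not None:
        n_scales = min(n_scales, int(max_scales))
    rates = np.broadcast_to(np.asarray(
        1.0 if perfusion_rates is None else perfusion_rates, dtype=float), (n_scales,))

    tab = territories.per_territory
    total_area = float(tab[tab["scale"] == 0]["area_mm2"].sum())
    area_of = {}  # (scale, id) -> area; flow is scale-independent
    flow_of = {}
    for s, sid, a, q in tab.itertuples(index=False):
        area_of[(s, sid)] = a
        flow_of[sid] = q

    acc = np.zeros((nr, nc), dtype=float)
    wsum = np.zeros((nr, nc), dtype=float)
    max_id = int(labels.max()) + 1
    parent = getattr(tree, "parent", None)
    depth_lut = np.zeros(max_id + 1, dtype=np.int64)
    depth_lut[:len(tree.depth)] = tree.depth
    for s in range(n_scales):
        lut = np.ones(max_id + 1, dtype=float)  # default: whole-domain limit
        seg_ids = [sid for (sc, sid) in area_of if sc == s]
        for sid in seg_ids:
            if fraction_base == "root" or s == 0:
                qf = flow_of[sid] / territories.root_flow
                af = area_of[(s, sid)] / total_area
            else:
                pid = int(parent[sid]) if parent[sid] >= 0 else sid
                # the parent territory at the previous scale is the segment at
                # depth s-1 on the same root path; identical segment => ratio 1
                ref = pid if (s - 1, pid) in area_of else sid
                qf = flow_of[sid] / flow_of[ref]
                af = area_of[(s, sid)] / area_of[(s - 1, ref)]
            qf = min(max(qf, _EPS), 1.0 - _EPS)
            af = min(max(af, _EPS), 1.0 - _EPS)
            if abs(af - (1.0 - _EPS)) < 1e-12 or area_of[(s, sid)] >= total_area:
                val = 1.0
            else:
                val = np.log(qf) / np.log(af)
            lut[sid] = val
        lut -= baseline
        if rate_mode == "territory-density":
            # weight by the territory's areal flow density relative to the
            # whole-domain density root_flow / total_area
            dlut = np.ones(max_id + 1, dtype=float)
            dom_density = territories.root_flow / total_area
            for sid in seg_ids:
                dlut[sid] = (flow_of[sid] / area_of[(s, sid)]) / dom_density
            lut = lut * dlut
        safe = np.where(labels[s] >= 0, labels[s], max_id)
        img = lut[safe]
        alive = labels[s] >= 0
        if terminal_mode == "stop" and s > 0:
            alive &= depth_lut[safe] >= s  # path exhausted at its terminal
        img[~alive] = 0.0
        acc += rates[s] * img
        wsum += rates[s] * alive

    if scale_aggregate == "mean":
        acc = np.divide(acc, wsum, out=acc, where=wsum > 0)

    if rescale:
        dommask = territories.domain_mask
        lo, hi = acc[dommask].min(), acc[dommask].max()
        if hi - lo < 1e-12:
            out = np.full_like(acc, dynamic_range / 2.0)
        else:
            out = (acc - lo) / (hi - lo) * dynamic_range
        out[~dommask] = 0.0
    else:
        out = acc
    return PerfusionImage(out, territories.pixel_spacing, territories.origin,
                          provenance="phantom")
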