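"""Vectorized planar geometry helpers for tree growth."""
from __future__ import annotations

import numpy as np

__all__ = ["point_segment_distance", "segments_intersect_any", "segment_circle_intersects"]


def point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from point ``p`` (2,) to each segment a[i]->b[i] ((n,2) arrays)."""
    ab = b - a
    ap = p[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.divide(np.einsum("ij,ij->i", ap, ab), denom,
                  out=np.zeros_like(denom), where=denom > 0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.hypot(*(p[None, :] - closest).T)


def _orient(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Signed orientation of triples; p, q broadcast against stacked r."""
    return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - \
           (q[..., 1] - p[..., 1]) * (r[..., 0] - p[..., 0])


def segments_intersect_any(p1: np.ndarray, p2: np.ndarray,
                           a: np.ndarray, b: np.ndarray,
                           eps: float = 1e-9) -> np.ndarray:
    """Whether query segment p1->p2 properly intersects each segment a[i]->b[i].

    Segments that merely share an endpoint (within ``eps``) are not counted:
    tree growth constantly creates segments meeting at bifurcation points.
    Returns a boolean array of length n.
    """
    if len(a) == 0:
        return np.zeros(0, dtype=bool)
    d1 = _orient(a, b, p1[None, :])
    d2 = _orient(a, b, p2[None, :])
    d3 = _orient(p1[None, :], p2[None, :], a)
    d4 = _orient(p1[None, :], p2[None, :], b)
    crossing = (d1 * d2 < -eps) & (d3 * d4 < -eps)
    # Exempt segments touching at a shared endpoint.
    for q in (p1, p2):
        touch = (np.hypot(*(a - q[None, :]).T) < eps) | (np.hypot(*(b - q[None, :]).T) < eps)
        crossing &= ~touch
    return crossing


def segment_circle_intersects(p1: np.ndarray, p2: np.ndarray,
                              center: np.ndarray, radius: float) -> bool:
    """Whether the segment p1->p2 enters the open disc (center, radius)."""
    d = point_segment_distance(np.asarray(center, dtype=float),
                               np.asarray(p1, dtype=float)[None, :],
                               np.asarray(p2, dtype=float)[None, :])
    return bool(d[0] < radius)
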