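"""Planar perfusion domains for vascular phantom growth.

The host prostate is modeled as a disc of 5 cm radius with a circular
placeholder hole into which a 1.6 cm tumor disc is later inserted; the tumor
tree itself grows in a plain disc congruent with that hole.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerfusionDomain"]


@dataclass(frozen=True)
class PerfusionDomain:
    """Circular 2-D tissue domain, optionally with a circular placeholder hole.

    All coordinates and radii are in millimetres.
    """

    shape: str  # "disc" | "disc-with-hole"
    center: tuple[float, float]
    radius: float
    hole_center: tuple[float, float] | None = None
    hole_radius: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "disc-with-hole"):
            raise ValueError(f"unknown domain shape {self.shape!r}")
        if self.radius <= 0:
            raise ValueError("domain radius must be positive")
        if self.shape == "disc-with-hole":
            if self.hole_center is None or self.hole_radius is None:
                raise ValueError("disc-with-hole requires hole_center and hole_radius")
            if self.hole_radius <= 0:
                raise ValueError("hole radius must be positive")
            d = float(np.hypot(self.hole_center[0] - self.center[0],
                               self.hole_center[1] - self.center[1]))
            if d + self.hole_radius > self.radius:
                raise ValueError("placeholder hole must lie fully inside the disc")
        else:
            if self.hole_center is not None or self.hole_radius is not None:
                raise ValueError("plain disc takes no hole parameters")

    @property
    def has_hole(self) -> bool:
        return self.shape == "disc-with-hole"

    def area(self) -> float:
        """Perfused area in mm^2 (disc area minus the hole, if any)."""
        a = np.pi * self.radius**2
        if self.has_hole:
            a -= np.pi * self.hole_radius**2  # type: ignore[operator]
        return float(a)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for (..., 2) arrays of points in mm."""
        pts = np.asarray(points, dtype=float)
        d = np.hypot(pts[..., 0] - self.center[0], pts[..., 1] - self.center[1])
        inside = d <= self.radius
        if self.has_hole:
            dh = np.hypot(pts[..., 0] - self.hole_center[0],  # type: ignore[index]
                          pts[..., 1] - self.hole_center[1])  # type: ignore[index]
            inside &= dh >= self.hole_radius
        return inside

    def boundary_point(self, angle: float) -> tuple[float, float]:
        """Point on the outer circle at the given angle (radians)."""
        return (self.center[0] + self.radius * np.cos(angle),
                self.center[1] + self.radius * np.sin(angle))

    def sample_point(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform random point inside the perfused region (rejection sampling)."""
        for _ in range(10_000):
            p = self.center + (rng.random(2) * 2.0 - 1.0) * self.radius
            if self.contains(p):
                return p
        raise RuntimeError("failed to sample a point inside the domain")

    def without_hole(self) -> "PerfusionDomain":
        """The same disc with the placeholder filled in (post tumor insertion)."""
        return PerfusionDomain("disc", self.center, self.radius)
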