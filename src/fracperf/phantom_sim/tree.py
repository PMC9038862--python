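"""Binary vascular trees: segments, invariants, radii, and JSON round-trips.

A tree is stored in flat arrays (one row per segment) for speed; the
``segments`` property materializes :class:`VesselSegment` records on demand.
Segment radii follow a Murray power law ``r = c * Q**(1/gamma)``, which makes
the bifurcation relation ``r_p**gamma = r_l**gamma + r_r**gamma`` hold exactly
whenever flow is conserved; the prefactor ``c`` is calibrated so that the mean
Poiseuille pressure drop from root to terminals matches a configured perfusion
pressure.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .domain import PerfusionDomain

__all__ = ["VesselSegment", "VascularTree", "BLOOD_VISCOSITY_PA_S", "MMHG_TO_PA"]

BLOOD_VISCOSITY_PA_S = 3.6e-3
MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class VesselSegment:
    """One vessel segment between a proximal and a distal point (mm)."""

    id: int
    proximal_point: tuple[float, float]
    distal_point: tuple[float, float]
    radius: float  # mm
    flow: float  # ml/min
    parent_id: int | None
    child_ids: tuple[int, ...]
    scale_level: int  # bifurcation depth from the root (root = 0)

    @property
    def is_terminal(self) -> bool:
        return len(self.child_ids) == 0

    @property
    def length(self) -> float:
        return float(np.hypot(self.distal_point[0] - self.proximal_point[0],
                              self.distal_point[1] - self.proximal_point[1]))


class VascularTree:
    """Array-backed binary branching tree of vessel segments."""

    def __init__(self, domain: PerfusionDomain, optimization_target: str,
                 rng_seed: int, gamma: float = 3.0) -> None:
        if optimization_target not in ("volume", "surface", "length"):
            raise ValueError(f"unknown optimization target {optimization_target!r}")
        self.domain = domain
        self.optimization_target = optimization_target
        self.rng_seed = int(rng_seed)
        self.gamma = float(gamma)
        self.root_id = 0
        self._prox = np.empty((0, 2), dtype=float)
        self._dist = np.empty((0, 2), dtype=float)
        self._flow = np.empty(0, dtype=float)
        self._radius = np.empty(0, dtype=float)
        self._parent = np.empty(0, dtype=np.int64)  # -1 = root
        self._children = np.empty((0, 2), dtype=np.int64)  # -1 = none
        self._depth: np.ndarray | None = None

    # -- construction -------------------------------------------------------

    def _append(self, prox, dist, flow, parent) -> int:
        idx = len(self._flow)
        self._prox = np.vstack([self._prox, np.asarray(prox, dtype=float)[None]])
        self._dist = np.vstack([self._dist, np.asarray(dist, dtype=float)[None]])
        self._flow = np.append(self._flow, float(flow))
        self._radius = np.append(self._radius, np.nan)
        self._parent = np.append(self._parent, int(parent))
        self._children = np.vstack([self._children, np.full((1, 2), -1, dtype=np.int64)])
        self._depth = None
        return idx

    # -- array views --------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self._flow)

    @property
    def prox(self) -> np.ndarray:
        return self._prox

    @property
    def dist(self) -> np.ndarray:
        return self._dist

    @property
    def flow(self) -> np.ndarray:
        return self._flow

    @property
    def radius(self) -> np.ndarray:
        return self._radius

    @property
    def parent(self) -> np.ndarray:
        return self._parent

    @property
    def children(self) -> np.ndarray:
        return self._children

    @property
    def lengths(self) -> np.ndarray:
        return np.hypot(*(self._dist - self._prox).T)

    @property
    def is_terminal(self) -> np.ndarray:
        return self._children[:, 0] < 0

    @property
    def terminal_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_terminal)

    @property
    def depth(self) -> np.ndarray:
        """Bifurcation depth of every segment from the root (root = 0)."""
        if self._depth is None:
            d = np.full(self.n_segments, -1, dtype=np.int64)
            d[self.root_id] = 0
            stack = [self.root_id]
            while stack:
                i = stack.pop()
                for c in self._children[i]:
                    if c >= 0:
                        d[c] = d[i] + 1
                        stack.append(int(c))
            self._depth = d
        return self._depth

    @property
    def max_depth(self) -> int:
        return int(self.depth.max())

    @property
    def root_flow(self) -> float:
        return float(self._flow[self.root_id])

    def path_to_root(self, i: int) -> list[int]:
        """Segment ids from ``i`` up to and including the root."""
        path = [i]
        while self._parent[path[-1]] >= 0:
            path.append(int(self._parent[path[-1]]))
        return path

    # -- functionals ---------------------------------------------------------

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def total_volume(self) -> float:
        """Total intravascular volume, sum of pi r^2 L (mm^3)."""
        return float(np.sum(np.pi * self._radius**2 * self.lengths))

    def total_surface(self) -> float:
        """Total endothelial (luminal) surface, sum of 2 pi r L (mm^2)."""
        return float(np.sum(2.0 * np.pi * self._radius * self.lengths))

    # -- radii ---------------------------------------------------------------

    def recompute_radii(self, pressure_drop_mmhg: float = 60.0,
                        viscosity_pa_s: float = BLOOD_VISCOSITY_PA_S) -> None:
        """Set radii from the Murray power law, Poiseuille-calibrated.

        ``r_i = c * Q_i**(1/gamma)`` with ``c`` chosen so the mean laminar
        (Poiseuille) pressure drop over all root-to-terminal paths equals
        ``pressure_drop_mmhg``.
        """
        r_unit = self._flow ** (1.0 / self.gamma)  # c = 1 trial radii, mm
        # Poiseuille drop per segment at c = 1, SI units.
        L_m = self.lengths * 1e-3
        q_si = self._flow * 1e-6 / 60.0
        dp = 8.0 * viscosity_pa_s * L_m * q_si / (np.pi * (r_unit * 1e-3) ** 4)
        # Accumulate path drops root -> terminal.
        cum = np.zeros(self.n_segments)
        order = np.argsort(self.depth)  # parents precede children
        for i in order:
            p = self._parent[i]
            cum[i] = dp[i] + (cum[p] if p >= 0 else 0.0)
        mean_drop = float(cum[self.is_terminal].mean())
        target = pressure_drop_mmhg * MMHG_TO_PA
        c = (mean_drop / target) ** 0.25
        self._radius = c * r_unit

    # -- invariants ----------------------------------------------------------

    def murray_residuals(self) -> np.ndarray:
        """Relative residual of Murray's law at every bifurcation."""
        bif = np.flatnonzero(~self.is_terminal)
        l, r = self._children[bif, 0], self._children[bif, 1]
        g = self.gamma
        rp = self._radius[bif] ** g
        return np.abs(rp - self._radius[l] ** g - self._radius[r] ** g) / rp

    def check_invariants(self) -> None:
        """Raise AssertionError on any structural or physical violation."""
        assert np.all(self._flow > 0), "non-positive flow"
        assert np.all(self._radius > 0), "non-positive radius"
        n_children = (self._children >= 0).sum(axis=1)
        assert np.all((n_children == 0) | (n_children == 2)), \
            "segment with exactly one child"
        assert int((self._parent < 0).sum()) == 1, "tree must have exactly one root"
        assert self._parent[self.root_id] < 0
        # connectivity + acyclicity: depth computation reaches every segment
        assert np.all(self.depth >= 0), "disconnected segment"
        # flow conservation at bifurcations (exact up to float rounding)
        bif = np.flatnonzero(n_children == 2)
        l, r = self._children[bif, 0], self._children[bif, 1]
        np.testing.assert_allclose(self._flow[bif], self._flow[l] + self._flow[r],
                                   rtol=1e-9)
        # children attach where the parent ends
        np.testing.assert_allclose(self._prox[l], self._dist[bif], atol=1e-9)
        np.testing.assert_allclose(self._prox[r], self._dist[bif], atol=1e-9)
        assert np.all(self.murray_residuals() <= 1e-6), "Murray's law violated"
        term = self.is_terminal
        assert np.all(self.domain.contains(self._dist[term])), \
            "terminal outside the perfused domain"

    # -- segment records -----------------------------------------------------

    @property
    def segments(self) -> list[VesselSegment]:
        depth = self.depth
        out = []
        for i in range(self.n_segments):
            kids = tuple(int(c) for c in self._children[i] if c >= 0)
            out.append(VesselSegment(
                id=i,
                proximal_point=(float(self._prox[i, 0]), float(self._prox[i, 1])),
                distal_point=(float(self._dist[i, 0]), float(self._dist[i, 1])),
                radius=float(self._radius[i]),
                flow=float(self._flow[i]),
                parent_id=int(self._parent[i]) if self._parent[i] >= 0 else None,
                child_ids=kids,
                scale_level=int(depth[i]),
            ))
        return out

    def __iter__(self) -> Iterator[VesselSegment]:
        return iter(self.segments)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        dom = self.domain
        return {
            "format": "fracperf-vascular-tree", "version": 1,
            "optimization_target": self.optimization_target,
            "rng_seed": self.rng_seed, "gamma": self.gamma,
            "root_id": self.root_id,
            "domain": {
                "shape": dom.shape, "center": list(dom.center), "radius": dom.radius,
                "hole_center": list(dom.hole_center) if dom.hole_center else None,
                "hole_radius": dom.hole_radius,
            },
            "segments": [
                {"id": s.id, "proximal": list(s.proximal_point),
                 "distal": list(s.distal_point), "radius": s.radius,
                 "flow": s.flow, "parent_id": s.parent_id,
                 "child_ids": list(s.child_ids)}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularTree":
        dd = d["domain"]
        dom = PerfusionDomain(
            dd["shape"], tuple(dd["center"]), dd["radius"],
            tuple(dd["hole_center"]) if dd["hole_center"] else None,
            dd["hole_radius"])
        tree = cls(dom, d["optimization_target"], d["rng_seed"], d["gamma"])
        segs = sorted(d["segments"], key=lambda s: s["id"])
        n = len(segs)
        tree._prox = np.array([s["proximal"] for s in segs], dtype=float).reshape(n, 2)
        tree._dist = np.array([s["distal"] for s in segs], dtype=float).reshape(n, 2)
        tree._flow = np.array([s["flow"] for s in segs], dtype=float)
        tree._radius = np.array([s["radius"] for s in segs], dtype=float)
        tree._parent = np.array(
            [-1 if s["parent_id"] is None else s["parent_id"] for s in segs],
            dtype=np.int64)
        kids = np.full((n, 2), -1, dtype=np.int64)
        for i, s in enumerate(segs):
            for j, c in enumerate(s["child_ids"]):
                kids[i, j] = c
        tree._children = kids
        tree.root_id = d["root_id"]
        return tree

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "VascularTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
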