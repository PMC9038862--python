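"""Constrained constructive optimization (CCO) growth of planar vascular trees.

Trees are grown by adding one terminal at a time at a pseudorandom in-domain
location, connecting it to a nearby segment through a new bifurcation whose
position is locally optimized to minimize the tree-wide target functional:

* ``volume``  — total intravascular volume, sum of pi r^2 L (low dedifferentiation)
* ``surface`` — total endothelial surface, sum of 2 pi r L (intermediate)
* ``length``  — total vessel length, sum of L (high dedifferentiation)

Because radii follow the Murray power law ``r = c * Q**(1/gamma)`` the segment
weight per unit length is proportional to ``Q**0``, ``Q**(1/gamma)`` or
``Q**(2/gamma)`` for the three targets; the prefactor is a global constant and
drops out of the optimization.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .domain import PerfusionDomain
from .geometry import point_segment_distance, segment_circle_intersects, segments_intersect_any
from .tree import VascularTree

__all__ = ["generate_tree", "insert_tumor"]

_TARGET_EXPONENT = {"length": 0.0, "surface": 1.0, "volume": 2.0}


def _weight(flow: np.ndarray | float, target: str, gamma: float):
    """Per-unit-length cost of a segment carrying ``flow``, up to a constant."""
    e = _TARGET_EXPONENT[target] / gamma
    return np.asarray(flow, dtype=float) ** e if e else np.ones_like(np.asarray(flow, dtype=float))


def _hole_crossing(domain: PerfusionDomain, p1: np.ndarray, p2: np.ndarray) -> bool:
    if not domain.has_hole:
        return False
    return segment_circle_intersects(
        p1, p2, np.asarray(domain.hole_center, dtype=float), domain.hole_radius)


def _optimize_bifurcation(p: np.ndarray, d: np.ndarray, t: np.ndarray,
                          w_trunk: float, w_cont: float, w_term: float) -> tuple[np.ndarray, float]:
    """Locally optimal bifurcation point for connecting terminal ``t`` into p->d.

    Cost: w_trunk*|p-x| + w_cont*|x-d| + w_term*|x-t|. A golden-section search
    along the parent segment seeds a 2-D Nelder-Mead refinement.
    """
    def cost(x: np.ndarray) -> float:
        return (w_trunk * np.hypot(*(x - p)) + w_cont * np.hypot(*(x - d))
                + w_term * np.hypot(*(x - t)))

    res1 = minimize_scalar(lambda s: cost(p + s * (d - p)), bounds=(0.05, 0.95),
                           method="bounded", options={"xatol": 1e-3})
    x0 = p + res1.x * (d - p)
    res2 = minimize(cost, x0, method="Nelder-Mead",
                    options={"maxiter": 80, "xatol": 1e-4, "fatol": 1e-9})
    return (res2.x, float(res2.fun)) if res2.fun < res1.fun else (x0, float(res1.fun))


def _split_segment(tree: VascularTree, j: int, x: np.ndarray, t: np.ndarray,
                   q: float) -> None:
    """Split segment ``j`` at ``x``, attaching a new terminal ending at ``t``.

    Segment ``j`` keeps its id and becomes the trunk p->x carrying Q_j + q; a
    new continuation segment x->d inherits j's children and flow, and a new
    terminal x->t carries q. All ancestors of ``j`` gain q.
    """
    old_dist = tree._dist[j].copy()
    old_children = tree._children[j].copy()
    q_j = float(tree._flow[j])
    cont = tree._append(x, old_dist, q_j, j)
    tree._children[cont] = old_children
    for c in old_children:
        if c >= 0:
            tree._parent[c] = cont
    term = tree._append(x, t, q, j)
    tree._dist[j] = x
    tree._flow[j] = q_j + q
    tree._children[j] = (cont, term)
    # propagate the added outflow up to the root
    a = int(tree._parent[j])
    while a >= 0:
        tree._flow[a] += q
        a = int(tree._parent[a])
    tree._depth = None


def generate_tree(domain: PerfusionDomain, n_terminals: int, target: str,
                  root_inlet: tuple[float, float], total_flow: float, seed: int,
                  *, gamma: float = 3.0, pressure_drop_mmhg: float = 60.0,
                  m_candidates: int = 5, retry_budget: int = 400,
                  density_factor: float = 0.8, min_length: float = 0.1) -> VascularTree:
    """Grow a CCO tree with ``n_terminals`` equal-outflow terminals.

    Parameters
    ----------
    domain
        Perfused region; terminal locations are sampled uniformly inside it and
        no segment may cross its placeholder hole (if present).
    n_terminals
        Number of terminal segments; each delivers ``total_flow / n_terminals``.
    target
        Optimization target functional: "volume", "surface" or "length".
    root_inlet
        Feeding-artery entry point, conventionally on the domain boundary.
    total_flow
        Root inflow in ml/min.
    seed
        Seed for the terminal-location stream; identical (seed, parameters)
        reproduce the tree exactly.
    density_factor
        Scales the minimum admissible distance between a new terminal and the
        existing tree, ``d_min = density_factor * sqrt(A / k)`` at terminal k;
        the threshold relaxes geometrically when candidates keep failing.
    """
    if n_terminals < 1:
        raise ValueError("n_terminals must be >= 1")
    if total_flow <= 0:
        raise ValueError("total_flow must be positive")
    rng = np.random.default_rng(seed)
    q = total_flow / n_terminals
    tree = VascularTree(domain, target, seed, gamma)
    inlet = np.asarray(root_inlet, dtype=float)

    # root segment: inlet -> first terminal
    for _ in range(retry_budget):
        p0 = domain.sample_point(rng)
        if not _hole_crossing(domain, inlet, p0) and np.hypot(*(p0 - inlet)) > min_length:
            break
    else:
        raise RuntimeError("could not place the root segment")
    tree._append(inlet, p0, q, -1)

    for k in range(2, n_terminals + 1):
        d_min = density_factor * np.sqrt(domain.area() / k)
        placed = False
        for attempt in range(retry_budget):
            t = domain.sample_point(rng)
            dists = point_segment_distance(t, tree._prox, tree._dist)
            if dists.min() < d_min:
                d_min *= 0.98  # relax so dense late-stage growth stays feasible
                continue
            j = _try_connect(tree, t, q, dists, target, gamma,
                             m_candidates, min_length)
            if j is not None:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"terminal {k}/{n_terminals}: retry budget {retry_budget} exhausted")

    tree.recompute_radii(pressure_drop_mmhg)
    return tree


def _try_connect(tree: VascularTree, t: np.ndarray, q: float, dists: np.ndarray,
                 target: str, gamma: float, m_candidates: int,
                 min_length: float) -> int | None:
    """Attempt to connect terminal location ``t``; returns the split segment id."""
    m = min(m_candidates, tree.n_segments)
    candidates = np.argsort(dists)[:m]
    w_term = float(_weight(q, target, gamma))
    best: tuple[float, int, np.ndarray] | None = None
    for j in candidates:
        j = int(j)
        p, d = tree._prox[j], tree._dist[j]
        q_j = float(tree._flow[j])
        w_trunk = float(_weight(q_j + q, target, gamma))
        w_cont = float(_weight(q_j, target, gamma))
        x, local = _optimize_bifurcation(p, d, t, w_trunk, w_cont, w_term)
        # delta of the tree-wide functional: local terms minus the removed
        # segment plus the weight increase along the root path (length-free
        # under the length target).
        path = tree.path_to_root(j)[1:]
        if path:
            lp = np.hypot(*(tree._dist[path] - tree._prox[path]).T)
            fp = tree._flow[path]
            d_anc = float(np.sum((_weight(fp + q, target, gamma)
                                  - _weight(fp, target, gamma)) * lp))
        else:
            d_anc = 0.0
        delta = local - w_cont * np.hypot(*(d - p)) + d_anc
        if not _feasible(tree, j, p, d, x, t, min_length):
            continue
        if best is None or delta < best[0]:
            best = (delta, j, x)
    if best is None:
        return None
    _, j, x = best
    _split_segment(tree, j, x, t, q)
    return j


def _feasible(tree: VascularTree, j: int, p: np.ndarray, d: np.ndarray,
              x: np.ndarray, t: np.ndarray, min_length: float) -> bool:
    if min(np.hypot(*(x - p)), np.hypot(*(x - d)), np.hypot(*(x - t))) < min_length:
        return False
    if not tree.domain.contains(x):
        return False
    dom = tree.domain
    for a, b in ((p, x), (x, d), (x, t)):
        if _hole_crossing(dom, a, b):
            return False
    mask = np.ones(tree.n_segments, dtype=bool)
    mask[j] = False  # the segment being split
    pa, da = tree._prox[mask], tree._dist[mask]
    for a, b in ((p, x), (x, d), (x, t)):
        if segments_intersect_any(a, b, pa, da).any():
            return False
    return True


def insert_tumor(host: VascularTree, tumor: VascularTree, *,
                 pressure_drop_mmhg: float = 60.0,
                 geometry_tol: float = 1e-6) -> VascularTree:
    """Insert a tumor tree into the placeholder hole of a host tree.

    The tumor root is re-attached at the nearest point of the nearest host
    segment, which is split there; the tumor root segment is extended to start
    at that junction, so the combined structure remains a single binary tree.
    Host flows along the feeding path are re-balanced by the tumor inflow and
    radii are recomputed tree-wide, so flow conservation and Murray's law hold
    everywhere.
    """
    if not host.domain.has_hole:
        raise ValueError("host domain has no placeholder hole for tumor insertion")
    if tumor.domain.shape != "disc":
        raise ValueError("tumor domain must be a plain disc")
    hc = np.asarray(host.domain.hole_center, dtype=float)
    tc = np.asarray(tumor.domain.center, dtype=float)
    if (np.hypot(*(hc - tc)) > geometry_tol
            or abs(host.domain.hole_radius - tumor.domain.radius) > geometry_tol):
        raise ValueError("tumor disc is not congruent with the host placeholder")
    if abs(host.gamma - tumor.gamma) > geometry_tol:
        raise ValueError("host and tumor Murray exponents differ")

    combined = VascularTree(host.domain.without_hole(), host.optimization_target,
                            host.rng_seed, host.gamma)
    n_h = host.n_segments
    combined._prox = np.vstack([host._prox, tumor._prox])
    combined._dist = np.vstack([host._dist, tumor._dist])
    combined._flow = np.concatenate([host._flow, tumor._flow])
    combined._radius = np.concatenate([host._radius, tumor._radius])
    t_parent = tumor._parent.copy()
    t_parent[t_parent >= 0] += n_h
    combined._parent = np.concatenate([host._parent, t_parent])
    t_children = tumor._children.copy()
    t_children[t_children >= 0] += n_h
    combined._children = np.vstack([host._children, t_children])
    combined.root_id = host.root_id
    tumor_root = n_h + tumor.root_id
    q_t = float(tumor._flow[tumor.root_id])

    # nearest host segment to the tumor root inlet
    inlet = combined._prox[tumor_root]
    dists = point_segment_distance(inlet, host._prox, host._dist)
    j = int(np.argmin(dists))
    p, d = combined._prox[j], combined._dist[j]
    ab = d - p
    s = float(np.clip(np.dot(inlet - p, ab) / max(np.dot(ab, ab), 1e-12), 0.1, 0.9))
    x = p + s * ab

    # split j at x; children become (continuation, extended tumor root)
    old_dist = combined._dist[j].copy()
    old_children = combined._children[j].copy()
    q_j = float(combined._flow[j])
    cont = combined._append(x, old_dist, q_j, j)
    combined._children[cont] = old_children
    for c in old_children:
        if c >= 0:
            combined._parent[c] = cont
    combined._dist[j] = x
    combined._flow[j] = q_j + q_t
    combined._children[j] = (cont, tumor_root)
    combined._prox[tumor_root] = x
    combined._parent[tumor_root] = j
    a = int(combined._parent[j])
    while a >= 0:
        combined._flow[a] += q_t
        a = int(combined._parent[a])
    combined._depth = None
    combined.recompute_radii(pressure_drop_mmhg)
    return combined
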