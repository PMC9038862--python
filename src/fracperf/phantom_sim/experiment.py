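"""The in-silico phantom experiment: host + tumor trees at three
dedifferentiation stages, rendered at clinical DCE resolution.

Each phantom embeds a 1.6 cm tumor disc in a 5 cm host disc. The tumor tree's
CCO optimization target encodes the vascular dedifferentiation stage:
minimizing intravascular volume (low), endothelial surface (intermediate) or
vessel length (high) — progressively cruder cost functions standing in for
the loss of hemodynamic optimality during tumor angiogenesis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import PerfusionImage, downsample
from ..roi import MarginRoi
from .cco import generate_tree, insert_tumor
from .domain import PerfusionDomain
from .render import render_phantom
from .territory import TerritoryMap, compute_territories
from .tree import VascularTree

__all__ = ["DedifferentiationStage", "PhantomSample", "make_experiment",
           "make_phantom", "STAGES"]

_STAGE_TARGET = {"low": "volume", "intermediate": "surface", "high": "length"}
STAGES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class DedifferentiationStage:
    """Vascular dedifferentiation stage with its fixed optimization target."""

    stage: str

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_TARGET:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def target(self) -> str:
        return _STAGE_TARGET[self.stage]


@dataclass
class PhantomSample:
    """One rendered phantom with its stage label and ground-truth margin band."""

    image: PerfusionImage
    stage: str
    margin: MarginRoi
    seed_info: dict
    host: VascularTree | None = None
    tumor: VascularTree | None = None
    combined: VascularTree | None = None
    territories: TerritoryMap | None = None


def _phantom_seeds(seed: int, stage_index: int, rep: int) -> tuple[int, int, int]:
    """Counter-based sub-seed derivation: independent, reproducible streams."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(stage_index, rep))
    host_s, tumor_s, geom_s = (int(v) for v in ss.generate_state(3) >> 1)
    return host_s, tumor_s, geom_s


def make_phantom(stage: str, seed: int, *, stage_index: int | None = None,
                 rep: int = 0, host_radius: float = 50.0,
                 tumor_radius: float = 16.0, host_n_terminals: int = 800,
                 tumor_n_terminals: int = 300, host_flow: float = 100.0,
                 tumor_flow: float = 23.0, gamma: float = 3.0,
                 pressure_drop_mmhg: float = 60.0, m_candidates: int = 5,
                 native_spacing: float = 0.25, clinical_spacing: float = 1.5,
                 hole_offset_max: float = 0.0, perfusion_rates=None,
                 render_kwargs: dict | None = None,
                 keep_intermediates: bool = False) -> PhantomSample:
    """Build one phantom: trees, insertion, territories, rendering, downsampling.

    The tumor flow default makes the lesion hyperperfused: its areal flow
    density is about twice that of the host tissue.
    """
    if stage_index is None:
        stage_index = STAGES.index(stage)
    target = DedifferentiationStage(stage).target
    host_seed, tumor_seed, geom_seed = _phantom_seeds(seed, stage_index, rep)
    geom = np.random.default_rng(geom_seed)

    # placeholder hole position: uniform in a disc around the host center
    ang, rad = geom.uniform(0, 2 * np.pi), hole_offset_max * np.sqrt(geom.random())
    center = (0.0, 0.0)
    hole_center = (rad * np.cos(ang), rad * np.sin(ang))
    host_domain = PerfusionDomain("disc-with-hole", center, host_radius,
                                  hole_center, tumor_radius)
    tumor_domain = PerfusionDomain("disc", hole_center, tumor_radius)

    host_inlet = host_domain.boundary_point(np.pi)
    host = generate_tree(host_domain, host_n_terminals, "volume", host_inlet,
                         host_flow, host_seed, gamma=gamma,
                         pressure_drop_mmhg=pressure_drop_mmhg,
                         m_candidates=m_candidates)
    # tumor fed from the side of its disc facing the host inlet
    inlet_ang = np.arctan2(host_inlet[1] - hole_center[1],
                           host_inlet[0] - hole_center[0])
    tumor_inlet = tumor_domain.boundary_point(inlet_ang)
    tumor = generate_tree(tumor_domain, tumor_n_terminals, target, tumor_inlet,
                          tumor_flow, tumor_seed, gamma=gamma,
                          pressure_drop_mmhg=pressure_drop_mmhg,
                          m_candidates=m_candidates)
    combined = insert_tumor(host, tumor, pressure_drop_mmhg=pressure_drop_mmhg)

    # raster pinned so the clinical grid is an exact block-average of the native
    factor = int(round(clinical_spacing / native_spacing))
    n_clin = int(np.ceil(2 * host_radius / clinical_spacing))
    n_native = n_clin * factor
    origin = (center[0] - n_native * native_spacing / 2 + native_spacing / 2,
              center[1] - n_native * native_spacing / 2 + native_spacing / 2)
    territories = compute_territories(combined, native_spacing,
                                      grid_shape=(n_native, n_native),
                                      origin=origin)
    native = render_phantom(combined, territories,
                            perfusion_rates=perfusion_rates,
                            **(render_kwargs or {}))
    image = downsample(native, clinical_spacing)

    margin = margin_band(image, hole_center, tumor_radius)
    sample = PhantomSample(image=image, stage=stage, margin=margin,
                           seed_info={"seed": seed, "stage_index": stage_index,
                                      "rep": rep, "host_seed": host_seed,
                                      "tumor_seed": tumor_seed,
                                      "geom_seed": geom_seed})
    if keep_intermediates:
        sample.host, sample.tumor = host, tumor
        sample.combined, sample.territories = combined, territories
    return sample


def margin_band(image: PerfusionImage, circle_center: tuple[float, float],
                circle_radius: float, band_pixels: int = 1) -> MarginRoi:
    """Pixels within ± ``band_pixels`` of the tumor circle: the ground-truth margin."""
    xx, yy = image.pixel_centers()
    d = np.hypot(xx - circle_center[0], yy - circle_center[1])
    band = np.abs(d - circle_radius) <= band_pixels * image.pixel_spacing
    rows, cols = np.nonzero(band)
    return MarginRoi(np.column_stack([rows, cols]), band_width=band_pixels,
                     source_frame="phantom")


def make_experiment(n_per_stage: int, seed: int, *, keep_intermediates: bool = False,
                    **phantom_kwargs) -> list[PhantomSample]:
    """Generate ``n_per_stage`` phantoms for each dedifferentiation stage.

    Phantoms are mutually independent: each draws its trees from sub-seeds
    derived from ``seed`` by the (stage, repetition) counter, so the whole set
    is reproducible from the single root seed.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    samples = []
    for si, stage in enumerate(STAGES):
        for rep in range(n_per_stage):
            samples.append(make_phantom(stage, seed, stage_index=si, rep=rep,
                                        keep_intermediates=keep_intermediates,
                                        **phantom_kwargs))
    return samples
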