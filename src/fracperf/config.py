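"""Layered pipeline configuration with schema validation.

A single :class:`PipelineConfig` carries every tunable constant of the
pipeline — tree growth, rendering, fractal analysis, margin extraction and
statistics — with units and defaults. Unknown keys are rejected, and the
full config snapshot is serialized into every output manifest for
provenance.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["TreeConfig", "RenderConfig", "FdConfig", "MarginConfig",
           "StatsConfig", "PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TreeConfig(_Strict):
    """CCO growth parameters."""

    gamma: float = Field(3.0, gt=1.0, description="Murray bifurcation exponent")
    pressure_drop_mmhg: float = Field(60.0, gt=0, description="root-to-terminal perfusion pressure")
    host_n_terminals: int = Field(800, ge=1)
    tumor_n_terminals: int = Field(300, ge=1, description="~3x host areal terminal density: hypervascularized lesion")
    host_flow_ml_min: float = Field(100.0, gt=0)
    tumor_flow_ml_min: float = Field(23.0, gt=0, description="~2x host areal flow density: hyperperfused lesion")
    host_radius_mm: float = Field(50.0, gt=0)
    tumor_radius_mm: float = Field(16.0, gt=0)
    hole_offset_max_mm: float = Field(0.0, ge=0, description="max offset of the tumor placeholder from the host center")
    m_candidates: int = Field(5, ge=1, description="nearest segments tried per connection")
    retry_budget: int = Field(400, ge=1)
    density_factor: float = Field(0.8, gt=0)


class RenderConfig(_Strict):
    """Perfusion rendering parameters."""

    native_spacing_mm: float = Field(0.25, gt=0)
    clinical_spacing_mm: float = Field(1.5, gt=0, description="typical clinical DCE in-plane resolution")
    dynamic_range: float = Field(255.0, gt=0)
    perfusion_rate: float = Field(1.0, description="per-scale weight (scalar default; vector via API)")
    fraction_base: str = Field("root", pattern="^(root|parent)$")
    terminal_mode: str = Field("stop", pattern="^(stop|clamp)$")
    baseline: float = Field(0.0, description="per-scale quotient baseline subtracted before accumulation")


class FdConfig(_Strict):
    """Blanket-method fractal analysis parameters."""

    window_radius: int = Field(7, ge=1, description="local window half-size in pixels")
    max_scale: int = Field(6, ge=3, description="blanket scales run 1..max_scale")
    neighborhood: str = Field("4", pattern="^(4|8)$")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(range(1, self.max_scale + 1))


class MarginConfig(_Strict):
    """Margin ROI parameters."""

    band_width_px: int = Field(2, ge=1, description="morphological band half-width, ~3 mm at DCE resolution")
    min_valid_px: int = Field(10, ge=1)


class StatsConfig(_Strict):
    """Statistics parameters."""

    n_boot: int = Field(2000, ge=100)
    bootstrap_seed: int = Field(0, ge=0)
    cutoffs: tuple[float, float, float] = (2.20, 2.31, 2.40)

    @model_validator(mode="after")
    def _increasing(self) -> "StatsConfig":
        c1, c2, c3 = self.cutoffs
        if not c1 < c2 < c3:
            raise ValueError("cutoffs must be strictly increasing")
        return self


class PipelineConfig(_Strict):
    """Complete pipeline configuration; the single source of defaults."""

    tree: TreeConfig = Field(default_factory=TreeConfig)
    render: RenderConfig = Field(default_factory=RenderConfig)
    fd: FdConfig = Field(default_factory=FdConfig)
    margin: MarginConfig = Field(default_factory=MarginConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    seed: int = Field(0, ge=0, description="root seed; all sub-streams derive from it")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def snapshot(self) -> dict:
        """JSON-serializable config snapshot for output manifests."""
        return self.model_dump(mode="json")
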