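"""Run configuration: one YAML-serializable object binding all stages.

A :class:`RunConfig` carries the geometry, population, assay, rendering,
segmentation, classification and statistics settings together with the master
seed and output directory; it round-trips losslessly through YAML, and every
CLI run echoes its resolved config + seed into a JSON sidecar so the run is
reproducible from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantify import ClassificationThresholds, SegmentationParams
from .render import RenderParams
from .simulate import AssayParams, GeometryConfig, PopulationSpec

__all__ = ["StatsOptions", "RunConfig"]


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    exact_threshold: int = 20
    continuity: bool = True


#: dataclass fields that must be coerced back to tuples after YAML round-trip
_TUPLE_FIELDS = {
    "shape",
    "nucleus_radius_px",
    "cyto_scale",
    "background",
    "nucleus_diameter_range",
    "spot_diameter_range",
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        elif f.name == "spot_threshold" and isinstance(v, list):
            v = (v[0], v[1])
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "molboolean_run"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    assay: AssayParams = field(default_factory=AssayParams)
    render: RenderParams = field(default_factory=RenderParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classification: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    stats: StatsOptions = field(default_factory=StatsOptions)

    @property
    def mode(self) -> str:
        return self.assay.mode

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            seed=int(data.get("seed", 0)),
            outdir=str(data.get("outdir", "molboolean_run")),
            geometry=_from_plain(GeometryConfig, data.get("geometry", {})),
            population=_from_plain(PopulationSpec, data.get("population", {})),
            assay=_from_plain(AssayParams, data.get("assay", {})),
            render=_from_plain(RenderParams, data.get("render", {})),
            segmentation=_from_plain(SegmentationParams, data.get("segmentation", {})),
            classification=_from_plain(ClassificationThresholds, data.get("classification", {})),
            stats=_from_plain(StatsOptions, data.get("stats", {})),
        )

    def to_yaml(self, path: "Path | str | None" = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: "Path | str") -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})
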