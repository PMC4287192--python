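"""Pipeline configuration: one strict, round-trippable parameter tree.

Every stage threshold defaults to the published protocol value (missing
0.15 / distortion P 1e-4, grouping LOD 6 then rec 0.3 / LOD 3, singleton
windows 5/10 cM, heterogeneity P 0.001, MAF 0.10, LD-block r2 0.3,
experiment-wise alpha 0.05 over LD blocks, marker-wise 0.01, CI pad
2.2 cM). Unknown keys are rejected on load and configs round-trip
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .linkage import MapParams

__all__ = ["SimDesign", "LDParams", "DiversityParams", "GwasParams", "PipelineConfig"]


@dataclass(frozen=True)
class SimDesign:
    """Shape of the simulated study (map, populations, panel, phenotype)."""

    n_groups: int = 3
    group_length_cM: float = 120.0
    n_markers_per_group: int = 30
    n_pops: int = 4
    anchor_fraction: float = 0.4
    pop_type: str = "RIL"
    n_lines: int = 150
    missing_rate: float = 0.05
    error_rate: float = 0.005
    subpop_sizes: tuple[int, ...] = (11, 55, 26, 56, 35)
    ne: int = 20
    generations: int = 8
    admixture: float = 0.1
    n_envs: int = 27
    n_areas: int = 5
    n_qtl: int = 6
    qtl_effect: float = 1.2
    major_slope: float = 4.0
    env_sd: float = 2.0


@dataclass(frozen=True)
class LDParams:
    maf_min: float = 0.10
    k: float = 4.0
    fit_alpha: bool = True
    background_min_cM: float = 50.0
    background_percentile: float = 95.0
    r2_block: float = 0.3


@dataclass(frozen=True)
class DiversityParams:
    n_perm: int = 200
    alpha: float = 0.01


@dataclass(frozen=True)
class GwasParams:
    maf_min: float = 0.10
    alpha_exp: float = 0.05
    alpha_marker: float = 0.01
    ci_pad: float = 2.2
    n_covariate_majors: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    heterogeneity_alpha: float = 0.001
    sim: SimDesign = field(default_factory=SimDesign)
    map_params: MapParams = field(default_factory=MapParams)
    ld: LDParams = field(default_factory=LDParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    gwas: GwasParams = field(default_factory=GwasParams)

    # -- strict (de)serialization ------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, path="")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValidationError(f"config section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValidationError(f"unknown config keys at {path or '<root>'}: {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        val = data[name]
        sub = _section_type(f)
        if sub is not None:
            kwargs[name] = _build(sub, val, f"{path}{name}.")
        elif _is_tuple_field(f):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def _section_type(f):
    t = f.type if not isinstance(f.type, str) else None
    for cand in (SimDesign, MapParams, LDParams, DiversityParams, GwasParams):
        if f.type in (cand, cand.__name__) or t is cand:
            return cand
    return None


def _is_tuple_field(f) -> bool:
    name = f.type if isinstance(f.type, str) else getattr(f.type, "__name__", "")
    return "tuple" in str(name)
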