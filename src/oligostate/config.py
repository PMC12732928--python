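"""Run configuration: one structured YAML file, strict keys, module defaults.

Every tolerance/threshold default equals the value documented in the module
it configures, so an empty config reproduces the package defaults exactly.
Unknown keys are rejected rather than ignored — silent typos in an analysis
config are worse than a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class SaxsConfig:
    qrg_limit: float = 1.3
    ift_n_r: int = 101
    ift_alpha_min: float = 1e-2
    ift_alpha_max: float = 1e8
    ift_alpha_points: int = 50
    quad_order: int = 76
    vbar: float = 0.73
    q_units: str = "1/A"


@dataclass
class MaldiConfig:
    proton_mass: float = 1.00728
    use_proton: bool = True
    n_max: int = 10
    z_max: int = 3
    tol_ppm: float = 500.0
    tol_ppm_high: float = 2000.0
    high_n_from: int = 5


@dataclass
class AfmConfig:
    threshold_nm: float = 0.5
    footprint_level_nm: float = 0.15
    min_area_px: int = 4
    smooth_sigma_px: float = 1.0
    flatten_order: int = 1
    min_count: int = 20


@dataclass
class ItcConfig:
    window_s: float = 290.0
    baseline_frac: float = 0.2


@dataclass
class ConsistencyConfig:
    helix_diameter_a: float = 12.0
    helix_tolerance: float = 0.25
    afm_saxs_tolerance: float = 0.35
    n_max: int = 10


@dataclass
class SyntheticConfig:
    saxs_frac_sd: float = 0.02
    afm_background_sd_nm: float = 0.05
    itc_noise_sd_uw: float = 0.02
    seed: int = 0


@dataclass
class RunConfig:
    saxs: SaxsConfig = field(default_factory=SaxsConfig)
    maldi: MaldiConfig = field(default_factory=MaldiConfig)
    afm: AfmConfig = field(default_factory=AfmConfig)
    itc: ItcConfig = field(default_factory=ItcConfig)
    consistency: ConsistencyConfig = field(default_factory=ConsistencyConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: "
                         f"{sorted(unknown)}; known: {sorted(known)}")
    return cls(**data)


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML config; missing sections/keys fall back to defaults.

    ``overrides`` (same nested structure) take precedence over the file —
    the analysis drivers map their command-line flags through it.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data = loaded
    if overrides:
        for sec, vals in overrides.items():
            data.setdefault(sec, {}).update(vals)
    sections = {f.name: f.default_factory for f in fields(RunConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}; "
                         f"known: {sorted(sections)}")
    built = {}
    for name, factory in sections.items():
        built[name] = _build(type(factory()), data.get(name, {}) or {}, name)
    return RunConfig(**built)
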