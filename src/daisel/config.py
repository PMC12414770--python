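"""Run configuration: one YAML/JSON file drives every pipeline stage.

Every knob the stages expose (curation thresholds, MAD constant, smoothing
parameter, SD levels for isolines, singular-value partitioning, simulator
seed, header aliases) lives here so a run is fully described by its resolved
config, which is logged at startup.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

log = logging.getLogger("daisel")

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # curation
    min_yield: float = 50.0  # g·plant⁻¹; values strictly below are dropped
    mad_cutoff: float = 6.0
    mad_scale_constant: float = 1.4826  # 1.0 gives the raw-MAD convention
    curation_group_by: tuple[str, ...] = ("year", "treatment")
    # spatial adjustment
    tps_lambda: float | None = None  # None → choose by GCV
    tps_per_block: bool = False
    tps_gcv_grid_size: int = 40
    # BLUP engine
    mean_basis_repeatability: bool = False  # divide Ve by replicate count in Vp
    # stress indices
    dai_sqrt: bool = False  # geometric-mean variant of the DAI
    yi_stress_mean: bool = False  # YI = Ys/Ȳs instead of Ys/Ȳp
    # adaptation classes
    sd_levels: tuple[float, ...] = (0.0, 1.0, 2.0)
    population_sd: bool = False  # n divisor instead of n-1
    # AMMI / GGE
    ammi_axes: int = 2
    gge_svp: str = "symmetric"
    # simulator / global
    seed: int = 1
    header_aliases: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["curation_group_by"] = list(self.curation_group_by)
        d["sd_levels"] = list(self.sd_levels)
        return d

    def log_resolved(self) -> None:
        log.info("resolved config: %s", json.dumps(self.to_dict(), sort_keys=True))


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML or JSON config file, apply overrides, log the result.

    Unknown keys raise ``KeyError`` so typos do not silently fall back to
    defaults.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("curation_group_by", "sd_levels"):
        if tup_key in data and isinstance(data[tup_key], list):
            data[tup_key] = tuple(data[tup_key])
    cfg = PipelineConfig(**data)
    cfg.log_resolved()
    return cfg
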