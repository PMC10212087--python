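"""Pipeline configuration: schema-validated, preset-aware, round-trippable.

A config file (YAML or JSON) selects a preset (day5 | day20 | custom) and
may override any pipeline parameter.  Unknown keys and out-of-range values
are rejected with a message listing every violation (pydantic does the
aggregation).  The effective config — defaults applied — is echoed to the
log and written beside the outputs so a run is reproducible from its
artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as _PydanticError

from ._errors import ConfigError

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """All tunable parameters of the two pipeline arms."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    preset: str = Field("day5", pattern="^(day5|day20|custom)$")
    seed: int = Field(0, ge=0, lt=2**31)
    out_dir: str = "spheromech_out"
    strict: bool = False

    # mechanics arm
    noise_sd: float = Field(0.02, ge=0.0, le=0.2)
    pixel_pitch_um: float = Field(2.0, gt=0.0)
    initial_separation_um: float = Field(500.0, gt=0.0)
    search_radius_px: int = Field(10, ge=1, le=100)
    score_floor: float = Field(0.5, ge=0.0, le=1.0)
    poisson_ratio: float = Field(0.5, ge=0.0, le=0.5)
    spring_constant: float | None = Field(None, gt=0.0)
    n_mech_runs: int = Field(6, ge=1, le=50)

    # custom-preset spheroid (ignored for day5/day20)
    diameter_um: float | None = Field(None, gt=0.0)
    youngs_modulus_pa: float | None = Field(None, ge=0.0)

    # TEM arm
    strip_height_um: float = Field(100.0, gt=0.0)
    strip_length_um: float | None = Field(None, gt=0.0)  # default: spheroid diameter
    panel_width_um: float = Field(60.0, gt=0.0)
    panel_overlap: float = Field(0.1, ge=0.0, lt=0.5)
    resolution_px_per_um: float = Field(2.0, gt=0.0)
    n_tem_strips: int = Field(3, ge=1, le=20)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load and validate a YAML/JSON config; overrides win over the file.

    An empty or missing file yields all defaults.  Validation failures
    raise :class:`ConfigError` listing every violation.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        config = PipelineConfig(**data)
    except _PydanticError as err:
        violations = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors())
        raise ConfigError(f"invalid configuration: {violations}") from err
    log.info("effective config: %s", config.model_dump())
    return config


def write_effective_config(config: PipelineConfig, out_dir) -> Path:
    """Write the effective config beside the outputs (JSON, sorted keys)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_config.json"
    path.write_text(json.dumps(config.model_dump(), sort_keys=True, indent=2) + "\n")
    return path
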