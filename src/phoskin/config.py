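"""Schema-validated run configuration for simulation and ensemble runs.

Unknown keys are rejected (pydantic ``extra="forbid"``), and validation
errors name the offending key.  A resolved snapshot of the configuration
is written next to every run's outputs so results are reconstructible.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class SamplingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    km_nonphos_range: tuple[float, float] = (0.5, 2.0)
    km_wt_glc6p_range: tuple[float, float] = (0.5, 2.0)
    vmax_nonphos_range: tuple[float, float] = (0.6, 1.0)
    vmax_glc6p_wt: float = 0.5
    v1max: float = 0.5
    hill_n_range: tuple[float, float] = (0.0, 4.0)
    ka_range: tuple[float, float] = (0.01, 1.0)
    ki_range: tuple[float, float] = (0.01, 1.0)
    n_draws: int = Field(default=200, ge=1)


class ModesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    v10_substrate: Literal["x4", "x8"] = "x4"
    shared_hill: bool = True
    p_multiplier: float = Field(default=1.0, ge=0.0)
    imputation: Optional[Literal["inherit"]] = None
    imputation_source: Optional[str] = None


class EnsembleConfig(BaseModel):
    """Top-level configuration document for `phoskin ensemble`."""

    model_config = ConfigDict(extra="forbid")

    initial_state: Optional[list[float]] = None
    horizon: float = Field(default=200.0, gt=0.0)
    n_points: int = Field(default=1000, ge=2)
    sampling: SamplingBlock = SamplingBlock()
    variants: list[str] = ["WT", "M1", "M2", "M3"]
    ratio_table: Optional[str] = None  # CSV path; None -> packaged default
    modes: ModesBlock = ModesBlock()
    seed: int = 0


def load_ensemble_config(payload: dict) -> EnsembleConfig:
    """Validate a configuration dict; errors name the offending key."""
    try:
        return EnsembleConfig.model_validate(payload)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from exc
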