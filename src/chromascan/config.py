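"""Pipeline configuration: nested, validated, fingerprinted.

Unknown keys are rejected, and the resolved configuration round-trips
serialize -> parse -> serialize byte-identically, so the fingerprint (a
stable hash of the resolved block) identifies the exact run conditions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InstrumentBlock(_Strict):
    na_illum: float = 0.6
    na_collect: float = 0.8
    lambda_min: float = 500.0
    lambda_max: float = 700.0
    lambda_step: float = 2.0
    coherence_side: float = 458.0
    depth_of_field: float = 3000.0
    sens_lo: float = 23.0
    sens_hi: float = 334.0


class SimulateBlock(_Strict):
    # demo-scale cohort; the full study-scale group sizes are the
    # CohortConfig defaults and can be set explicitly here
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"Control": 8, "DA": 3, "NDA": 3, "AA": 8, "HNPCC": 3, "CRC": 3}
    )
    cells_per_patient: int = 8
    nucleus_radius_px: int = 5
    grid_cols: int = 4
    noise_sd: float = 0.01
    group_d_sd: float = 0.075
    nucleus_d_sd: float = 0.04
    age_coeff: float = -0.008


class DmapBlock(_Strict):
    phi: float = 0.35
    nf: float = 200_000.0
    d_grid_lo: float = 2.05
    d_grid_hi: float = 2.95
    d_grid_step: float = 0.05
    noise_floor: float = 0.01  # matches SimulateBlock.noise_sd by default


class AggregateBlock(_Strict):
    delta_ref: float = 0.06
    ci_level: float = 0.95


class RiskStratumBlock(_Strict):
    sex: str
    age_band: str
    annual_aa_to_crc: float


class RiskBlock(_Strict):
    # PLACEHOLDER strata; the cited surveillance tables do not print values
    strata: list[RiskStratumBlock] = Field(
        default_factory=lambda: [
            RiskStratumBlock(sex="male", age_band="<80", annual_aa_to_crc=0.026),
            RiskStratumBlock(sex="male", age_band=">=80", annual_aa_to_crc=0.050),
            RiskStratumBlock(sex="female", age_band="<80", annual_aa_to_crc=0.021),
            RiskStratumBlock(sex="female", age_band=">=80", annual_aa_to_crc=0.043),
        ]
    )
    # cumulative probability of a future advanced adenoma, by diagnostic group
    group_aar: dict[str, float] = Field(
        default_factory=lambda: {
            "Control": 0.06, "DA": 0.12, "NDA": 0.20, "AA": 0.40, "HNPCC": 0.70, "CRC": 0.40,
        }
    )
    # fraction of each group's patients counted as having a cancer history
    group_cancer_history_frac: dict[str, float] = Field(
        default_factory=lambda: {
            "Control": 0.0, "DA": 0.0, "NDA": 0.0, "AA": 0.0, "HNPCC": 0.0, "CRC": 1.0,
        }
    )
    crcm: float = 0.25
    horizon: float = 5.0


class ClassifyBlock(_Strict):
    endpoint: str = "Control vs AA"
    k: int = 4
    repeats: int = 2
    latent_dim: int = 8
    epochs: int = 200
    out_side: int = 32
    grid: dict[str, list] | None = Field(
        default_factory=lambda: {"n_estimators": [100], "max_depth": [None], "max_features": ["sqrt"]}
    )


class ReportBlock(_Strict):
    reference_group: str = "Control"


class PipelineConfig(_Strict):
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    instrument: InstrumentBlock = Field(default_factory=InstrumentBlock)
    dmap: DmapBlock = Field(default_factory=DmapBlock)
    aggregate: AggregateBlock = Field(default_factory=AggregateBlock)
    risk_model: RiskBlock = Field(default_factory=RiskBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)
    report: ReportBlock = Field(default_factory=ReportBlock)

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.dmap.d_grid_lo >= self.dmap.d_grid_hi:
            raise ValueError("d_grid_lo must be below d_grid_hi")
        return self

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())

    def fingerprint(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing path means all defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
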