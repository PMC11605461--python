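"""Run configuration: a single JSON document with per-stage sections.

All randomness is routed through named seeds recorded in every stage
manifest, so any report number can be traced to (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator


class SynthSection(BaseModel):
    n_patients: int = 2000
    case_fraction: float = 0.444
    vocab_size: int = 450
    mean_pathway_length: float = 40.0
    signal_mode: Literal["marginal_shift", "order_only"] = "marginal_shift"
    seed: int = 0


class PathwaySection(BaseModel):
    lookback_months: int = 36
    trim_months: int = 1
    min_codes: int = 10
    max_len: int = 128

    @model_validator(mode="after")
    def _check(self):
        if self.trim_months >= self.lookback_months:
            raise ValueError("trim_months must be < lookback_months")
        return self


class CohortSection(BaseModel):
    train_fraction: float = 0.7
    eval_size: int = 300
    validation_sample_size: Optional[int] = None
    stratum_quotas: Optional[dict[str, int]] = None
    seed: int = 0


class PlanSection(BaseModel):
    batch_size: int = 32
    epochs: int = 6
    learning_rate: float = 1e-3
    restarts: int = 1
    seed: int = 0


class EvaluationSection(BaseModel):
    threshold: float = 0.4
    thresholds: list[float] = Field(
        default_factory=lambda: [round(0.40 + 0.05 * i, 2) for i in range(7)]
    )
    n_boot: int = 200
    seed: int = 0


class InterpretationSection(BaseModel):
    k: int = 6
    n_init: int = 10
    perplexity: float = 30.0
    seed: int = 0


class RunConfig(BaseModel):
    """Top-level run configuration (see ``pathdx init-config``)."""

    outdir: str = "runs/demo"
    preset: Literal["desk", "paper"] = "desk"
    synth: SynthSection = Field(default_factory=SynthSection)
    pathway: PathwaySection = Field(default_factory=PathwaySection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    pretrain_plan: PlanSection = Field(default_factory=PlanSection)
    finetune_plan: PlanSection = Field(
        default_factory=lambda: PlanSection(epochs=8, learning_rate=5e-4, restarts=2)
    )
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    interpretation: InterpretationSection = Field(default_factory=InterpretationSection)
    # external-data mode: set these to use your own tables instead of `synth`
    patients_path: Optional[str] = None
    events_path: Optional[str] = None
    codemap_path: Optional[str] = None

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(mode="json"), indent=2))
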