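"""Pipeline configuration: a single YAML file validated up front.

Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults), and the effective configuration — with all defaults
materialised — is written into the output directory so a run is
re-executable from its artifacts alone. All randomness derives from the
single top-level ``seed``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DigestionConfig(_Strict):
    min_len: int = 7
    max_len: int = 30
    max_missed: int = 3
    proline_rule: bool = True


class FilterConfig(_Strict):
    precursor_q: float = 0.01
    protein_group_q: float = 0.01
    pep: float = 0.01
    min_unique_peptides: int = 2
    remove_reverse: bool = True
    remove_contaminants: bool = True
    per_protocol: bool = True
    modified_q: float = 0.05
    modified_pep: float = 0.05
    modified_min_unique: int = 2


class ImputationConfig(_Strict):
    quantile: float = 0.01


class LmmConfig(_Strict):
    response: Literal["gravy", "pi"] = "gravy"


class RiskConfig(_Strict):
    thresholds: list[float] = [1e-4, 1e-3, 1e-2, 5e-2]


class ProtocolConfig(_Strict):
    name: str
    depth: float = 2000.0
    bias_gravy: float = 0.0
    bias_pi: float = 0.0
    missed_cleavage_rate: float = 0.12
    contaminant_load: float = 0.03
    faims_gain: float = 1.0
    ms1_ms2_ratio: float = 1.3


class DiagenesisConfig(_Strict):
    hydrolysis_intensity: float = 1.5
    deamidation_site_rate: dict[str, float] = {
        "N": 0.300,
        "Q": 0.1821,
        "R": 0.0784,
    }
    oxidation_rate: dict[str, float] = {"M": 0.10, "P": 0.05}
    contaminant_damage_scale: float = 0.5


class SimulatorConfig(_Strict):
    n_proteins: int = 150
    length_min: int = 120
    length_max: int = 400
    abundance_log_mean: float = 13.8
    abundance_log_sd: float = 2.0
    censor_quantile: float = 0.15
    protocols: list[ProtocolConfig] | None = None
    diagenesis: DiagenesisConfig = DiagenesisConfig()


class PipelineConfig(_Strict):
    out_dir: str
    seed: int = 1
    fasta: str | None = None
    report: str | None = None
    dialect: Literal["diann", "maxquant"] = "diann"
    pka_set: str = "IPC_peptide"
    digestion: DigestionConfig = DigestionConfig()
    filters: FilterConfig = FilterConfig()
    imputation: ImputationConfig = ImputationConfig()
    lmm: LmmConfig = LmmConfig()
    risk: RiskConfig = RiskConfig()
    simulate: SimulatorConfig | None = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_effective_config(config: PipelineConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
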