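"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .categorize import PERCENTILE_METHODS
from .conditions import DRUG_CONCENTRATIONS_UG_ML, Policy
from .errors import ConfigError
from .scoring import DEFAULT_QC_MIN_CELLS
from .stats import KAPPA_SE_METHODS


@dataclass
class RunConfig:
    qc_min_cells: int = DEFAULT_QC_MIN_CELLS
    percentile_method: str = "linear"
    policy: str = str(Policy.ANY_PROGRESSION)
    level: float = 0.95
    kappa_se: str = "fleiss-cohen-everitt"
    #: final assay concentrations, µg/mL; metadata only, never used in
    #: any computation
    drug_concentrations_ug_ml: dict[str, float] = field(
        default_factory=lambda: dict(DRUG_CONCENTRATIONS_UG_ML)
    )

    def __post_init__(self) -> None:
        if self.qc_min_cells < 1:
            raise ConfigError("qc_min_cells must be >= 1")
        if self.percentile_method not in PERCENTILE_METHODS:
            raise ConfigError(
                f"percentile_method must be one of {PERCENTILE_METHODS}"
            )
        try:
            Policy(str(self.policy))
        except ValueError as exc:
            raise ConfigError(f"unknown policy {self.policy!r}") from exc
        if not 0.0 < self.level < 1.0:
            raise ConfigError("level must lie in (0, 1)")
        if self.kappa_se not in KAPPA_SE_METHODS:
            raise ConfigError(f"kappa_se must be one of {KAPPA_SE_METHODS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
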