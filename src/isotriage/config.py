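"""Pipeline configuration: one YAML file holding every path and threshold.

Unknown keys are rejected so silent typos cannot change a run; all
thresholds default to the package's documented values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .cascade import DEFAULT_STAGE_CUTOFFS
from .hits import TierThresholds
from .screen import ScreenThresholds

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one end-to-end triage run."""

    transcripts: Optional[str] = None
    out_dir: str = "triage_out"
    seed: int = 0
    min_length: int = 300
    gene_model_format: Optional[str] = None  # gff3 | bed12 | None (infer)
    max_evalue: float = 1e-10
    contaminant_hits: Dict[str, str] = field(default_factory=dict)
    validation_hits: Optional[str] = None
    stage_hits: Dict[str, str] = field(default_factory=dict)
    rfam_hits: Optional[str] = None
    stage_cutoffs: Dict[str, Optional[float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_CUTOFFS)
    )
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    tiers: TierThresholds = field(default_factory=TierThresholds)
    trust_qcovs: bool = False
    uorf_min_len: int = 9
    allow_uorf_overlap_main: bool = True
    polya_motifs: tuple = ("AATAAA",)
    subgenome_margin: float = 0.5
    retention_threshold: float = 0.95

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        payload = dict(data)
        for key, sub_cls in (("screen", ScreenThresholds), ("tiers", TierThresholds)):
            if key in payload and isinstance(payload[key], Mapping):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(payload[key]) - sub_known
                if sub_unknown:
                    raise ConfigError(
                        f"unknown config key(s) under {key!r}: {sorted(sub_unknown)}"
                    )
                try:
                    payload[key] = sub_cls(**payload[key])
                except ValueError as exc:
                    raise ConfigError(str(exc)) from exc
        if "polya_motifs" in payload:
            payload["polya_motifs"] = tuple(payload["polya_motifs"])
        try:
            return cls(**payload)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_manifest(self) -> Dict[str, Any]:
        """Machine-readable record of every input and threshold."""
        from dataclasses import asdict

        payload = asdict(self)
        payload["polya_motifs"] = list(self.polya_motifs)
        return payload
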