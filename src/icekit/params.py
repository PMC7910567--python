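"""Bundled analysis parameters with plain-text (YAML) config support."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .hbond import HBondCriterion
from .icedetect import SwitchingParams

__all__ = ["AnalysisParams"]


@dataclass
class AnalysisParams:
    """All knobs of the classification/binding pipeline in one place."""

    switching: SwitchingParams = field(default_factory=SwitchingParams)
    threshold: float = 0.45
    normalize: bool = True
    link_cutoff: float = 0.35
    criterion: HBondCriterion = field(default_factory=HBondCriterion)
    binding_threshold: float = 0.20
    shell_cutoff: float = 0.45

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sw = SwitchingParams(**data.pop("switching", {}))
        crit = HBondCriterion(**data.pop("criterion", {}))
        return cls(switching=sw, criterion=crit, **data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
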