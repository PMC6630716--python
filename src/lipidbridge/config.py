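"""Pipeline parameter sets with the workflow's standard defaults.

Retention times are minutes and mass tolerances absolute Da throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .targeted import TargetedParams


@dataclass(frozen=True)
class UntargetedParams:
    """Untargeted (peak spotting + annotation) parameters."""

    ms1_tol: float = 0.01                 # accurate mass tolerance (MS1), Da
    ms2_tol: float = 0.025                # MS2 tolerance, Da
    smoothing_level: int = 3
    min_peak_width: int = 5               # scans
    min_peak_height: float = 1000.0
    mass_slice_width: float = 0.1         # Da; doubles as XIC extraction width
    rt_tol_identification: float = 4.0    # minutes
    ms1_tol_identification: float = 0.01  # Da
    ms2_tol_identification: float = 0.05  # Da
    score_cutoff: float = 70.0            # percent
    rt_tol_alignment: float = 0.05        # minutes
    ms1_tol_alignment: float = 0.015      # Da
    blank_fold: float = 5.0               # sample max / blank average


@dataclass(frozen=True)
class PipelineConfig:
    untargeted: UntargetedParams = field(default_factory=UntargetedParams)
    targeted: TargetedParams = field(default_factory=TargetedParams)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"untargeted": asdict(self.untargeted),
                 "targeted": asdict(self.targeted), "seed": self.seed},
                fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            untargeted=UntargetedParams(**data.get("untargeted", {})),
            targeted=TargetedParams(**data.get("targeted", {})),
            seed=int(data.get("seed", 0)),
        )
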