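"""Serializable pipeline configuration (YAML)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import yaml

from .synthetic import CohortSpec, MeshSpec, NoiseSpec, ProtocolSpec


@dataclass
class PipelineConfig:
    """Full configuration of one end-to-end run.

    A snapshot is written alongside the outputs so every run is
    reproducible from (config, seed) alone.
    """

    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(
        groups={"controls": 6, "amputees": 5, "one_handers": 5}))
    winner_statistic: str = "t_like"      # or "beta_mean"
    wta_threshold: float = 0.0
    glm_derivatives: bool = False
    rsa_lambda: Optional[float] = None    # None -> analytic shrinkage
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "somatomap_out"
    write_gifti: bool = True
    distance_scale: float = 1.0           # per-subject size-normalisation hook

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        cohort_d = d.pop("cohort", {})
        if cohort_d:
            for key, sub_cls in (("mesh", MeshSpec), ("protocol", ProtocolSpec),
                                 ("noise", NoiseSpec)):
                if key in cohort_d and isinstance(cohort_d[key], dict):
                    cohort_d[key] = sub_cls(**cohort_d[key])
            if "conditions" in cohort_d:
                cohort_d["conditions"] = tuple(cohort_d["conditions"])
            if "hemispheres" in cohort_d:
                cohort_d["hemispheres"] = tuple(cohort_d["hemispheres"])
            cohort = CohortSpec(**cohort_d)
        else:
            cohort = CohortSpec(groups={"controls": 6, "amputees": 5,
                                        "one_handers": 5})
        return cls(cohort=cohort, **d)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
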