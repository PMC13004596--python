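"""Run configuration: every analysis threshold with its stated default.

The effective configuration is serialized (YAML) next to every run's
outputs so a result can always be traced to the cutoffs that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # co-regulation quadrants
    dpsi_min: float = 10.0
    mv_min: float = 0.0
    controls_n: int = 1000
    control_dpsi_max: float = 1.0
    control_mv_max: float = 0.0
    base_mean_min: float = 100.0
    # 3'ss-proximal windows
    window_from_up: int = 60
    window_to_up: int = 20
    yeast_window_from_up: int = 80
    yeast_window_to_up: int = 1
    # motif scan
    core_motif: str = "ACTAA"
    halfsite_motif: str = "YAAY"
    halfsite_max_dist: int = 20
    enrichment_method: str = "chi2"
    # percent-unspliced statistics
    pu_alpha: float = 0.1
    expression_min: float = 100.0
    tpm_min: float = 0.2
    pseudocount: float = 0.5
    # DIA differential
    dia_loose_l2fc: float = 0.2
    dia_strict_l2fc: float = 0.7
    dia_p_max: float = 0.01
    # reproducibility / output
    seed: int = 0
    out_prefix: str = "bscomp_run"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        known.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**known)
        cfg.extra = extra
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
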