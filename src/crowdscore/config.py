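"""Flat key=value configuration for pipeline runs."""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, fields


@dataclass
class PipelineConfig:
    # randomness
    seed: int = 0
    # synthetic crowd
    n_patients: int = 150
    cores_per_patient: int = 2
    marker_id: str = "M1"
    scheme: int = 1
    raters_per_segment: int = 5
    central_only: bool = True
    expert_fraction: float = 0.12
    expert_noise_sd: float = 2.0
    p_miss_cancer: float = 0.10
    p_false_cancer: float = 0.05
    proportion_noise_sd: float = 15.0
    intensity_noise_sd: float = 0.5
    baseline_rate: float = 0.02
    beta_h: float = math.log(0.991)
    censor_rate: float = 0.005
    # analysis
    k_folds: int = 10
    n_boot: int = 1000
    min_raters_per_segment: int = 5
    run_curves: bool = False
    curve_n_values: tuple = (20, 40, 80)
    curve_n_boot: int = 100
    multivariable: bool = False
    exclude_cystectomy_multivariable: bool = True

    def to_text(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            elif isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


_BOOLS = {"true": True, "false": False, "1": True, "0": False,
          "yes": True, "no": False}


def _coerce(raw: str, annotation, default):
    raw = raw.strip()
    if isinstance(default, bool):
        try:
            return _BOOLS[raw.lower()]
        except KeyError:
            raise ValueError(f"cannot parse boolean: {raw!r}") from None
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, tuple):
        return tuple(int(v) for v in raw.split(",") if v.strip())
    return raw


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Read a flat ``key = value`` file (# comments allowed) into a config.

    Unknown keys are an error; omitted keys keep their defaults.
    """
    cfg = PipelineConfig()
    by_name = {f.name: f for f in fields(cfg)}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{line_no}: expected key = value")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in by_name:
                    raise ValueError(f"{path}:{line_no}: unknown key {key!r}")
                setattr(cfg, key, _coerce(raw, by_name[key].type,
                                          getattr(cfg, key)))
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in by_name:
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    return cfg
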