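"""Analysis configuration shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass
class AnalysisConfig:
    equilibration_fraction: float = 0.2
    temperature: float = 300.0
    gas_constant: float = GAS_CONSTANT_KCAL
    bin_width_z: float = 1.0
    bulk_cutoff_z: float | None = None  # default: thickness/2 + 10 A, set per system
    crossing_margin: float = 5.0
    neighbor_cutoff_xy: float = 12.0
    segment_length: float = 10.0
    msd_remove_drift: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError(
                f"equilibration_fraction must be in [0, 1), got {self.equilibration_fraction}"
            )
        for name in ("temperature", "gas_constant", "bin_width_z",
                     "crossing_margin", "neighbor_cutoff_xy", "segment_length"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.bulk_cutoff_z is not None and self.bulk_cutoff_z <= 0:
            raise ValueError(f"bulk_cutoff_z must be positive, got {self.bulk_cutoff_z}")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML mapping; unknown keys go to ``extra``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(AnalysisConfig)} - {"extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return AnalysisConfig(extra=extra, **kwargs)
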