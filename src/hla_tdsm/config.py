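"""Run configuration: thresholds, regions, fit mode.

Defaults are the system's published operating constants: acceptability at
0.2 Å (class I) / 0.1 Å (class II) revised RMSD, severity cutoff 0.50 Å,
region-fit superposition, 4-decimal reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .matching import SEVERITY_CUTOFF
from .matrix import ACCEPTABLE_THRESHOLDS
from .structure import RegionSet, load_region_overrides

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    class_i_threshold: float = ACCEPTABLE_THRESHOLDS["I"]
    class_ii_threshold: float = ACCEPTABLE_THRESHOLDS["II"]
    severity_cutoff: float = SEVERITY_CUTOFF
    fit: str = "region"  # superpose on region residues (or "all")
    regions: dict[str, RegionSet] = field(default_factory=dict)
    rounding_decimals: int = 4

    def __post_init__(self) -> None:
        for name in ("class_i_threshold", "class_ii_threshold", "severity_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fit not in ("region", "all"):
            raise ValueError("fit must be 'region' or 'all'")

    @property
    def acceptability_thresholds(self) -> dict[str, float]:
        return {"I": self.class_i_threshold, "II": self.class_ii_threshold}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        regions = {}
        if "regions" in raw:
            regions = {
                hla_class: RegionSet(
                    hla_class, tuple((int(s), int(e)) for s, e in ranges)
                )
                for hla_class, ranges in raw.pop("regions").items()
            }
        if "region_file" in raw:
            regions.update(load_region_overrides(raw.pop("region_file")))
        return cls(regions=regions, **raw)

    def override(self, **kwargs) -> "RunConfig":
        """Apply non-None flag overrides on top of this config (flags win)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
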