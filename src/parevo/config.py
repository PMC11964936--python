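"""Run configuration: every tunable threshold of the pipeline in one place.

Config files may be TOML or YAML (chosen by extension); CLI flags override
file values, which override the defaults below.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Tissue vocabulary used throughout (order is the canonical output order).
DEFAULT_TISSUES: tuple[str, ...] = (
    "apex",
    "cotyledon",
    "hypocotyl",
    "inflorescence",
    "leaves",
)


@dataclass
class RunConfig:
    """All analysis thresholds, with defaults matching the published values."""

    # replicate QC
    spearman_min: float = 0.75
    # fate classification
    coexpr_high: float = 0.9
    coexpr_low: float = 0.5
    fc_mean: float = 1.0
    fc_sd: float = 1.0
    # gene-level features
    breadth_tpm: float = 3.0
    tau_min: float = 0.7
    tissue_specific_tpm: float = 5.0
    functional_tpm: float = 3.0
    # dosage test
    alpha: float = 0.05
    min_orthogroups_per_comparison: int = 3
    robust_z: bool = False
    z_cutoff: float | None = None
    # positional duplication classification
    proximal_max_gap: int = 10
    # Ks windows for the WGD / SSD stratified summary (closed intervals)
    ks_wgd: tuple[float, float] = (0.2, 2.5)
    ks_ssd: tuple[float, float] = (0.05, 2.5)
    # misc
    seed: int = 0
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    def __post_init__(self) -> None:
        if not 0.0 <= self.spearman_min <= 1.0:
            raise ValueError("spearman_min must be in [0, 1]")
        for name in ("coexpr_high", "coexpr_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coexpr_low > self.coexpr_high:
            raise ValueError("coexpr_low must not exceed coexpr_high")
        for name in ("fc_mean", "fc_sd", "breadth_tpm", "tissue_specific_tpm",
                     "functional_tpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.proximal_max_gap < 1:
            raise ValueError("proximal_max_gap must be >= 1")
        if self.min_orthogroups_per_comparison < 2:
            raise ValueError("min_orthogroups_per_comparison must be >= 2")
        self.ks_wgd = tuple(self.ks_wgd)  # type: ignore[assignment]
        self.ks_ssd = tuple(self.ks_ssd)  # type: ignore[assignment]
        self.tissues = tuple(self.tissues)  # type: ignore[assignment]
        for name in ("ks_wgd", "ks_ssd"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a valid non-negative interval")
        if not self.tissues:
            raise ValueError("tissues must be non-empty")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ks_wgd"] = list(self.ks_wgd)
        d["ks_ssd"] = list(self.ks_ssd)
        d["tissues"] = list(self.tissues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in {".toml", ".tml"}:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        elif path.suffix in {".yaml", ".yml", ".json"}:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        else:
            raise ValueError(f"unrecognized config extension: {path.suffix!r}")
        if data is None:
            data = {}
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            with open(path, "w") as fh:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        elif path.suffix == ".json":
            with open(path, "w") as fh:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        else:
            raise ValueError("config is written as .yaml/.yml or .json")

    def hash(self) -> str:
        """Stable content hash of the configuration (for run summaries)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
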