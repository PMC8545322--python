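"""Run configuration: every tunable of the comparison pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of a comparison run.

    Attributes
    ----------
    z
        Contact cutoff in Angstrom on the minimum sidechain-atom distance
        (glycine uses C-alpha).  Default 4.0; 5.0 and 6.0 are the usual
        alternates for robustness checks.
    min_separation
        Minimum number of intervening residues between a scored pair
        (``m``); pairs closer along the backbone are contacts by default
        and carry no coupling information.
    reweight_threshold
        Sequence-identity threshold for reweighting (0.7 / 0.8 / 0.9 grid).
    reg_strength
        Pairwise regularisation strength of the Potts fit (0.1 / 0.2 / 0.3).
    sd_multiplier
        Outlier exclusion threshold in SDs above the mean discrepancy.
    diversity_cutoff
        Maximum pairwise identity among reference structures; None skips
        the diversity selection.
    max_null_fraction
        Columns of flush alignments with a larger null fraction are not
        scored.
    redundancy_cutoff
        Identity cutoff for optional sequence dereplication (CLI-level).
    seed
        Seed for any stochastic step; the comparison itself is
        deterministic.
    """

    z: float = 4.0
    min_separation: int = 5
    reweight_threshold: float = 0.8
    reg_strength: float = 0.2
    sd_multiplier: float = 2.0
    diversity_cutoff: float | None = 0.65
    max_null_fraction: float = 0.5
    redundancy_cutoff: float = 0.95
    seed: int = 0
    allow_single_structure: bool = False

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ConfigError("contact cutoff z must be positive")
        if self.min_separation < 0:
            raise ConfigError("min_separation must be >= 0")
        if not 0.0 < self.reweight_threshold <= 1.0:
            raise ConfigError("reweight_threshold outside (0, 1]")
        if self.reg_strength <= 0:
            raise ConfigError("reg_strength must be positive")
        if self.sd_multiplier <= 0:
            raise ConfigError("sd_multiplier must be positive")
        if self.diversity_cutoff is not None and not 0.0 < self.diversity_cutoff <= 1.0:
            raise ConfigError("diversity_cutoff outside (0, 1]")
        if not 0.0 <= self.max_null_fraction < 1.0:
            raise ConfigError("max_null_fraction outside [0, 1)")
        if not 0.0 < self.redundancy_cutoff <= 1.0:
            raise ConfigError("redundancy_cutoff outside (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML (or JSON) mapping of flag names to values."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
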