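"""Run configuration shared by the CLI subcommands.

One flat, human-readable YAML file holds every tunable with a documented
default; CLI flags override individual keys. The config round-trips
through serialization unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from stackpol.constants import (
    BEAD_EFFECTIVE_MASS_G,
    FORCE_CLAMP_RPM,
    ROOM_TEMPERATURE_K,
    ROTOR_RADIUS_M,
)


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Units: temperatures K, rotor radius m, bead mass g, times s, lengths
    nm unless the field name says otherwise.
    """

    # thermodynamics / force clamp
    temperature_K: float = ROOM_TEMPERATURE_K
    rpm: float = FORCE_CLAMP_RPM
    rotor_radius_m: float = ROTOR_RADIUS_M
    bead_mass_g: float = BEAD_EFFECTIVE_MASS_G

    # kinetics fitting
    n_bins: int = 50
    weighted_fit: bool = False
    n_groups: int = 3

    # bead tracking
    detect_radius_min_px: int = 3
    detect_radius_max_px: int = 8
    detect_min_score: float = 0.45
    screen_min_separation_px: float = 12.0
    screen_min_circularity: float = 0.85
    call_drop_fraction: float = 0.5
    call_persistence_frames: int = 5

    # geometry / ensemble
    rho_cutoff_nm: float = 0.75
    cluster_ic_margin: float = 10.0

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature_K", "rotor_radius_m", "bead_mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rpm < 0:
            raise ValueError("rpm must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
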