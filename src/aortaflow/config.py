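"""Run configuration: every tunable of the quantification pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable thresholds and modes, serialisable to YAML/JSON.

    Attributes
    ----------
    onset_frac : float
        Systole onset threshold as a fraction of peak flow (default 0.10).
    fd_gate_pct : float
        Flow-displacement gate below which a frame carries no usable jet
        direction (default 12%).
    stab_tol_deg, stab_len : float, int
        Rotational-angle stabilisation rule: ``stab_len`` consecutive
        angle steps each within ``stab_tol_deg``.
    normalization : str
        'diameter' (FD normalised by 2*sqrt(A/pi)) or 'radius'.
    sfrr_denominator : str
        'sff' (ratio SRF/SFF) or 'sff_plus_srf'.
    vs_peak_mode : str
        'max' (single maximum pixel velocity) or 'p95' (95th percentile).
    seed : int
        Seed for any stochastic stage run under this config.
    """

    onset_frac: float = 0.10
    fd_gate_pct: float = 12.0
    stab_tol_deg: float = 15.0
    stab_len: int = 2
    normalization: str = "diameter"
    sfrr_denominator: str = "sff"
    vs_peak_mode: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.onset_frac < 1):
            raise ValueError("onset_frac must lie in [0, 1)")
        if self.fd_gate_pct < 0 or self.fd_gate_pct > 100:
            raise ValueError("fd_gate_pct must lie in [0, 100]")
        if self.stab_tol_deg <= 0 or self.stab_len < 1:
            raise ValueError("invalid stabilisation rule")
        if self.normalization not in ("diameter", "radius"):
            raise ValueError("normalization must be 'diameter' or 'radius'")
        if self.sfrr_denominator not in ("sff", "sff_plus_srf"):
            raise ValueError("sfrr_denominator must be 'sff' or 'sff_plus_srf'")
        if self.vs_peak_mode not in ("max", "p95"):
            raise ValueError("vs_peak_mode must be 'max' or 'p95'")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
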