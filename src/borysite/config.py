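"""Run configuration shared by the CLI stages.

A single seed drives every source of randomness (substrate generation,
splits, forests) so one config reproduces one result. Reports embed the
config and its hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

from .chem_core import AROMATICITY_MODEL
from .drfp import DEFAULT_N_BITS, DEFAULT_RADIUS, HASH_NAME


@dataclass
class RunConfig:
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS
    success_threshold: float = 5.0
    seed: int = 0
    mode: str = "aromatic_CH"
    require_yield: bool = False
    require_ir: bool = True
    n_estimators: int = 100
    shingle_hash: str = HASH_NAME
    aromaticity: str = AROMATICITY_MODEL

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def digest(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)
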