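"""Run configuration: every published threshold as a named default.

Keeping all cutoffs in one flat, JSON-serializable object means
sensitivity experiments (e.g. relaxing the identity criterion) need a
config edit, not a code edit, and every pipeline log can record exactly
which thresholds were applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional


@dataclass
class RunConfig:
    # unbound-structure acceptance (strict inequalities)
    identity_min: float = 0.93
    coverage_min: float = 0.80
    evalue_max: float = 1e-5
    # pairwise redundancy (strict inequalities)
    redundant_identity_min: float = 0.60
    redundant_evalue_max: float = 1e-30
    rmsd_max: float = 5.0
    # interface geometry
    interface_cutoff: float = 10.0
    contact_cutoff: float = 5.0
    # difficulty classification
    rigid_irmsd_max: float = 1.5
    rigid_fnn_max: float = 0.40
    difficult_irmsd_min: float = 2.2
    # numerics
    sasa_probe: float = 1.4
    sasa_points: int = 960
    tie_break_seed: Optional[int] = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
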