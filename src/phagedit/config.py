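"""Run configuration: one plain-text (YAML) file drives every module's
tunable, so a run is reproducible from its resolved config alone."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .goldengate import BBSI_DONOR_OVERHANGS, BSAI_SPACER_DROPOUT


@dataclass
class RunConfig:
    spacer_len: int = 31
    seed_window: tuple[int, int] = (5, 12)  # spacer positions, 1-based
    rare_threshold: float = 0.10
    deletion_arm_len: int = 250
    recode_arm_len: int = 52
    offtarget_min_match: int = 15
    hairpin_min_stem: int = 8
    hairpin_min_loop: int = 3
    min_contiguous_seed_changes: int = 3
    countable_range: tuple[int, int] = (1, 50)
    spot_volume_ul: float = 2.0
    bsai_dropout: str = BSAI_SPACER_DROPOUT
    bbsi_overhangs: tuple[str, str] = BBSI_DONOR_OVERHANGS
    # effector-specific direct repeat; not shipped, must be supplied per
    # effector before mature-crRNA hairpin screening
    direct_repeat: Optional[str] = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seed_window", "countable_range", "bbsi_overhangs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
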