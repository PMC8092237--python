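"""Run configuration: the package's defaults in one serializable place.

A :class:`RunConfig` collects every tunable the subcommands share —
editor windows, design defaults, scan and classifier thresholds, quality
filters and the seed — so a run can be reproduced from its logged
configuration.  Values load from a flat YAML/JSON ``defaults`` section
and individual CLI flags override them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # editor windows, protospacer coordinates (PAM-distal = 1), inclusive
    window_cbe: tuple[int, int] = (4, 8)
    window_abe: tuple[int, int] = (4, 7)
    # design defaults
    hairpin_len: int = 12
    bubble_size: int = 3
    bubble_start_cbe: int = 5
    bubble_start_abe: int = 4
    loop: str = "ACAA"
    # folding
    min_loop: int = 3
    allow_wobble: bool = True
    # off-target scan
    pam: str = "NGG"
    max_mm: int = 4
    # SNV classifier
    min_matches: int = 15
    require_pam: bool = True
    window_flank: int = 0
    # quantification
    min_qual: int = 20
    detection_floor: float = 0.001
    any_substitution: bool = False
    # randomness
    seed: int = 0

    def window(self, editor: str) -> tuple[int, int]:
        return self.window_cbe if editor.upper() == "CBE" else self.window_abe

    def bubble_start(self, editor: str) -> int:
        return self.bubble_start_cbe if editor.upper() == "CBE" else self.bubble_start_abe

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_cbe"] = list(d["window_cbe"])
        d["window_abe"] = list(d["window_abe"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("window_cbe", "window_abe"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; a top-level ``defaults`` key is optional."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            return cls()
        if "defaults" in data:
            data = data["defaults"]
        return cls.from_dict(data)

    def dump(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump({"defaults": self.to_dict()}, sort_keys=True))
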