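"""Run-level configuration shared by the CLI stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .panels import DEFAULT_MIR_PANEL, HOUSEKEEPER_ALIASES, normalize_mir_id
from .qpcr import ScoringConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    panel: tuple[str, ...] = DEFAULT_MIR_PANEL
    seed: int = 0
    n_permutations: int = 1000
    n_splits: int = 100
    n_trees: int = 500
    out_dir: str = "mirpipe_out"
    verbosity: int = 1

    def __post_init__(self) -> None:
        panel = tuple(normalize_mir_id(m) for m in self.panel)
        if not panel:
            raise ValueError("panel must be non-empty")
        if len(set(panel)) != len(panel):
            raise ValueError("panel contains duplicate microRNA ids")
        clash = [m for m in panel if m in HOUSEKEEPER_ALIASES]
        if clash:
            raise ValueError(f"housekeeper id(s) {clash} may not be in the analysis panel")
        self.panel = panel

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scoring = ScoringConfig(**raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = list(self.panel)
        return d
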