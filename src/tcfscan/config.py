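"""Run configuration with the survey's fixed parameters as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters tying the pipeline stages together.

    Defaults are the standard survey settings: stringent calling profile
    (HMG 4.5 / Helper 6.5; relaxed 3.5/5.0 and the per-CRM annotation
    profile 5.35/6.5 are selectable by name), spacers 0-15, ten background
    runs, and a 150-bp peak-partition radius.
    """

    profile: str = "stringent"
    max_spacer: int = 15
    n_background_runs: int = 10
    master_seed: int = 0
    partition_radius: int = 150
    partition_mode: str = "center-to-edge"
    anchor_orientation: str = "FF"
    anchor_spacer: int = 1
    window_halfwidth: int = 500
    hmg_training: str | None = None  # path; None -> packaged synthetic set
    helper_training: str | None = None
    background_frequencies: list[float] = field(
        default_factory=lambda: [0.25, 0.25, 0.25, 0.25]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
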