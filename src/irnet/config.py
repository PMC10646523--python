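"""Analysis configuration shared by the library, the pipeline, and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All knobs of an inter-system recurrence analysis in one place.

    ``rr_auto`` / ``rr_cross`` are the target recurrence rates used to
    calibrate the auto- and cross-recurrence thresholds (cross should not
    exceed auto). ``lag`` / ``dim`` are the shared delay-embedding
    parameters used for every scalar series in a run; keeping one set per
    analysis keeps cross-recurrence between different series well defined.
    ``convention`` selects the cross-clustering estimator used for
    direction inference (see :mod:`irnet.network`), and
    ``direction_threshold`` is the half-width of the band of coefficient
    differences read as bidirectional-or-uncoupled.
    """

    window_minutes: int = 35
    min_minutes: int = 25
    rr_auto: float = 0.05
    rr_cross: float = 0.04
    lag: int = 100
    dim: int = 5
    norm: str = "euclidean"
    convention: str = "time"
    direction_threshold: float = 0.01
    multiplex_mode: str = "cross_person"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rr_cross <= self.rr_auto < 1:
            raise ValueError("require 0 < rr_cross <= rr_auto < 1")
        if self.convention not in ("time", "graph"):
            raise ValueError("convention must be 'time' or 'graph'")
        if self.multiplex_mode not in ("cross_person", "within_client", "within_caregiver"):
            raise ValueError("unknown multiplex_mode")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
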