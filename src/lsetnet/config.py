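"""Run configuration: the experiment-level knobs, with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Training/experiment configuration.

    Defaults mirror the study protocol: 248-px inputs, batch size 32, up
    to 50 epochs of Adam (betas 0.9/0.999) with step decay from 1e-3 to
    1e-4, early-stopping patience 10, seed 42, 5-fold CV, a 70/15/15
    stratified split and post-augmentation per-class quotas 700/150/150.
    """

    image_size: int = 248
    batch_size: int = 32
    max_epochs: int = 50
    initial_lr: float = 1e-3
    final_lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    patience: int = 10
    seed: int = 42
    k_folds: int = 5
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    quotas: tuple[int, int, int] = (700, 150, 150)

    def __post_init__(self):
        self.split_ratios = tuple(self.split_ratios)
        self.quotas = tuple(int(q) for q in self.quotas)
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.split_ratios}")
        if any(q <= 0 for q in self.quotas):
            raise ValueError(f"quotas must be positive, got {self.quotas}")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 0:
            raise ValueError("batch_size/max_epochs must be >= 1 and patience >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)
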