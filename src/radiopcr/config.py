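"""Run configuration: every tunable of the pipeline in one serialisable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .features import BankConfig
from .imaging import DEFAULT_TARGET_SPACING_MM, LogBank
from .modeling import ROSTER

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults reproduce the protocol constants: 0.548 mm planar spacing,
    13 LoG sigmas (0–4.2 mm step 0.35), 10% IB level steps (55 pairs),
    8-fold selection with alpha 0.05 / >= 5 votes / |r| < 0.6 pruning, and
    3 x 8-fold CV model selection."""

    target_spacing_mm: float = DEFAULT_TARGET_SPACING_MM
    log_sigma_max_mm: float = 4.2
    log_sigma_step_mm: float = 0.35
    ib_step_pct: int = 10
    glcm_bins: int = 32
    glcm_distance: int = 1
    min_subpop_voxels: int = 8
    max_missing_frac: float = 0.2
    selection_k: int = 8
    alpha: float = 0.05
    min_votes: int = 5
    r_max: float = 0.6
    cv_k: int = 8
    cv_repeats: int = 3
    roster: tuple[str, ...] = ROSTER
    seed: int = 0

    def __post_init__(self) -> None:
        self.roster = tuple(self.roster)
        unknown = set(self.roster) - set(ROSTER)
        if unknown:
            raise ValueError(f"unknown roster keys: {sorted(unknown)}")

    def bank_config(self) -> BankConfig:
        return BankConfig(
            log_bank=LogBank(self.log_sigma_max_mm, self.log_sigma_step_mm),
            ib_step_pct=self.ib_step_pct,
            glcm_bins=self.glcm_bins,
            glcm_distance=self.glcm_distance,
            min_subpop_voxels=self.min_subpop_voxels,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roster"] = list(self.roster)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)
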