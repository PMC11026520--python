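"""Run configuration: defaults, YAML round-trip, seed substreams."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    """End-to-end pipeline parameters; every field has a recorded default."""

    out_dir: str = "plastcov_run"
    seed: int = 0
    # synth stage (omitted when cohort_csv is given)
    cohort_csv: str | None = None
    n_subjects: int = 1414
    n_modes: int = 3
    mode_strengths: list[float] = field(default_factory=lambda: [8.0, 6.0, 4.0])
    noise_sd: float = 1.0
    confound_effects: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.3, "head_size": 0.3}
    )
    asymmetry_mode_1: list[float] = field(default_factory=lambda: [0.0] * 9)
    n_phenotypes: int = 40
    phenotype_effect: float = 0.3
    # analysis parameters
    n_pls_modes: int = 3
    n_perm: int = 100
    n_boot: int = 100
    alpha: float = 0.05
    fdr_q: float = 0.05
    perm_alpha: float = 0.005
    ci_lower_pct: float = 10.0
    ci_upper_pct: float = 90.0
    age_bins: int = 6
    include_site: bool = True
    include_position: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def substreams(self, names: list[str]) -> dict[str, np.random.Generator]:
        """Named per-stage RNG substreams from the single run seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}
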