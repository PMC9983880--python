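"""Run configuration: a strict YAML schema with pipeline-wide defaults.

Every convention flag the procedure leaves open (quantile
convention, clipping, ranking mode, R^2 convention, importance mode) lives
here so a run log can state exactly which conventions were in effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import DEFAULT_DOSE_GRID

_KNOWN_KEYS = {
    "paths", "dose_grid", "feature_classes", "n_folds", "seeds",
    "k_features", "hyperparameter_grid", "flags", "synthetic",
}
_KNOWN_SEEDS = {"fold", "model", "resample", "synthetic"}
_KNOWN_FLAGS = {"clip_max", "signed_ranking", "importance_mode",
                "r2_convention", "truncation_percentile",
                "min_confidence", "include_dose"}
_KNOWN_GRID = {"trees", "predictors_per_split", "min_node_size"}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    paths: dict[str, str] = field(default_factory=dict)
    dose_grid: list[float] = field(
        default_factory=lambda: list(DEFAULT_DOSE_GRID))
    feature_classes: list[str] = field(
        default_factory=lambda: ["inhibition", "expression"])
    n_folds: int = 10
    seeds: dict[str, int] = field(
        default_factory=lambda: {"fold": 0, "model": 0, "resample": 0,
                                 "synthetic": 0})
    k_features: list[int] = field(default_factory=lambda: [200])
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    flags: dict = field(default_factory=lambda: {
        "clip_max": None, "signed_ranking": False,
        "importance_mode": "impurity", "r2_convention": "pearson",
        "truncation_percentile": 99.99, "min_confidence": 0.7,
        "include_dose": True})
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        grid = list(self.dose_grid)
        if not grid or any(x <= 0 for x in grid) or \
                any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("dose_grid must be positive and strictly "
                             "increasing")
        for name, s in self.seeds.items():
            if name not in _KNOWN_SEEDS:
                raise ValueError(f"unknown seed key {name!r}")
            if not isinstance(s, int):
                raise ValueError(f"seed {name!r} must be an integer")
        for name in self.flags:
            if name not in _KNOWN_FLAGS:
                raise ValueError(f"unknown flag {name!r}")
        for name, vals in self.hyperparameter_grid.items():
            if name not in _KNOWN_GRID:
                raise ValueError(f"unknown hyperparameter {name!r}")
            if any(int(v) <= 0 for v in vals):
                raise ValueError(f"hyperparameter {name!r} values must be "
                                 "positive")
        if any(k < 1 for k in self.k_features):
            raise ValueError("k_features entries must be >= 1")
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ValueError(f"path for {key!r} does not exist: {p}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level keys, unknown flags/seeds, missing paths and
    malformed grids raise ValueError naming the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    defaults = RunConfig()
    merged: dict = {}
    for key in _KNOWN_KEYS:
        default = getattr(defaults, key)
        if key not in raw:
            merged[key] = default
        elif isinstance(default, dict):
            merged[key] = {**default, **raw[key]}
        else:
            merged[key] = raw[key]
    return RunConfig(**merged).validate()
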