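"""Pipeline configuration with production defaults.

Defaults are the production analysis settings: 500-km x 40-day stixels, 10
partitions, 30-list stixel minimum, 1000-tree GBMs, prediction reference
(list total 25, year 2018, complete list), 0.01 occurrence floor, 25% season
cutoff, 17/30% policy baselines, 5 CV folds.  Reduced configurations for
fast runs scale the world, stixels and tree counts down, never the rule
parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .stem import GbmParams


@dataclass
class WorldConfig:
    n_x: int = 40
    n_y: int = 40
    cell_size_km: float = 10.0
    seed: int = 1
    n_species: int = 3
    protected_total_fraction: float = 0.201
    protected_farmland_bias: float = -2.0


@dataclass
class EffortSection:
    events_per_cell_day: float = 0.035
    p_complete: float = 0.6
    detectability: float = 0.8
    casual_rate: float = 15.0
    casual_report_rate: float = 0.8
    habitat_bias: dict = field(default_factory=lambda: {"urban": 1.0, "trees": -0.5})


@dataclass
class StemConfig:
    width_km: float = 500.0
    depth_days: float = 40.0
    n_partitions: int = 10
    min_lists: int = 30
    gbm: GbmParams = field(default_factory=GbmParams)
    floor: float = 0.01
    cv_folds: int = 5
    reference_list_length: float = 25.0
    reference_year: int = 2018


@dataclass
class CoverageConfig:
    season_cutoff: float = 0.25
    target_bases: tuple[float, float] = (17.0, 30.0)
    category_filter: tuple[str, ...] = ("I-IV", "V-VI", "undesignated")
    cell_threshold: float | None = None


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    effort: EffortSection = field(default_factory=EffortSection)
    stem: StemConfig = field(default_factory=StemConfig)
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    seed: int = 1
    out_dir: str = "run"

    def validate(self) -> None:
        if self.world.n_species < 1:
            raise ValueError("config must request at least one species")
        if self.world.n_x < 2 or self.world.n_y < 2:
            raise ValueError("world dimensions must be >= 2")
        if not (0 < self.stem.floor < 1):
            raise ValueError("occurrence floor must lie in (0, 1)")
        if not (0 < self.coverage.season_cutoff < 1):
            raise ValueError("season cutoff must lie in (0, 1)")
        if self.stem.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coverage"]["target_bases"] = list(self.coverage.target_bases)
        d["coverage"]["category_filter"] = list(self.coverage.category_filter)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        world = WorldConfig(**d.get("world", {}))
        effort = EffortSection(**d.get("effort", {}))
        stem_d = dict(d.get("stem", {}))
        gbm = GbmParams(**stem_d.pop("gbm", {}))
        stem = StemConfig(gbm=gbm, **stem_d)
        cov_d = dict(d.get("coverage", {}))
        if "target_bases" in cov_d:
            cov_d["target_bases"] = tuple(cov_d["target_bases"])
        if "category_filter" in cov_d:
            cov_d["category_filter"] = tuple(cov_d["category_filter"])
        coverage = CoverageConfig(**cov_d)
        return cls(
            world=world, effort=effort, stem=stem, coverage=coverage,
            seed=int(d.get("seed", 1)), out_dir=d.get("out_dir", "run"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def reduced_config(seed: int = 1) -> PipelineConfig:
    """Desk-scale configuration: 40x40 world, 5 partitions,
    100-tree base learners.  Rule parameters (floor, cutoff, targets,
    minimum lists, reference settings) keep their production values."""
    cfg = PipelineConfig(seed=seed)
    cfg.world.seed = seed
    cfg.stem.n_partitions = 5
    cfg.stem.gbm = GbmParams(n_trees=100)
    return cfg
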