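"""Pipeline configuration: one YAML-serializable object holding every tunable.

Defaults mirror the study's printed constants where one exists: adult-grid
sampling of 0.98 x 0.98 x 3 mm, T1 thresholds of 85% (pediatric) and 83%
(adult) of surrounding NAWM, a 3-voxel minimum size for counting a
T2-weighted lesion, one-voxel separation (26-connectivity) between distinct
lesions, and a 0.05 significance threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .io import load_yaml, save_yaml

# printed study constants, asserted against module defaults in the test suite
PAPER_CONSTANTS = {
    "adult_slice_thickness_mm": 3.0,
    "pediatric_slice_thickness_mm": 2.0,
    "inplane_mm": 0.98,
    "t1_fraction_pediatric": 0.85,
    "t1_fraction_adult": 0.83,
    "min_t2_lesion_voxels": 3,
    "alpha": 0.05,
    "n_per_group": 29,
    "n_calibration_subjects": 10,
}


class ConfigurationError(Exception):
    pass


@dataclass
class PreprocessSettings:
    bias_smoothness_mm: float = 30.0
    bias_iterations: int = 4
    landmark_percentiles: tuple = (2.0, 50.0, 98.0)
    standard_scale: tuple = (0.0, 100.0, 200.0)
    register: bool = True
    registration_coarse_factor: int = 3
    registration_fine: bool = False  # contrasts are near-aligned; coarse is enough


@dataclass
class SegmentSettings:
    posterior_threshold: float = 0.5
    nawm_ring_mm: float = 5.0
    t1_fraction_pediatric: float = 0.85
    t1_fraction_adult: float = 0.83
    infratentorial_threshold_multiple: float = 1.3
    lesion_prior: float = 0.04
    # lesion-class (PD, T2, T1) mean as multiples of the WM mean, raw scale
    lesion_contrast_multipliers: tuple = (1.33, 1.5, 0.80)
    lesion_covariance_inflation: float = 4.0


@dataclass
class QuantifySettings:
    connectivity: int = 26
    min_voxels_t2: int = 3
    min_voxels_t1: int = 1
    periventricular_distance_mm: float = 3.0


@dataclass
class StatsSettings:
    log_constant_cm3: float = 1.0
    equal_variance: bool = True
    alpha: float = 0.05


@dataclass
class CohortSettings:
    n_pediatric: int = 10
    n_adult: int = 10
    grid_shape: tuple = (96, 96, 60)
    noise_sigma: float = 4.0
    bias_field_amplitude: float = 0.2


@dataclass
class PipelineConfig:
    seed: int = 1234
    out_dir: str = "lesionquant_out"
    cohort: CohortSettings = field(default_factory=CohortSettings)
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    segment: SegmentSettings = field(default_factory=SegmentSettings)
    quantify: QuantifySettings = field(default_factory=QuantifySettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def __post_init__(self):
        if not (0.0 < self.stats.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        sections = {"cohort": CohortSettings, "preprocess": PreprocessSettings,
                    "segment": SegmentSettings, "quantify": QuantifySettings,
                    "stats": StatsSettings}
        for name, typ in sections.items():
            if name in kw and isinstance(kw[name], dict):
                sect = kw[name]
                known = {f.name for f in fields(typ)}
                unknown = set(sect) - known
                if unknown:
                    raise ConfigurationError(f"unknown keys in {name}: {sorted(unknown)}")
                kw[name] = typ(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in sect.items()})
        known = {f.name for f in fields(cls)}
        unknown = set(kw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def save(self, path) -> None:
        save_yaml(path, self.to_dict())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        return cls.from_dict(load_yaml(path))


def demo_config(out_dir: str = "lesionquant_demo", seed: int = 1234,
                n_per_group: int = 10) -> PipelineConfig:
    """Small end-to-end demonstration configuration (two cohorts of phantoms)."""
    return PipelineConfig(seed=seed, out_dir=out_dir,
                          cohort=CohortSettings(n_pediatric=n_per_group,
                                                n_adult=n_per_group))
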