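"""Run configuration: YAML-serializable defaults for every pipeline knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .core import SchemaError


@dataclass
class RunConfig:
    """All tunable parameters of a run, serializable to/from YAML.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.  CLI flags override file values.
    """

    # registration
    ncc_window_px: int = 10
    pyramid_factors: tuple = (8, 4, 2, 1)
    pre_sigma: float = 5.0
    post_sigma: float = 4.0
    iterations_per_level: int = 100
    affine_maxiter: int = 40
    rigid_trials: int = 64
    working_size: int = 1024
    seed: int = 0
    # geometry defaults
    resolution_um: float = 1.0
    spot_diameter_um: float = 55.0
    spot_pitch_um: float = 100.0
    msi_pitch_um: float = 30.0
    # preprocessing
    min_region_um2: float = 10_000.0
    spatial_radius: int = 20
    color_radius: float = 15.0
    tissue_darker: bool = True
    denoise: bool = True
    # analysis filters
    coverage_threshold: float = 0.8
    tissue_min_fraction: float = 0.5
    # warping
    fill_value: float = 0.0

    def registration_options(self):
        from .registration import RegistrationOptions

        return RegistrationOptions(
            ncc_window_px=self.ncc_window_px,
            pyramid_factors=tuple(self.pyramid_factors),
            pre_sigma=self.pre_sigma,
            post_sigma=self.post_sigma,
            iterations_per_level=self.iterations_per_level,
            affine_maxiter=self.affine_maxiter,
            rigid_trials=self.rigid_trials,
            seed=self.seed,
            working_size=self.working_size,
            denoise=self.denoise,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["pyramid_factors"] = list(data["pyramid_factors"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "pyramid_factors" in data:
            data = dict(data)
            data["pyramid_factors"] = tuple(data["pyramid_factors"])
        return cls(**data)
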