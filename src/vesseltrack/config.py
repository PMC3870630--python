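"""Run configuration: every tunable of the pipeline with its default.

Defaults follow the published operating point of the method: grid lines every
30 px, seed threshold factor alpha = 1.2 over a 61 x 61 neighborhood, a
look-ahead of s = 3 px, an initial window of L0 = 10 px, branch threshold
T_angle = 5 degrees and Gibbs prior parameters Z = 1, lambda = 0.01.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import SpecError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # seed selection
    grid_spacing: int = 30
    alpha: float = 1.2
    seed_window: int = 61
    profile_sigma: float = 2.0
    kernel_length: int = 9
    # tracking geometry
    s: float = 3.0
    L0: float = 10.0
    t_angle_deg: float = 5.0
    neighborhood: int = 5
    gradient_sigma: float = 1.0
    semicircle_radius_factor: float = 1.5
    min_window_length: float = 4.0
    candidate_spacing: float = 0.5
    max_iterations: int = 2000
    # Bayesian model
    gibbs_lambda: float = 0.01
    gibbs_z: float = 1.0
    sigma_floor: float = 0.5
    kappa_contrast: float = 1.0
    region_margin: float = 2.0
    # semicircle pruning
    min_gap: int = 2
    max_chord_factor: float = 1.5
    # randomness (phantom generation and any stochastic fixture)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing < 2:
            raise SpecError("grid_spacing must be >= 2")
        if self.alpha <= 0:
            raise SpecError("alpha must be positive")
        if self.seed_window < 1 or self.seed_window % 2 == 0:
            raise SpecError("seed_window must be odd and positive")
        if self.profile_sigma <= 0:
            raise SpecError("profile_sigma must be positive")
        if self.kernel_length < 3:
            raise SpecError("kernel_length must be >= 3")
        if self.s <= 0 or self.L0 <= 0:
            raise SpecError("s and L0 must be positive")
        if self.candidate_spacing <= 0:
            raise SpecError("candidate_spacing must be positive")
        if self.gradient_sigma < 0:
            raise SpecError("gradient_sigma must be non-negative")
        if not 0 < self.t_angle_deg <= 90:
            raise SpecError("t_angle_deg must be in (0, 90]")
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise SpecError("neighborhood must be odd and >= 3")
        if self.gibbs_z <= 0 or self.gibbs_lambda < 0:
            raise SpecError("gibbs_z must be > 0 and gibbs_lambda >= 0")
        if self.sigma_floor <= 0:
            raise SpecError("sigma_floor must be positive")
        if self.max_iterations < 1:
            raise SpecError("max_iterations must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise SpecError("configuration file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
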