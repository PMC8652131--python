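"""Run configuration: one serializable object covering every pipeline stage."""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, fields

import yaml

from .scene import ConditionEffects, SceneParams


@dataclass
class RunConfig:
    """All tunables of the simulate and quantify workflows.

    Round-trips through YAML; ``config_hash`` is recorded in every output
    table so results can be traced to the exact configuration.
    """

    scene: SceneParams = field(default_factory=SceneParams)
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    # channel binarization
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    threshold_value: float | None = None
    # ridge kernel bank
    kernel_length_px: int = 21
    kernel_width_px: float = 1.5
    n_orientations: int = 7
    max_deviation_deg: float = 15.0
    # string shape filter
    response_threshold: float | str = "otsu"
    min_length_um: float = 5.0
    min_axis_ratio: float = 3.0
    max_orientation_dev_deg: float = 20.0
    closing_radius_px: int = 0
    # particle gates (μm²)
    platelet_min_area_um2: float = math.pi
    platelet_max_area_um2: float = math.inf
    vwf_min_area_um2: float = 0.0
    vwf_max_area_um2: float = math.inf
    # statistics
    t_test_variant: str = "welch"  # "welch" | "student"
    # study layout
    n_fov: int = 35
    n_experiments: int = 3

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("platelet_max_area_um2", "vwf_max_area_um2"):
            if math.isinf(d[key]):
                d[key] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = d.pop("scene", {})
        effects = d.pop("effects", {})
        if isinstance(scene, dict):
            for k in ("fov_shape_px", "string_length_um_lognormal_mu_sigma", "agglomerate_radius_um"):
                if k in scene and scene[k] is not None:
                    scene[k] = tuple(scene[k])
            scene = SceneParams(**scene)
        if isinstance(effects, dict):
            effects = ConditionEffects(**effects)
        for key in ("platelet_max_area_um2", "vwf_max_area_um2"):
            if d.get(key) == "inf":
                d[key] = math.inf
        known = {f.name for f in fields(cls)} - {"scene", "effects"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scene=scene, effects=effects, **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
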