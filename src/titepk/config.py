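"""YAML design configuration for command-line runs.

A design file collects everything a dose-escalation analysis needs besides
the patient data: kinetic constants, the reference schedule, dose grids,
prior presets and decision bounds.  Two named presets ship with the package:
``"simulation"`` (reference 7.5 mg daily, BLRM sigma1 = 2) and
``"everolimus"`` (reference 5 mg daily, BLRM sigma1 = 1.25).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .pk import PKParams, Regimen

__all__ = ["DesignConfig", "PRESETS"]


@dataclass(frozen=True)
class DesignConfig:
    half_life_h: float = 30.0
    k_eff_per_h: float = 0.37
    ref_dose_mg: float = 5.0
    ref_interval_h: float = 24.0
    cycle_length_h: float = 504.0
    prior_p_ref: float = 0.30
    titepk_prior_sd: float = 1.25
    blrm_sigmas: tuple[float, float] = (1.25, 1.0)
    interval: tuple[float, float] = (0.20, 0.40)
    feasibility: float = 0.25
    target: float = 0.30
    crm_halfwidth: float = 0.10
    crm_prior_sd: float = 2.0
    dose_grids: dict = field(
        default_factory=lambda: {"daily": [2.5, 5.0, 7.5, 10.0]}
    )
    dose_intervals: dict = field(default_factory=lambda: {"daily": 24.0})
    seed: int = 0

    @property
    def pk(self) -> PKParams:
        return PKParams(self.half_life_h, self.k_eff_per_h)

    @property
    def ref(self) -> Regimen:
        return Regimen(self.ref_dose_mg, self.ref_interval_h, self.cycle_length_h)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        for key in ("blrm_sigmas", "interval"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def digest(self) -> str:
        """Stable hash identifying the design; recorded in outputs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


PRESETS: dict[str, DesignConfig] = {
    "everolimus": DesignConfig(),
    "simulation": DesignConfig(
        ref_dose_mg=7.5,
        blrm_sigmas=(2.0, 1.0),
        dose_grids={"daily": [2.5, 5.0, 7.5, 10.0, 12.5, 15.0],
                    "q48h": [2.5, 5.0, 7.5, 10.0, 12.5, 15.0]},
        dose_intervals={"daily": 24.0, "q48h": 48.0},
    ),
}
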