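"""Run configuration with physically meaningful defaults.

Defaults reflect the studied system: Michaelis-Menten oxygen uptake of
r_max = 0.026 mg/l/s and K_M = 0.11 mg/l determined for the same strain
and conditions, medium oxygen diffusivity 2,800 um^2/s, and Sh = 2 for a
sphere in quiescent liquid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .pellet_model import MMKinetics
from .profile_fitting import FitOptions

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    r_max: float = 0.026          # mg O2 / l / s
    K_M: float = 0.11             # mg O2 / l
    d_medium: float = 2800.0      # um^2 / s
    sherwood: float = 2.0
    d_eff_init: float = 1000.0    # um^2 / s
    d_eff_bounds: tuple[float, float] = (100.0, 5000.0)
    smoothing_lam: float | None = None   # None -> generalized cross-validation
    seed: int = 0
    output_dir: str = "pelletox_out"

    def __post_init__(self) -> None:
        for name in ("r_max", "K_M", "d_medium", "sherwood", "d_eff_init"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.d_eff_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid d_eff_bounds {self.d_eff_bounds}")

    @property
    def kinetics(self) -> MMKinetics:
        return MMKinetics(self.r_max, self.K_M)

    @property
    def fit_options(self) -> FitOptions:
        return FitOptions(d_eff_init=self.d_eff_init, d_eff_bounds=tuple(self.d_eff_bounds))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        if "d_eff_bounds" in data:
            data["d_eff_bounds"] = tuple(data["d_eff_bounds"])
        return cls(**data)

    @property
    def hash(self) -> str:
        """Short digest identifying this configuration in logs."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
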