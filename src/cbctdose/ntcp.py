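"""Acute coronary event (ACE) risk from mean heart dose (MHD).

The model interpolates between two monotone linear-in-MHD risk curves:
``risk_min`` for the lowest-risk age bracket (> 70 years at treatment, least
remaining lifetime at risk) and ``risk_max`` for the highest-risk bracket
(< 40 years).  Each curve is ``baseline * (1 + slope * MHD)`` with the
relative slope defaulting to the published 0.074 per Gy excess-rate figure
for cardiac events after breast radiotherapy; the age-bracket baselines are
configurable defaults, not values asserted from any specific cohort.  Only
the mean heart dose enters the risk number; D1/D2 heart deviations are
reported elsewhere but do not feed this model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ACEModel", "ace_risk", "ace_delta"]


@dataclass(frozen=True)
class ACEModel:
    """Two-bracket linear ACE risk model, interpolated by a weight in [0, 1]."""

    baseline_min: float = 1.0  # % cumulative ACE risk at 0 Gy, > 70 y bracket
    baseline_max: float = 10.0  # % at 0 Gy, < 40 y bracket
    slope_per_gy: float = 0.074  # relative excess risk per Gy of MHD

    def __post_init__(self) -> None:
        if not (0 <= self.baseline_min <= self.baseline_max <= 100):
            raise ValueError("need 0 <= baseline_min <= baseline_max <= 100")
        if self.slope_per_gy < 0:
            raise ValueError("risk must be non-decreasing in MHD")

    def risk_min(self, mhd: float) -> float:
        return self.baseline_min * (1.0 + self.slope_per_gy * mhd)

    def risk_max(self, mhd: float) -> float:
        return self.baseline_max * (1.0 + self.slope_per_gy * mhd)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_min": self.baseline_min,
                "baseline_max": self.baseline_max,
                "slope_per_gy": self.slope_per_gy,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ACEModel":
        return cls(**json.loads(text))


def ace_risk(mhd: float, model: ACEModel | None = None, w: float = 0.5) -> float:
    """ACE risk (%) at a mean heart dose, interpolating between age brackets.

    ``w = 0`` returns exactly the minimum-risk (> 70 y) curve, ``w = 1`` the
    maximum-risk (< 40 y) curve; the result is clamped to [0, 100] %.
    """
    if mhd < 0:
        raise ValueError("mean heart dose must be >= 0")
    if not 0.0 <= w <= 1.0:
        raise ValueError("interpolation weight must be in [0, 1]")
    model = model or ACEModel()
    risk = (1.0 - w) * model.risk_min(mhd) + w * model.risk_max(mhd)
    return float(np.clip(risk, 0.0, 100.0))


def ace_delta(
    mhd_a: float, mhd_b: float, model: ACEModel | None = None, w: float = 0.5
) -> float:
    """Risk difference (%) between two mean heart doses: risk(b) - risk(a)."""
    if mhd_a < 0 or mhd_b < 0:
        raise ValueError("mean heart doses must be >= 0")
    return ace_risk(mhd_b, model, w) - ace_risk(mhd_a, model, w)
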