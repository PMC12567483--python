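"""Six-attribute multiparameter-optimization (MPO) desirability scoring.

The score is ``D = sum_k w_k * T_k(x_k)`` over the six attributes
{logP, logD7.4, MW, TPSA, HBD, pKa(basic)}, where each ``T_k`` is a
piecewise-linear desirability in [0, 1]. With unit weights D spans
0..6; a compound with every attribute inside its full-desirability
threshold scores 6.0.

Upper-bounded attributes use a monotone ramp: T = 1 at or below the
threshold, 0 at or beyond the zero-desirability limit, linear between.
TPSA is a hump: desirability ramps up between a low pair of breakpoints
and back down between a high pair (polarity can be both too low and too
high for oral absorption).

Two configurations ship:

* :data:`DEFAULT_CONFIG` — thresholds logP <= 3, logD7.4 <= 2,
  MW <= 360, TPSA 40-90, HBD <= 1, pKa <= 8, with generic zero limits
  (logP 5, logD 4, MW 500, HBD 3.5, pKa 10, TPSA 20/120).
* :data:`CALIBRATED_CONFIG` — same thresholds with zero limits
  MW 450, logD7.4 6.5, HBD 3.0, calibrated so that the reference
  descriptor rows shipped with this package reproduce the literature
  scores 5.5 (sitagliptin), 5.3 (LASSBio-2129) and 4.4 (LASSBio-2125)
  at one-decimal reporting precision (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .chemstruct import DescriptorSet

__all__ = [
    "ATTRIBUTES",
    "Ramp",
    "Hump",
    "MpoConfig",
    "MpoResult",
    "DEFAULT_CONFIG",
    "CALIBRATED_CONFIG",
    "desirability",
    "mpo_score",
    "radar_coordinates",
]

#: Fixed attribute order (N = 6).
ATTRIBUTES = ("logp", "logd74", "mw", "tpsa", "hbd", "pka_basic")


@dataclass(frozen=True)
class Ramp:
    """Upper-bounded desirability: 1 at/below ``threshold``, 0 at/beyond
    ``zero_limit``, linear between."""

    threshold: float
    zero_limit: float

    def __post_init__(self) -> None:
        if not self.zero_limit > self.threshold:
            raise ValueError("zero_limit must exceed threshold")

    def __call__(self, x: float) -> float:
        if x <= self.threshold:
            return 1.0
        if x >= self.zero_limit:
            return 0.0
        return (self.zero_limit - x) / (self.zero_limit - self.threshold)


@dataclass(frozen=True)
class Hump:
    """Band desirability: 0 outside [zero_low, zero_high], 1 inside
    [full_low, full_high], linear on the shoulders."""

    zero_low: float
    full_low: float
    full_high: float
    zero_high: float

    def __post_init__(self) -> None:
        pts = (self.zero_low, self.full_low, self.full_high, self.zero_high)
        if not all(a < b for a, b in zip(pts, pts[1:])):
            raise ValueError(f"hump breakpoints must ascend, got {pts}")

    def __call__(self, x: float) -> float:
        if x <= self.zero_low or x >= self.zero_high:
            return 0.0
        if self.full_low <= x <= self.full_high:
            return 1.0
        if x < self.full_low:
            return (x - self.zero_low) / (self.full_low - self.zero_low)
        return (self.zero_high - x) / (self.zero_high - self.full_high)


@dataclass(frozen=True)
class MpoConfig:
    """Per-attribute desirability shapes and weights (default unit)."""

    shapes: Mapping[str, Ramp | Hump]
    weights: Mapping[str, float] = dc_field(
        default_factory=lambda: {a: 1.0 for a in ATTRIBUTES}
    )

    def __post_init__(self) -> None:
        missing = set(ATTRIBUTES) - set(self.shapes)
        if missing:
            raise ValueError(f"config missing attribute(s): {sorted(missing)}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")

    @property
    def max_score(self) -> float:
        return sum(self.weights[a] for a in ATTRIBUTES)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MpoConfig":
        raw = yaml.safe_load(Path(path).read_text())
        shapes: dict[str, Ramp | Hump] = {}
        for attr, spec in raw["shapes"].items():
            shapes[attr] = (
                Hump(**spec) if "full_low" in spec else Ramp(**spec)
            )
        return cls(shapes=shapes, weights=raw.get(
            "weights", {a: 1.0 for a in ATTRIBUTES}))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "shapes": {a: vars(s).copy() for a, s in self.shapes.items()},
            "weights": dict(self.weights),
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _make_config(mw_zero: float, logd_zero: float, hbd_zero: float) -> MpoConfig:
    return MpoConfig(
        shapes={
            "logp": Ramp(3.0, 5.0),
            "logd74": Ramp(2.0, logd_zero),
            "mw": Ramp(360.0, mw_zero),
            "tpsa": Hump(20.0, 40.0, 90.0, 120.0),
            "hbd": Ramp(1.0, hbd_zero),
            "pka_basic": Ramp(8.0, 10.0),
        }
    )


DEFAULT_CONFIG = _make_config(mw_zero=500.0, logd_zero=4.0, hbd_zero=3.5)
CALIBRATED_CONFIG = _make_config(mw_zero=450.0, logd_zero=6.5, hbd_zero=3.0)


@dataclass
class MpoResult:
    """Per-attribute desirabilities, total score and violations."""

    compound_id: str
    values: dict[str, float]
    desirabilities: dict[str, float]
    weights: dict[str, float]
    score: float
    violations: tuple[str, ...]

    @property
    def rounded_score(self) -> float:
        """Score at one-decimal reporting precision."""
        return round(self.score, 1)


def desirability(attribute: str, value: float, cfg: MpoConfig = DEFAULT_CONFIG) -> float:
    """Desirability T(value) in [0, 1] for one attribute."""
    if attribute not in cfg.shapes:
        raise KeyError(
            f"unknown attribute {attribute!r}; configured: {sorted(cfg.shapes)}"
        )
    if not math.isfinite(value):
        raise ValueError(f"{attribute} value must be finite, got {value}")
    return cfg.shapes[attribute](float(value))


def mpo_score(
    descr: DescriptorSet | Mapping[str, float],
    cfg: MpoConfig = DEFAULT_CONFIG,
) -> MpoResult:
    """Score one compound: ``D = sum_k w_k * T_k(x_k)``.

    Every one of the six attributes must be present (computed or
    supplied); a missing attribute is an error, never imputed.
    """
    if isinstance(descr, DescriptorSet):
        cid = descr.compound_id
        raw = {a: getattr(descr, a) for a in ATTRIBUTES}
    else:
        cid = str(descr.get("compound_id", "unnamed"))
        raw = {a: descr.get(a) for a in ATTRIBUTES}
    missing = [a for a, v in raw.items()
               if v is None or (isinstance(v, float) and math.isnan(v))]
    if missing:
        raise ValueError(f"{cid}: missing MPO attribute(s): {missing}")
    values = {a: float(raw[a]) for a in ATTRIBUTES}
    tk = {a: desirability(a, values[a], cfg) for a in ATTRIBUTES}
    weights = {a: float(cfg.weights[a]) for a in ATTRIBUTES}
    score = sum(weights[a] * tk[a] for a in ATTRIBUTES)
    violations = tuple(a for a in ATTRIBUTES if tk[a] < 1.0)
    return MpoResult(
        compound_id=cid, values=values, desirabilities=tk,
        weights=weights, score=score, violations=violations,
    )


def radar_coordinates(result: MpoResult) -> np.ndarray:
    """Radar-plot polygon for one scored compound.

    Returns a (6, 2) array of (x, y) vertices in fixed attribute order,
    each at radius = that attribute's desirability (the value normalized
    to its configured span, clamped to [0, 1]) on evenly spaced spokes.
    """
    radii = np.array([result.desirabilities[a] for a in ATTRIBUTES])
    angles = 2.0 * np.pi * np.arange(len(ATTRIBUTES)) / len(ATTRIBUTES)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
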