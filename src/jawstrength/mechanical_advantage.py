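"""Jaw lever mechanical advantage.

The lower jaw is modelled as a third-class lever: the articulation (jaw
hinge) is the fulcrum, each muscle group pulls along its line of action at
its insertion site, and the load is the food item at the bite point (apex of
the 10th tooth, a little over one third of the way along the tooth row).

* in-lever  = moment arm of a muscle about the hinge: the perpendicular
  distance from the hinge to the muscle's line of action, measured in a 2D
  projection plane (lateral by default, mirroring a screenshot-based
  measurement protocol; the lingual plane is available per muscle);
* out-lever = hinge-to-bite-point distance in that plane;
* MA        = in-lever / out-lever (dimensionless).

Total jaw MA weights each muscle group's MA by the proportion of bite force
that group contributes at a 35 degree gape — combined external adductor +
adductor posterior 48.1%, pseudotemporalis 31.6%, and the pterygoideus
resultant modelled half external / half internal (10.2% each).  "Adductor
MA" is the combined adductor's MA alone.

The literal hinge-to-insertion Euclidean distance (rather than the moment
arm) is available via ``in_lever_mode='insertion_distance'`` for comparison
with protocols that measured it that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_MUSCLE_WEIGHTS,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

__all__ = [
    "MuscleModel",
    "LeverSet",
    "measure_levers",
    "weighted_ma",
    "adductor_ma",
    "read_lever_table",
    "levers_from_table",
]

MUSCLE_NAMES = tuple(DEFAULT_MUSCLE_WEIGHTS)

#: 2D projection planes in the canonical orientation (axis index pairs)
PLANES = {"lateral": (0, 1), "lingual": (0, 2)}


@dataclass(frozen=True)
class MuscleModel:
    """One muscle group: insertion point, line of action, force proportion."""

    name: str
    insertion: np.ndarray  # 3D point, mm
    line_of_action: np.ndarray  # unit direction
    force_proportion: float
    plane: str = "lateral"

    def __post_init__(self) -> None:
        if self.name not in MUSCLE_NAMES:
            raise ValidationError(f"unknown muscle group {self.name!r}")
        ins = np.asarray(self.insertion, dtype=float)
        d = np.asarray(self.line_of_action, dtype=float)
        n = np.linalg.norm(d)
        if n <= 0:
            raise ValidationError(f"{self.name}: zero line of action")
        object.__setattr__(self, "insertion", ins)
        object.__setattr__(self, "line_of_action", d / n)
        if not (0 < self.force_proportion <= 1):
            raise ValidationError(f"{self.name}: force proportion out of (0, 1]")
        if self.plane not in PLANES:
            raise ValidationError(f"{self.name}: unknown plane {self.plane!r}")


def default_muscles(
    insertions: dict[str, np.ndarray],
    lines: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    planes: dict[str, str] | None = None,
) -> list[MuscleModel]:
    """Build the four-muscle model with the default force proportions."""
    weights = weights or DEFAULT_MUSCLE_WEIGHTS
    total = sum(weights.values())
    if abs(total - 1.0) > 0.01:
        raise ValidationError(f"muscle proportions must sum to 1, got {total:.4f}")
    planes = planes or {}
    out = []
    for name in MUSCLE_NAMES:
        if name not in insertions or name not in lines:
            raise ValidationError(f"missing geometry for muscle {name!r}")
        out.append(
            MuscleModel(
                name,
                insertions[name],
                lines[name],
                weights[name],
                planes.get(name, "lingual" if name == "pterygoideus_internal" else "lateral"),
            )
        )
    return out


@dataclass
class LeverSet:
    """In-/out-levers and MA per muscle group for one jaw geometry."""

    hinge: np.ndarray
    bite_point: np.ndarray
    in_levers: dict[str, float] = field(default_factory=dict)
    out_levers: dict[str, float] = field(default_factory=dict)

    def ma(self, muscle: str) -> float:
        if muscle not in self.in_levers:
            raise ValidationError(f"no levers measured for muscle {muscle!r}")
        return self.in_levers[muscle] / self.out_levers[muscle]


def _project(p: np.ndarray, plane: str) -> np.ndarray:
    i, j = PLANES[plane]
    p = np.asarray(p, dtype=float)
    return p[..., [i, j]]


def measure_levers(
    hinge: np.ndarray,
    bite_point: np.ndarray,
    muscles: list[MuscleModel],
    in_lever_mode: str = "moment_arm",
) -> LeverSet:
    """Measure in- and out-levers for each muscle in its projection plane.

    ``in_lever_mode='moment_arm'`` (default) takes the perpendicular
    distance from the hinge to the muscle's line of action;
    ``'insertion_distance'`` takes the hinge-to-insertion distance.
    The out-lever is the hinge-to-bite-point distance in the same plane and
    is identical across muscles sharing a plane.
    """
    if in_lever_mode not in ("moment_arm", "insertion_distance"):
        raise ValidationError(f"unknown in_lever_mode {in_lever_mode!r}")
    levers = LeverSet(np.asarray(hinge, float), np.asarray(bite_point, float))
    for m in muscles:
        h2 = _project(hinge, m.plane)
        b2 = _project(bite_point, m.plane)
        i2 = _project(m.insertion, m.plane)
        d2 = _project(m.line_of_action + np.zeros(3), m.plane)
        nd = np.linalg.norm(d2)
        out_lever = float(np.linalg.norm(b2 - h2))
        if out_lever <= 0:
            raise DegenerateInputError("bite point coincides with the hinge")
        if in_lever_mode == "insertion_distance":
            in_lever = float(np.linalg.norm(i2 - h2))
        else:
            if nd <= 1e-12:
                raise DegenerateInputError(
                    f"{m.name}: line of action is normal to plane {m.plane!r}"
                )
            u = d2 / nd
            rel = h2 - i2
            perp = rel - (rel @ u) * u
            in_lever = float(np.linalg.norm(perp))
        if in_lever <= 1e-12:
            raise DegenerateInputError(
                f"{m.name}: line of action passes through the hinge "
                "(zero in-lever)"
            )
        levers.in_levers[m.name] = in_lever
        levers.out_levers[m.name] = out_lever
    return levers


def weighted_ma(levers: LeverSet, weights: dict[str, float] | None = None) -> float:
    """Total jaw MA: sum of per-muscle MA weighted by force proportion."""
    weights = weights or DEFAULT_MUSCLE_WEIGHTS
    total = 0.0
    for name, w in weights.items():
        if name not in levers.in_levers:
            raise ValidationError(f"levers missing for muscle {name!r}")
        total += w * levers.ma(name)
    return total


def adductor_ma(levers: LeverSet) -> float:
    """MA of the combined adductor group alone."""
    return levers.ma("adductor_combined")


# ---------------------------------------------------------------------------
# Lever tables (per-population pre-measured levers)
# ---------------------------------------------------------------------------


def read_lever_table(path: str | Path) -> pd.DataFrame:
    """Read a per-population lever CSV: population, muscle, in_lever, out_lever."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"lever table not found: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("population", "muscle", "in_lever", "out_lever"):
        if col not in df.columns:
            raise FormatError(f"lever table {path} missing column {col!r}")
    if (df["in_lever"] <= 0).any() or (df["out_lever"] <= 0).any():
        raise ValidationError(f"lever table {path}: levers must be positive")
    return df


def levers_from_table(df: pd.DataFrame, population: str) -> LeverSet:
    """Build a LeverSet from a pre-measured lever table row group."""
    sub = df[df["population"] == population]
    if sub.empty:
        raise ValidationError(f"population {population!r} not in lever table")
    levers = LeverSet(np.zeros(3), np.zeros(3))
    for _, row in sub.iterrows():
        levers.in_levers[str(row["muscle"])] = float(row["in_lever"])
        levers.out_levers[str(row["muscle"])] = float(row["out_lever"])
    return levers
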