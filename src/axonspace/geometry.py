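"""Stimulus-position geometries for free-field speaker/LED arrays.

Positions live on a small spherical section and are indexed by azimuth and
elevation in degrees. The sign convention follows the recording hemisphere:
negative azimuths are ipsilateral to the imaged (left) hemisphere, positive
azimuths contralateral; elevation 0 is head level. Distances between
positions are Euclidean in the (azimuth, elevation) degree plane, which is
exact for single-row arrays and a close approximation over the 120° x 40°
section the default array spans.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Position",
    "ArrayGeometry",
    "default_array",
    "motorized_arm_array",
    "angular_distance",
    "chance_error",
    "virtual_isotropic_arrays",
]


@dataclass(frozen=True)
class Position:
    """A stimulus location in degrees (azimuth, elevation)."""

    azimuth: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -180.0 <= self.azimuth <= 180.0:
            raise ValueError(f"azimuth {self.azimuth} outside [-180, 180]")
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")


@dataclass(frozen=True)
class ArrayGeometry:
    """A rectangular grid of stimulus positions.

    ``positions`` enumerates the grid row-major with elevation as the outer
    axis, so position index ``i`` maps to
    ``(azimuths[i % n_az], elevations[i // n_az])``.
    """

    azimuths: tuple[float, ...]
    elevations: tuple[float, ...]

    def __post_init__(self) -> None:
        az = np.asarray(self.azimuths, dtype=float)
        el = np.asarray(self.elevations, dtype=float)
        if az.size == 0 or el.size == 0:
            raise ValueError("geometry must have at least one azimuth and elevation")
        if az.size > 1 and not np.all(np.diff(az) > 0):
            raise ValueError("azimuths must be strictly increasing")
        if el.size > 1 and not np.all(np.diff(el) > 0):
            raise ValueError("elevations must be strictly increasing")
        object.__setattr__(self, "azimuths", tuple(float(a) for a in az))
        object.__setattr__(self, "elevations", tuple(float(e) for e in el))

    @property
    def positions(self) -> list[Position]:
        return [
            Position(a, e)
            for e, a in itertools.product(self.elevations, self.azimuths)
        ]

    @property
    def n_positions(self) -> int:
        return len(self.azimuths) * len(self.elevations)

    def position_array(self) -> np.ndarray:
        """(n_positions, 2) array of (azimuth, elevation)."""
        el, az = np.meshgrid(self.elevations, self.azimuths, indexing="ij")
        return np.column_stack([az.ravel(), el.ravel()])

    def index_of(self, position: Position) -> int:
        try:
            ia = self.azimuths.index(position.azimuth)
            ie = self.elevations.index(position.elevation)
        except ValueError as err:
            raise KeyError(f"{position} not on this geometry") from err
        return ie * len(self.azimuths) + ia

    def to_json(self) -> str:
        return json.dumps(
            {"azimuths": list(self.azimuths), "elevations": list(self.elevations)}
        )

    @classmethod
    def from_json(cls, payload: str) -> "ArrayGeometry":
        d = json.loads(payload)
        return cls(tuple(d["azimuths"]), tuple(d["elevations"]))


def default_array() -> ArrayGeometry:
    """The 39-position speaker/LED array: 13 azimuths x 3 elevations.

    Azimuths run from −20° (ipsilateral) to +100° (contralateral) in 10°
    steps; elevations are −20°, 0°, +20°.
    """
    return ArrayGeometry(
        azimuths=tuple(float(a) for a in range(-20, 101, 10)),
        elevations=(-20.0, 0.0, 20.0),
    )


_ARM_PLANS = {
    "published": tuple(
        float(a) for a in list(range(-90, -29, 20)) + list(range(-20, 101, 10))
    ),
}


def motorized_arm_array(step_plan: str = "published") -> ArrayGeometry:
    """Single-elevation geometry of the motorized-speaker arm.

    The published plan covers −90° to −30° in 20° steps and −20° to +100°
    in 10° steps (17 azimuths), all at elevation 0.
    """
    try:
        azimuths = _ARM_PLANS[step_plan]
    except KeyError as err:
        raise ValueError(
            f"unknown step plan {step_plan!r}; known: {sorted(_ARM_PLANS)}"
        ) from err
    return ArrayGeometry(azimuths=azimuths, elevations=(0.0,))


def angular_distance(a: Position, b: Position) -> float:
    """Euclidean distance between two positions in the degree plane."""
    return float(np.hypot(a.azimuth - b.azimuth, a.elevation - b.elevation))


def chance_error(geometry: ArrayGeometry) -> float:
    """Expected decoding error when true and decoded positions are both
    uniform and independent on the grid.

    Computed by exact enumeration over all ordered position pairs
    (including identical pairs, which contribute zero error).
    """
    pts = geometry.position_array()
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.mean(np.hypot(diff[..., 0], diff[..., 1])))


def virtual_isotropic_arrays(geometry: ArrayGeometry) -> list[ArrayGeometry]:
    """Downsample the azimuth axis into every 40°-wide, 20°-step sub-array.

    For a 10°-spaced azimuth axis this takes azimuth indices (i, i+2, i+4)
    for every valid i and crosses them with all elevations, producing
    isotropic 3 x 3 sub-grids (40° x 40° for the default array). Used to
    compare azimuth and elevation modulation on an equal footing.
    """
    az = np.asarray(geometry.azimuths)
    if az.size < 5 or not np.allclose(np.diff(az), 10.0):
        raise ValueError("virtual arrays require a 10°-spaced azimuth axis with >= 5 positions")
    out = []
    for i in range(az.size - 4):
        out.append(
            ArrayGeometry(
                azimuths=(az[i], az[i + 2], az[i + 4]),
                elevations=geometry.elevations,
            )
        )
    return out
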