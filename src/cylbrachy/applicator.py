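"""Single-channel vaginal cylinder geometry.

Coordinate convention: the applicator axis is z, the dome center sits at the
origin, and the apex pole points toward +z (at z = dome_radius).  The
cylindrical body extends toward negative z.  Right-handed frame, cm units.

The model builds two things: the dwell positions of the stepping source along
the central channel (fixed 5 mm step), and the six reference lines used for
optimization and evaluation — left, right and apex lines on the applicator
surface, plus the same three lines 5 mm deeper into tissue.  The lines live
in the sagittal (y = 0) plane; each surface point is paired one-to-one with a
depth point 5 mm farther along the outward surface normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .source_model import DosePoint, DwellPosition

STANDARD_DIAMETERS = (2.5, 3.0, 3.5)
DWELL_STEP_CM = 0.5
DEPTH_CM = 0.5  # evaluation depth below the applicator surface


@dataclass(frozen=True)
class CylinderApplicator:
    """Geometry of one single-channel cylinder.

    Parameters
    ----------
    diameter : float
        Outer diameter in cm; 2.5/3.0/3.5 are the standard sizes (other
        values are allowed with a warning).
    dome_radius : float, optional
        Radius of the hemispherical dome, default diameter/2.
    tip_offset : float
        Distance from the apex surface to the first dwell center, cm.
    treatment_length : float
        Active dwell span along the axis, cm.
    dwell_step : float
        Source step size, fixed at 0.5 cm; overriding requires
        ``allow_nonstandard_step=True``.
    """

    diameter: float
    dome_radius: float | None = None
    tip_offset: float = 0.6
    treatment_length: float = 4.0
    dwell_step: float = DWELL_STEP_CM
    allow_nonstandard_step: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.diameter not in STANDARD_DIAMETERS:
            warnings.warn(
                f"non-standard cylinder diameter {self.diameter} cm "
                f"(standard sizes: {STANDARD_DIAMETERS})",
                stacklevel=2,
            )
        if self.dome_radius is None:
            object.__setattr__(self, "dome_radius", self.diameter / 2.0)
        if self.dome_radius > self.diameter / 2.0 + 1e-9:
            raise ValueError("dome_radius cannot exceed the cylinder radius")
        if abs(self.dwell_step - DWELL_STEP_CM) > 1e-12 and not self.allow_nonstandard_step:
            raise ValueError(
                "dwell_step is fixed at 0.5 cm; pass allow_nonstandard_step=True to override"
            )
        if self.treatment_length < self.dwell_step:
            raise ValueError("treatment_length must be at least one dwell step")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def apex_z(self) -> float:
        """z of the apex pole on the surface."""
        return self.dome_radius


def generate_dwell_positions(app: CylinderApplicator) -> list[DwellPosition]:
    """Dwell centers on the central axis, first at ``tip_offset`` below the
    apex surface, stepping 5 mm toward the cylinder base.

    Returns floor(treatment_length/step) + 1 positions.
    """
    n = int(np.floor(app.treatment_length / app.dwell_step + 1e-9)) + 1
    z0 = app.apex_z - app.tip_offset
    axis = np.array([0.0, 0.0, 1.0])
    return [
        DwellPosition(index=i, position=np.array([0.0, 0.0, z0 - i * app.dwell_step]),
                      orientation=axis)
        for i in range(n)
    ]


@dataclass(frozen=True)
class ReferencePointSet:
    """The six optimization/evaluation lines as tagged dose points.

    Surface and depth points are stored in matched order: ``points[i]`` with
    site ``surface`` pairs with the point at the same (line_tag, on-line
    index) with site ``depth5mm``, 5 mm farther along the outward normal.
    """

    points: tuple[DosePoint, ...]
    spacing: float
    apex_angular_samples: int

    def select(self, site_tag: str | None = None, line_tag: str | None = None) -> list[DosePoint]:
        return [
            p for p in self.points
            if (site_tag is None or p.site_tag == site_tag)
            and (line_tag is None or p.line_tag == line_tag)
        ]

    def positions(self, site_tag: str | None = None, line_tag: str | None = None) -> np.ndarray:
        return np.asarray([p.position for p in self.select(site_tag, line_tag)]).reshape(-1, 3)

    def surface_depth_pairs(self) -> Iterator[tuple[DosePoint, DosePoint]]:
        """Yield (surface point, matched 5 mm-depth point) pairs."""
        surf = self.select("surface")
        deep = self.select("depth5mm")
        assert len(surf) == len(deep)
        yield from zip(surf, deep)

    def to_frame(self) -> pd.DataFrame:
        pos = np.asarray([p.position for p in self.points])
        return pd.DataFrame(
            {
                "site_tag": [p.site_tag for p in self.points],
                "line_tag": [p.line_tag for p in self.points],
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Geometry dump for audit/plotting."""
        self.to_frame().to_csv(path, index=False)


def _line_points(app: CylinderApplicator, spacing: float, offset: float,
                 side: float) -> np.ndarray:
    """Points of one straight line at radial distance radius+offset.

    The line runs from the dome junction (z = 0) down to the z of the most
    distal dwell, so the reference points cover exactly the mucosa adjacent
    to the active dwell span (points beyond the last dwell would sit in the
    unavoidable longitudinal falloff and poison the optimization targets).
    """
    z_last = app.apex_z - app.tip_offset - app.treatment_length
    extent = max(-z_last, spacing)
    n = int(np.floor(extent / spacing + 1e-9)) + 1
    z = -np.arange(n) * spacing
    x = np.full(n, side * (app.radius + offset))
    return np.column_stack([x, np.zeros(n), z])


def _arc_points(app: CylinderApplicator, apex_samples: int, offset: float,
                half: str) -> np.ndarray:
    """Points on one half of the apex arc (junction to pole, pole excluded
    for the right half to avoid duplication is handled by the caller)."""
    rad = app.dome_radius + offset
    if half == "left":
        ang = np.linspace(-90.0, 0.0, apex_samples + 1)
    else:
        ang = np.linspace(0.0, 90.0, apex_samples + 1)
    a = np.radians(ang)
    return np.column_stack([rad * np.sin(a), np.zeros(a.size), rad * np.cos(a)])


def generate_reference_lines(app: CylinderApplicator, spacing: float = 0.25,
                             apex_samples: int = 9) -> ReferencePointSet:
    """Build the six reference lines.

    Left/right straight lines run parallel to the axis in the sagittal plane
    from the dome junction (z = 0) over the treatment length; the apex arc
    spans the dome from the left junction through the pole to the right
    junction.  Depth lines repeat the surface lines 5 mm farther along the
    outward normal (radial for straight lines, spherical-radial for the arc).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if apex_samples < 3:
        raise ValueError("apex_samples must be at least 3")
    if spacing > app.treatment_length:
        raise ValueError("spacing exceeds the treatment length")

    points: list[DosePoint] = []
    for site, offset in (("surface", 0.0), ("depth5mm", DEPTH_CM)):
        for line, side in (("left", -1.0), ("right", +1.0)):
            for pos in _line_points(app, spacing, offset, side):
                points.append(DosePoint(position=pos, site_tag=site, line_tag=line))
        # apex arc: left half (junction..pole) then right half (pole..junction),
        # pole kept once
        left_half = _arc_points(app, apex_samples, offset, "left")
        right_half = _arc_points(app, apex_samples, offset, "right")[1:]
        for pos in np.vstack([left_half, right_half]):
            points.append(DosePoint(position=pos, site_tag=site, line_tag="apex"))

    return ReferencePointSet(points=tuple(points), spacing=spacing,
                             apex_angular_samples=apex_samples)
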