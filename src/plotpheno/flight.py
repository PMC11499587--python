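"""Flight-geometry arithmetic: ground sample distance and coverage rates."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class CameraSpec:
    sensor_width_mm: float
    sensor_height_mm: float
    image_width_px: int
    image_height_px: int
    focal_mm: float
    fov_deg: Optional[float] = None  # published value takes precedence

    def __post_init__(self) -> None:
        for name in ("sensor_width_mm", "sensor_height_mm", "focal_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def field_of_view_deg(self) -> float:
        """Published FOV when given, else the diagonal FOV from the optics."""
        if self.fov_deg is not None:
            return self.fov_deg
        diag = math.hypot(self.sensor_width_mm, self.sensor_height_mm)
        return math.degrees(2.0 * math.atan(diag / (2.0 * self.focal_mm)))


#: the two cameras used in the trials, with their published FOVs
P1 = CameraSpec(
    sensor_width_mm=35.9,
    sensor_height_mm=24.0,
    image_width_px=8192,
    image_height_px=5460,
    focal_mm=35.0,
    fov_deg=63.5,
)
IXM100 = CameraSpec(
    sensor_width_mm=53.4,
    sensor_height_mm=40.0,
    image_width_px=11664,
    image_height_px=8750,
    focal_mm=80.0,
    fov_deg=30.4,
)

CAMERAS = {"p1": P1, "ixm100": IXM100}


def ground_sample_distance(cam: CameraSpec, altitude_m: float) -> float:
    """GSD in mm/pixel: pixel pitch times the altitude-to-focal ratio."""
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    pitch = cam.sensor_width_mm / cam.image_width_px
    return pitch * (altitude_m * 1000.0 / cam.focal_mm)


def coverage_rate_ratio(fov_a_deg: float, fov_b_deg: float) -> float:
    """Areal coverage-rate ratio of camera a over camera b.

    At equal altitude, speed and overlaps, the area swept per unit time
    scales with the footprint side squared, i.e. the squared tangent ratio
    of the half fields of view.
    """
    for fov in (fov_a_deg, fov_b_deg):
        if not (0 < fov < 180):
            raise ValueError("field of view must be in (0, 180) degrees")
    ta = math.tan(math.radians(fov_a_deg / 2.0))
    tb = math.tan(math.radians(fov_b_deg / 2.0))
    return (ta / tb) ** 2
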