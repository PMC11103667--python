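"""DBT acquisition geometry.

The geometry of a digital breast tomosynthesis (DBT) system is described by
the source-to-rotation-center distance ``D_SO``, the rotation-center-to-
detector distance ``D_OD``, the set of scan angles, the focal spot size and
its motion angle per pulse, and the detector / reconstruction sampling.
Coordinates: the detector lies in the plane ``z = 0``; slice heights ``z_s``
are measured upward from the detector; ``y`` is the source-motion (tube
travel) direction; the rotation center sits at ``(y=0, z=D_OD)``.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DBTGeometry", "siemens_inspiration", "load_geometry", "save_geometry"]


@dataclasses.dataclass(frozen=True)
class DBTGeometry:
    """Constants of a DBT acquisition.

    Parameters
    ----------
    D_SO : float
        Source to rotation-center distance, mm.
    D_OD : float
        Rotation-center to detector distance, mm.
    scan_angles : tuple of float
        Scan angles of the projection views, degrees, strictly increasing.
    nominal_focal_spot : float
        Nominal focal spot size (the collapsed 1D line-source length for a
        stationary source), mm.
    motion_angle_per_pulse : float
        Angle traveled by the continuously moving source during one x-ray
        pulse, degrees.  Zero models step-and-shoot acquisition.
    detector_pixel : float
        Detector cell pitch, mm.
    voxel_xy : float
        In-plane reconstruction voxel pitch, mm.
    voxel_z : float
        Slice spacing of the reconstruction, mm.
    breast_gap : float
        Gap between the detector plane and the bottom of the compressed
        breast, mm (metadata; not part of the kernel formula).
    """

    D_SO: float
    D_OD: float
    scan_angles: tuple[float, ...]
    nominal_focal_spot: float = 0.3
    motion_angle_per_pulse: float = 0.0
    detector_pixel: float = 0.085
    voxel_xy: float = 0.085
    voxel_z: float = 1.0
    breast_gap: float = 20.0

    def __post_init__(self) -> None:
        if not self.D_SO > 0:
            raise ValueError(f"D_SO must be positive, got {self.D_SO}")
        if self.D_OD < 0:
            raise ValueError(f"D_OD must be nonnegative, got {self.D_OD}")
        ang = np.asarray(self.scan_angles, dtype=float)
        if ang.size == 0:
            raise ValueError("scan_angles must be nonempty")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("scan_angles must be strictly increasing")
        if np.any(np.abs(ang) >= 90):
            raise ValueError("scan angles must satisfy |alpha| < 90 deg")
        if self.nominal_focal_spot < 0:
            raise ValueError("nominal_focal_spot must be >= 0")
        if self.motion_angle_per_pulse < 0:
            raise ValueError("motion_angle_per_pulse must be >= 0")
        for name in ("detector_pixel", "voxel_xy", "voxel_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "scan_angles", tuple(float(a) for a in ang))

    @property
    def n_views(self) -> int:
        """Number of projection views N_p."""
        return len(self.scan_angles)

    @property
    def source_detector_distance(self) -> float:
        """Distance from the central-view source position to the detector, mm."""
        return self.D_SO + self.D_OD

    def source_position(self, alpha_deg: float) -> tuple[float, float]:
        """(y, z) position of the source at scan angle ``alpha_deg``.

        The source travels on an arc of radius ``D_SO`` about the rotation
        center; positive angles move the source toward positive ``y``.
        """
        a = math.radians(alpha_deg)
        return (self.D_SO * math.sin(a), self.D_OD + self.D_SO * math.cos(a))

    def magnification(self, z_s: float, alpha_deg: float = 0.0) -> float:
        """Cone-beam magnification of a plane at height ``z_s`` (central view).

        ``M = (D_SO·cosα + D_OD) / (D_SO·cosα + D_OD − z_s)``; for the default
        central view this is ``(D_SO+D_OD)/(D_SO+D_OD−z_s)``.
        """
        ca = math.cos(math.radians(alpha_deg))
        sdd = self.D_SO * ca + self.D_OD
        if not 0 <= z_s < sdd:
            raise ValueError(f"z_s={z_s} outside [0, {sdd})")
        return sdd / (sdd - z_s)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scan_angles"] = list(d["scan_angles"])
        return d


def siemens_inspiration() -> DBTGeometry:
    """Siemens Mammomat Inspiration preset.

    25 views spanning −25° to +25°, D_SO = 600 mm, D_OD = 50 mm, 0.3 mm
    nominal focal spot with 0.18° continuous source motion per pulse,
    0.085 mm detector pixels, 20 mm detector-to-breast gap, and
    0.085 × 0.085 × 1.0 mm reconstruction voxels.
    """
    angles = tuple(np.linspace(-25.0, 25.0, 25))
    return DBTGeometry(
        D_SO=600.0,
        D_OD=50.0,
        scan_angles=angles,
        nominal_focal_spot=0.3,
        motion_angle_per_pulse=0.18,
        detector_pixel=0.085,
        voxel_xy=0.085,
        voxel_z=1.0,
        breast_gap=20.0,
    )


_PRESETS = {"siemens_inspiration": siemens_inspiration}


def load_geometry(source: str | Path | dict) -> DBTGeometry:
    """Load a geometry from a preset name, a YAML/JSON file, or a dict."""
    if isinstance(source, dict):
        return DBTGeometry(**{**source, "scan_angles": tuple(source["scan_angles"])})
    name = str(source)
    if name in _PRESETS:
        return _PRESETS[name]()
    path = Path(source)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"geometry file {path} does not contain a mapping")
    return load_geometry(cfg)


def save_geometry(geom: DBTGeometry, path: str | Path) -> None:
    """Write a geometry to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(geom.to_dict(), fh, sort_keys=False)
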