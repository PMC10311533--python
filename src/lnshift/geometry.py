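"""Pseudo-C3 axis construction and donor–metal–axis angle series.

The instantaneous pseudo-threefold axis C̃3 of the tricapped complex is the
normalized average of the unit normals of three planes: the O-donor triplet,
the axial-N (TACN) triplet and the equatorial (pyridyl) N triplet. Normals
are oriented consistently toward the N_ax hemisphere (reference vector from
the O-triplet centroid to the N_ax-triplet centroid), which reproduces the
conventional regime of ≈52° O angles and ≈39° N_ax angles. The axis is
recomputed for every frame; angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import DonorMap, Frame, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "AxisResult",
    "AngleSeries",
    "plane_unit_normal",
    "pseudo_c3_axis",
    "donor_axis_angle",
    "angle_time_series",
]

_DONOR_GROUPS = ("O", "N_ax", "N_eq")


class DegenerateGeometryError(ValueError):
    """Collinear/coincident points where a plane or axis is required."""


@dataclass
class AxisResult:
    axis: np.ndarray                  # unit 3-vector
    component_normals: np.ndarray     # 3×3, rows = O, N_ax, N_eq plane normals
    frame_index: int = 0


@dataclass
class AngleSeries:
    """Per-arm donor–metal–C̃3 angle time series (degrees) for one group."""

    group: str
    angles: np.ndarray  # (n_frames, 3), arm order follows the DonorMap
    times: np.ndarray   # fs

    def pooled(self) -> np.ndarray:
        """All arms and frames as one flat sample (Table-1-style pooling)."""
        return self.angles.ravel()

    def arm_mean(self) -> np.ndarray:
        """Per-frame mean over the three arms."""
        return self.angles.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_fs": self.times,
                "arm1_deg": self.angles[:, 0],
                "arm2_deg": self.angles[:, 1],
                "arm3_deg": self.angles[:, 2],
            }
        )


def plane_unit_normal(p1, p2, p3, orient_ref) -> np.ndarray:
    """Unit normal of the plane through three points, oriented so that
    normal·orient_ref > 0."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    area2 = np.linalg.norm(n)
    if area2 / 2.0 <= 1e-10:
        raise DegenerateGeometryError("the three points are (nearly) collinear")
    n = n / area2
    proj = float(np.dot(n, np.asarray(orient_ref, dtype=float)))
    if abs(proj) < 1e-12:
        raise DegenerateGeometryError("orientation reference orthogonal to plane normal")
    return n if proj > 0 else -n


def pseudo_c3_axis(frame: Frame, donors: DonorMap) -> AxisResult:
    """Average of the three donor-plane normals, renormalized to unit length."""
    donors.validate_against(frame.n_atoms)
    xyz = frame.coords
    o_pts = xyz[donors.o_donors]
    nax_pts = xyz[donors.n_ax]
    orient_ref = nax_pts.mean(axis=0) - o_pts.mean(axis=0)
    normals = np.empty((3, 3))
    for row, group in enumerate(_DONOR_GROUPS):
        pts = xyz[donors.donor_group(group)]
        try:
            normals[row] = plane_unit_normal(pts[0], pts[1], pts[2], orient_ref)
        except DegenerateGeometryError as err:
            raise DegenerateGeometryError(
                f"frame {frame.index}: degenerate {group} donor triplet: {err}"
            ) from err
    axis = normals.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateGeometryError(f"frame {frame.index}: component normals cancel")
    return AxisResult(axis=axis / norm, component_normals=normals, frame_index=frame.index)


def donor_axis_angle(metal, donor, axis) -> float:
    """Angle (degrees, in [0, 180]) between the metal→donor bond and the axis."""
    bond = np.asarray(donor, dtype=float) - np.asarray(metal, dtype=float)
    r = np.linalg.norm(bond)
    if r < 1e-12:
        raise DegenerateGeometryError("zero-length metal–donor vector")
    c = np.dot(bond / r, np.asarray(axis, dtype=float))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_time_series(traj: Trajectory, donors: DonorMap, group: str) -> AngleSeries:
    """Per-frame arm angles of one donor group against the frame-local C̃3.

    Arm identity (1/2/3) follows DonorMap order and is stable across frames.
    """
    idx = donors.donor_group(group)
    angles = np.empty((len(traj), 3))
    for i, frame in enumerate(traj):
        try:
            axis = pseudo_c3_axis(frame, donors).axis
            metal = frame.coords[donors.metal]
            for a, j in enumerate(idx):
                angles[i, a] = donor_axis_angle(metal, frame.coords[j], axis)
        except DegenerateGeometryError as err:
            raise DegenerateGeometryError(f"frame {frame.index}: {err}") from err
    return AngleSeries(group=group, angles=angles, times=traj.times)
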