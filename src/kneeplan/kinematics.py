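"""Tibiofemoral kinematics in the Grood-Suntay joint coordinate system.

The knee's relative motion is described by three rotations and three
translations that clinicians can read directly: flexion-extension (FE)
about a femur-fixed mediolateral axis, external-internal (EI) tibial
rotation about a tibia-fixed longitudinal axis, varus-valgus (VV) about
the mutually perpendicular floating axis, and anterior-posterior (AP),
lateral-medial (LM) and proximal-distal (PD) translations resolved along
the same non-orthogonal axis triad.

Conventions (right knee throughout; left knees are mirrored at input):

* anatomical frames have x anterior, y proximal, z lateral;
* positive pose values are anterior, lateral and proximal translations,
  and external and varus rotations;
* the FE axis is the femoral z axis, the EI axis is the tibial y axis,
  and VV is carried by the floating axis; the sequence is the intrinsic
  Z-X-Y Euler decomposition, singular at VV = +/-90 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AnatomicalFrame",
    "Pose6",
    "GimbalError",
    "compose_jcs",
    "decompose_jcs",
    "jcs_transform",
    "jcs_pose_from_transform",
    "mirror_pose",
    "pose_curve_frame",
    "POSE_CSV_COLUMNS",
]

_GIMBAL_COS_TOL = 1e-7  # cos(vv) below this is treated as gimbal lock


class GimbalError(ValueError):
    """Raised when a pose or transform sits at the VV = +/-90 deg singularity."""


@dataclass(frozen=True)
class AnatomicalFrame:
    """A body-fixed anatomical frame: origin plus orthonormal axes.

    ``axes`` stores the frame's x (anterior), y (proximal) and z (lateral)
    unit vectors as the *columns* of a 3x3 matrix expressed in a common
    world frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(origin)) or not np.all(np.isfinite(axes)):
            raise ValueError("frame contains non-finite values")
        err = np.abs(axes.T @ axes - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"frame axes not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(axes) < 0.0:
            raise ValueError("frame axes are left-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(origin=np.zeros(3), axes=np.eye(3))

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous world pose of this frame."""
        T = np.eye(4)
        T[:3, :3] = self.axes
        T[:3, 3] = self.origin
        return T


@dataclass(frozen=True)
class Pose6:
    """Grood-Suntay coordinates of the tibia relative to the femur.

    Angles in degrees, translations in mm.  Positive values: flexion (fe),
    tibial external rotation (ei), varus (vv), anterior (ap), lateral (lm)
    and proximal (pd).
    """

    fe: float = 0.0
    ei: float = 0.0
    vv: float = 0.0
    ap: float = 0.0
    lm: float = 0.0
    pd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fe", "ei", "vv", "ap", "lm", "pd"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"pose component {name} is not finite")
            object.__setattr__(self, name, v)
        for name in ("fe", "ei", "vv"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"angle {name}={v} outside (-180, 180]")

    def free_coords(self) -> np.ndarray:
        """The five quasi-statically equilibrated coordinates (ap, lm, pd, ei, vv)."""
        return np.array([self.ap, self.lm, self.pd, self.ei, self.vv])

    def with_free_coords(self, q: np.ndarray) -> "Pose6":
        ap, lm, pd, ei, vv = (float(v) for v in q)
        return replace(self, ap=ap, lm=lm, pd=pd, ei=ei, vv=vv)

    def as_array(self) -> np.ndarray:
        return np.array([self.fe, self.ei, self.vv, self.ap, self.lm, self.pd])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def jcs_transform(pose: Pose6) -> np.ndarray:
    """Relative 4x4 transform of the tibial frame in femoral-frame coordinates.

    Rotation is the intrinsic Z-X-Y sequence R = Rz(-fe) Rx(vv) Ry(-ei);
    the signs realize the clinical positive directions for a right knee
    with x anterior, y proximal, z lateral.  The translation vector is
    resolved along the non-orthogonal Grood-Suntay triad: LM along the
    femoral z axis (e1), PD along the rotated tibial y axis (e3), and AP
    along the floating axis e2 = (e3 x e1)/|e3 x e1|.
    """
    if abs(math.cos(math.radians(pose.vv))) < _GIMBAL_COS_TOL:
        raise GimbalError(f"vv={pose.vv} deg is at the floating-axis singularity")
    a = math.radians(-pose.fe)
    b = math.radians(pose.vv)
    c = math.radians(-pose.ei)
    R = _rot_z(a) @ _rot_x(b) @ _rot_y(c)
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R @ np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    d = pose.lm * e1 + pose.ap * e2 + pose.pd * e3
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = d
    return T


def jcs_pose_from_transform(T: np.ndarray, fe_hint: float | None = None) -> Pose6:
    """Inverse of :func:`jcs_transform` for relative transforms.

    ``fe_hint`` disambiguates flexion angles whose Z-X-Y decomposition is
    not unique only at the singularity; it is unused otherwise.
    """
    T = np.asarray(T, dtype=float)
    R = T[:3, :3]
    _check_rigid(R)
    sb = R[2, 1]
    sb = min(1.0, max(-1.0, sb))
    cb = math.sqrt(max(0.0, 1.0 - sb * sb))
    if cb < _GIMBAL_COS_TOL:
        raise GimbalError("transform is at the VV = +/-90 deg singularity")
    b = math.asin(sb)
    a = math.atan2(-R[0, 1], R[1, 1])
    c = math.atan2(-R[2, 0], R[2, 2])
    fe = -math.degrees(a)
    vv = math.degrees(b)
    ei = -math.degrees(c)
    # translations: solve d = lm e1 + ap e2 + pd e3 in the JCS triad
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R @ np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    basis = np.column_stack([e2, e1, e3])
    ap, lm, pd = np.linalg.solve(basis, T[:3, 3])
    return Pose6(fe=_wrap_angle(fe), ei=_wrap_angle(ei), vv=_wrap_angle(vv),
                 ap=float(ap), lm=float(lm), pd=float(pd))


def compose_jcs(pose: Pose6,
                femur_frame: AnatomicalFrame | None = None,
                tibia_frame: AnatomicalFrame | None = None) -> np.ndarray:
    """World-frame rigid transform realizing ``pose`` between the two frames.

    Points fixed in the tibia body, expressed in world coordinates at the
    reference configuration, map through the returned 4x4 matrix.  With
    coincident identity frames this is the bare JCS transform.
    """
    T_jcs = jcs_transform(pose)
    if femur_frame is None and tibia_frame is None:
        return T_jcs
    Ff = (femur_frame or AnatomicalFrame.identity()).as_matrix()
    Ft = (tibia_frame or AnatomicalFrame.identity()).as_matrix()
    return Ff @ T_jcs @ np.linalg.inv(Ft)


def decompose_jcs(T: np.ndarray,
                  femur_frame: AnatomicalFrame | None = None,
                  tibia_frame: AnatomicalFrame | None = None) -> Pose6:
    """Grood-Suntay pose of a world-frame rigid transform (inverse of compose)."""
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise ValueError(f"expected 4x4 transform, got shape {T.shape}")
    _check_rigid(T[:3, :3])
    if femur_frame is None and tibia_frame is None:
        return jcs_pose_from_transform(T)
    Ff = (femur_frame or AnatomicalFrame.identity()).as_matrix()
    Ft = (tibia_frame or AnatomicalFrame.identity()).as_matrix()
    return jcs_pose_from_transform(np.linalg.inv(Ff) @ T @ Ft)


def mirror_pose(pose: Pose6) -> Pose6:
    """Pose of the sagittally mirrored knee: lm, vv, ei flip sign."""
    return replace(pose, lm=-pose.lm, vv=-pose.vv, ei=-pose.ei)


def _check_rigid(R: np.ndarray, tol: float = 1e-6) -> None:
    if np.abs(R.T @ R - np.eye(3)).max() > tol:
        raise ValueError("rotation block is not orthonormal: transform is not rigid")
    if np.linalg.det(R) < 0.0:
        raise ValueError("rotation block has det < 0: transform is not rigid")


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


POSE_CSV_COLUMNS = ["flexion_deg", "ap_mm", "lm_mm", "pd_mm", "ei_deg", "vv_deg"]


def pose_curve_frame(flexion_deg: np.ndarray, poses: "list[Pose6]"):
    """Pose curve as a pandas DataFrame in the canonical CSV column order."""
    import pandas as pd

    rows = np.array([[f, p.ap, p.lm, p.pd, p.ei, p.vv]
                     for f, p in zip(flexion_deg, poses, strict=True)])
    return pd.DataFrame(rows, columns=POSE_CSV_COLUMNS)
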