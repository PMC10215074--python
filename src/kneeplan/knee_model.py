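"""Knee model: ligament bundles, articular contact surrogate, energies.

A :class:`KneeModel` holds everything the quasi-static simulation needs
for one knee state (pre-diseased or implanted): anatomical frames, eight
named ligament bundles modelled as straight-line nonlinear springs, a
smooth per-condyle contact surrogate, and the mass properties of the
hanging shank.

Ligaments follow the standard piecewise quadratic-toe / linear law in
engineering strain (Blankevoort-style): tension is zero when slack,
quadratic up to twice the toe-limit strain, and linear beyond, with a C1
transition.  Contact is a per-condyle femoral sphere articulating on a
dished second-order tibial profile; penetration has a closed form, and
the contact pressure law is elastic-foundation-like,
``F = K * d**exponent``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import AnatomicalFrame, Pose6, jcs_transform

__all__ = [
    "LIGAMENT_NAMES",
    "STRAIN_OBJECTIVE_NAMES",
    "LigamentBundle",
    "TibialPatch",
    "ContactSurfacePair",
    "KneeModel",
    "ligament_length",
    "ligament_strain",
    "ligament_force",
    "ligament_energy",
    "contact_force",
    "total_potential_energy",
    "generalized_gradient",
    "GRAVITY_M_S2",
]

#: canonical ligament order used in CSV exports and strain vectors
LIGAMENT_NAMES = ("ACL", "PCL", "dMCL", "sMCL", "LCL", "ALL", "OPL", "PC")
#: ligaments entering strain objectives after ACL resection (CR implant)
STRAIN_OBJECTIVE_NAMES = ("PCL", "dMCL", "sMCL", "LCL", "ALL", "OPL", "PC")

GRAVITY_M_S2 = 9.80665


@dataclass(frozen=True)
class LigamentBundle:
    """One named ligament as a straight-line nonlinear spring.

    ``origin`` lives in the femoral frame, ``insertion`` in the tibial
    frame (mm).  ``stiffness`` is the linear-region stiffness in N per
    unit strain, ``slack_length`` the zero-tension length L0 in mm, and
    ``toe_limit`` the strain at which the toe region ends (the law is
    quadratic up to 2*toe_limit).
    """

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    stiffness: float
    slack_length: float
    toe_limit: float = 0.03

    def __post_init__(self) -> None:
        if self.name not in LIGAMENT_NAMES:
            raise ValueError(f"unknown ligament name {self.name!r}")
        if self.slack_length <= 0.0:
            raise ValueError("slack_length must be > 0")
        if self.stiffness < 0.0:
            raise ValueError("stiffness must be >= 0")
        if self.toe_limit <= 0.0:
            raise ValueError("toe_limit must be > 0")
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, float).reshape(3))


@dataclass(frozen=True)
class TibialPatch:
    """Dished second-order tibial articular profile for one compartment.

    Surface height in its component frame: ``y = y0 + slope_x*x +
    curv_x*(x-x_center)**2 + curv_z*(z-z_center)**2``.  ``slope_x > 0``
    tilts the surface down posteriorly (posterior tibial slope).
    """

    y0: float
    slope_x: float
    curv_x: float
    curv_z: float
    x_center: float
    z_center: float


@dataclass(frozen=True)
class ContactSurfacePair:
    """Per-condyle femoral spheres on dished tibial patches.

    Sphere centers are in the femoral frame; patches in the tibial
    component frame, which may be rotated/translated inside the tibial
    bone frame by the implant placement.  ``stiffness`` (N/mm^exponent)
    and ``exponent`` define the penetration law per compartment.
    """

    sphere_centers: np.ndarray          # (2, 3): medial, lateral
    sphere_radius: float
    patches: tuple[TibialPatch, TibialPatch]
    stiffness: float
    exponent: float = 2.0
    tibia_component_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    tibia_component_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    working_range_mm: float = 8.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.sphere_centers, float).reshape(2, 3)
        object.__setattr__(self, "sphere_centers", centers)
        object.__setattr__(self, "tibia_component_rotation",
                           np.asarray(self.tibia_component_rotation, float).reshape(3, 3))
        object.__setattr__(self, "tibia_component_origin",
                           np.asarray(self.tibia_component_origin, float).reshape(3))
        if self.sphere_radius <= 0.0:
            raise ValueError("sphere_radius must be > 0")
        if self.stiffness < 0.0:
            raise ValueError("contact stiffness must be >= 0")
        for p in self.patches:
            if p.curv_x >= 1.0 / (2.0 * self.sphere_radius) or \
               p.curv_z >= 1.0 / (2.0 * self.sphere_radius):
                raise ValueError("patch curvature must stay below the sphere curvature "
                                 "for the penetration to be uniquely defined")


@dataclass(frozen=True)
class KneeModel:
    """Bones, frames, ligaments, contact and mass for one knee state.

    A native (pre-diseased) model carries all eight ligaments; an
    implanted cruciate-retaining model carries seven (the ACL is
    resected at surgery).  Gravity acts along ``gravity_direction`` in
    the femoral frame; the shank hangs from the knee with its center of
    mass given in the tibial frame.
    """

    femur_frame: AnatomicalFrame
    tibia_frame: AnatomicalFrame
    ligaments: tuple[LigamentBundle, ...]
    contact: ContactSurfacePair
    mass_kg: float
    com_tibia: np.ndarray
    gravity_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.mass_kg <= 0.0:
            raise ValueError("mass must be > 0")
        names = [l.name for l in self.ligaments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ligament names")
        full = set(LIGAMENT_NAMES)
        if set(names) not in (full, full - {"ACL"}):
            raise ValueError("ligament set must be the 8 named bundles, or 7 with the "
                             "ACL resected")
        object.__setattr__(self, "com_tibia", np.asarray(self.com_tibia, float).reshape(3))
        g = np.asarray(self.gravity_direction, float).reshape(3)
        n = np.linalg.norm(g)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("gravity_direction must be a unit vector")
        object.__setattr__(self, "gravity_direction", g)

    @property
    def ligament_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.ligaments)

    def ligament(self, name: str) -> LigamentBundle:
        for l in self.ligaments:
            if l.name == name:
                return l
        raise KeyError(name)

    def replace_contact(self, contact: ContactSurfacePair) -> "KneeModel":
        return replace(self, contact=contact)

    # -- serialization (JSON round-trips Python floats bit-exactly) ---------

    def to_dict(self) -> dict:
        return {
            "femur_frame": {"origin": self.femur_frame.origin.tolist(),
                            "axes": self.femur_frame.axes.tolist()},
            "tibia_frame": {"origin": self.tibia_frame.origin.tolist(),
                            "axes": self.tibia_frame.axes.tolist()},
            "ligaments": [{"name": l.name,
                           "origin": l.origin.tolist(),
                           "insertion": l.insertion.tolist(),
                           "stiffness": l.stiffness,
                           "slack_length": l.slack_length,
                           "toe_limit": l.toe_limit} for l in self.ligaments],
            "contact": {
                "sphere_centers": self.contact.sphere_centers.tolist(),
                "sphere_radius": self.contact.sphere_radius,
                "patches": [vars(p).copy() for p in self.contact.patches],
                "stiffness": self.contact.stiffness,
                "exponent": self.contact.exponent,
                "tibia_component_rotation": self.contact.tibia_component_rotation.tolist(),
                "tibia_component_origin": self.contact.tibia_component_origin.tolist(),
                "working_range_mm": self.contact.working_range_mm,
            },
            "mass_kg": self.mass_kg,
            "com_tibia": self.com_tibia.tolist(),
            "gravity_direction": self.gravity_direction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KneeModel":
        c = d["contact"]
        return cls(
            femur_frame=AnatomicalFrame(np.array(d["femur_frame"]["origin"]),
                                        np.array(d["femur_frame"]["axes"])),
            tibia_frame=AnatomicalFrame(np.array(d["tibia_frame"]["origin"]),
                                        np.array(d["tibia_frame"]["axes"])),
            ligaments=tuple(LigamentBundle(**{**l,
                                              "origin": np.array(l["origin"]),
                                              "insertion": np.array(l["insertion"])})
                            for l in d["ligaments"]),
            contact=ContactSurfacePair(
                sphere_centers=np.array(c["sphere_centers"]),
                sphere_radius=c["sphere_radius"],
                patches=tuple(TibialPatch(**p) for p in c["patches"]),
                stiffness=c["stiffness"],
                exponent=c["exponent"],
                tibia_component_rotation=np.array(c["tibia_component_rotation"]),
                tibia_component_origin=np.array(c["tibia_component_origin"]),
                working_range_mm=c["working_range_mm"],
            ),
            mass_kg=d["mass_kg"],
            com_tibia=np.array(d["com_tibia"]),
            gravity_direction=np.array(d["gravity_direction"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "KneeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# ligament mechanics
# ---------------------------------------------------------------------------

def ligament_length(bundle: LigamentBundle, pose: Pose6) -> float:
    """Straight-line origin-insertion distance (mm) at a given pose."""
    T = jcs_transform(pose)
    p = T[:3, :3] @ bundle.insertion + T[:3, 3]
    return float(np.linalg.norm(p - bundle.origin))


def ligament_strain(length: float, slack_length: float) -> float:
    """Engineering strain (length - L0)/L0; negative when slack."""
    if slack_length <= 0.0:
        raise ValueError("slack_length must be > 0")
    return (length - slack_length) / slack_length


def ligament_force(bundle: LigamentBundle, strain: float) -> float:
    """Tension (N, >= 0): zero slack, quadratic toe, linear beyond 2*toe_limit."""
    return float(_force_vec(np.asarray(strain, float), bundle.stiffness, bundle.toe_limit))


def ligament_energy(bundle: LigamentBundle, strain: float) -> float:
    """Stored elastic energy (N*mm) at the given strain."""
    return float(_energy_vec(np.asarray(strain, float), bundle.stiffness,
                             bundle.toe_limit, bundle.slack_length))


def _force_vec(eps, k, eps_l):
    eps = np.asarray(eps, float)
    toe = k * eps ** 2 / (4.0 * eps_l)
    lin = k * (eps - eps_l)
    return np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, lin))


def _energy_vec(eps, k, eps_l, L0):
    """Integral of force over length change: L0 * int f(e) de."""
    eps = np.asarray(eps, float)
    toe = k * eps ** 3 / (12.0 * eps_l)
    lin = k * ((2.0 / 3.0) * eps_l ** 2 + 0.5 * ((eps - eps_l) ** 2 - eps_l ** 2))
    return L0 * np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, lin))


# ---------------------------------------------------------------------------
# contact surrogate
# ---------------------------------------------------------------------------

def _penetration(patch: TibialPatch, radius: float, c: np.ndarray):
    """Closed-form penetration of a sphere into the dished patch.

    The sphere cap is osculated by its bottom paraboloid so the gap
    function is quadratic and separable; the minimizer is linear in the
    center coordinates.  Returns (depth, contact point (u, y, w), unit
    normal) in the component frame; depth 0 when separated.
    """
    r = radius
    # minimize G(u, w) = (c_y - r - y0) - slope*u + (u-c_u)^2/(2r) - curv_x (u-x_c)^2
    #                    + (w-c_w)^2/(2r) - curv_z (w-z_c)^2
    du = 1.0 / r - 2.0 * patch.curv_x
    dw = 1.0 / r - 2.0 * patch.curv_z
    u = (c[0] / r + patch.slope_x - 2.0 * patch.curv_x * patch.x_center) / du
    w = (c[2] / r - 2.0 * patch.curv_z * patch.z_center) / dw
    y_sphere = c[1] - r + ((u - c[0]) ** 2 + (w - c[2]) ** 2) / (2.0 * r)
    y_surf = (patch.y0 + patch.slope_x * u
              + patch.curv_x * (u - patch.x_center) ** 2
              + patch.curv_z * (w - patch.z_center) ** 2)
    gap = y_sphere - y_surf
    depth = max(0.0, -gap)
    n = np.array([-(patch.slope_x + 2.0 * patch.curv_x * (u - patch.x_center)),
                  1.0,
                  -2.0 * patch.curv_z * (w - patch.z_center)])
    n /= np.linalg.norm(n)
    return depth, np.array([u, y_surf, w]), n


def contact_force(pair: ContactSurfacePair, pose: Pose6):
    """Per-compartment contact force on the tibia at a pose.

    Returns a list of (force 3-vector on the tibia, application point),
    both expressed in the femoral frame, one entry per compartment
    (medial, lateral).  Zero force when the surfaces are separated.
    Raises ``ValueError`` when penetration exceeds the working range.
    """
    T = jcs_transform(pose)
    R, d = T[:3, :3], T[:3, 3]
    Rc = pair.tibia_component_rotation
    oc = pair.tibia_component_origin
    out = []
    for center, patch in zip(pair.sphere_centers, pair.patches):
        c_t = R.T @ (center - d)           # sphere center in tibial frame
        c = Rc.T @ (c_t - oc)              # ... in tibial component frame
        depth, point_c, n_c = _penetration(patch, pair.sphere_radius, c)
        if depth > pair.working_range_mm:
            raise ValueError(f"penetration {depth:.2f} mm outside working range")
        mag = pair.stiffness * depth ** pair.exponent
        n_f = R @ (Rc @ n_c)               # normal back to femoral frame
        p_f = R @ (Rc @ point_c + oc) + d
        out.append((-mag * n_f, p_f))      # pushes the tibia away from the femur
    return out


def _contact_energy_and_center_grads(pair: ContactSurfacePair, c: np.ndarray,
                                     patch: TibialPatch):
    """Energy K d^(p+1)/(p+1) and its gradient wrt the center (component frame)."""
    depth, point, _ = _penetration(patch, pair.sphere_radius, c)
    p = pair.exponent
    E = pair.stiffness * depth ** (p + 1.0) / (p + 1.0)
    if depth <= 0.0:
        return 0.0, np.zeros(3)
    # envelope theorem: d(gap*)/dc = dG/dc at the minimizer
    r = pair.sphere_radius
    u, _, w = point
    dG_dc = np.array([-(u - c[0]) / r, 1.0, -(w - c[2]) / r])
    dE_dc = pair.stiffness * depth ** p * (-dG_dc)   # depth = -gap
    return E, dE_dc


# ---------------------------------------------------------------------------
# total potential and generalized gradient (drives the quasi-static solve)
# ---------------------------------------------------------------------------

_FD_STEP = 1e-6  # step for transform derivatives (mm / deg)


def _transform_and_partials(pose: Pose6):
    """T(q) and dT/dq for the 5 free coordinates (ap, lm, pd, ei, vv)."""
    T0 = jcs_transform(pose)
    q0 = pose.free_coords()
    partials = []
    for j in range(5):
        qp, qm = q0.copy(), q0.copy()
        qp[j] += _FD_STEP
        qm[j] -= _FD_STEP
        Tp = jcs_transform(pose.with_free_coords(qp))
        Tm = jcs_transform(pose.with_free_coords(qm))
        partials.append((Tp - Tm) / (2.0 * _FD_STEP))
    return T0, partials


def total_potential_energy(model: KneeModel, pose: Pose6) -> float:
    """Ligament + contact + gravitational potential (N*mm) at a pose."""
    return _energy_impl(model, jcs_transform(pose))


def _energy_impl(model: KneeModel, T: np.ndarray) -> float:
    R, d = T[:3, :3], T[:3, 3]
    E = 0.0
    for lig in model.ligaments:
        p = R @ lig.insertion + d
        length = float(np.linalg.norm(p - lig.origin))
        eps = (length - lig.slack_length) / lig.slack_length
        E += float(_energy_vec(eps, lig.stiffness, lig.toe_limit, lig.slack_length))
    pair = model.contact
    Rc, oc = pair.tibia_component_rotation, pair.tibia_component_origin
    for center, patch in zip(pair.sphere_centers, pair.patches):
        c = Rc.T @ (R.T @ (center - d) - oc)
        Ec, _ = _contact_energy_and_center_grads(pair, c, patch)
        E += Ec
    Fg = model.mass_kg * GRAVITY_M_S2
    com = R @ model.com_tibia + d
    E -= Fg * float(model.gravity_direction @ com)
    return E


def generalized_gradient(model: KneeModel, pose: Pose6) -> np.ndarray:
    """Gradient of the potential wrt (ap, lm, pd, ei, vv).

    Translational components are in N; rotational components are in
    N*mm per degree (the caller rescales to its residual convention).
    The equilibrium condition is gradient = 0.
    """
    T0, partials = _transform_and_partials(pose)
    R, d = T0[:3, :3], T0[:3, 3]
    grad = np.zeros(5)

    for lig in model.ligaments:
        p = R @ lig.insertion + d
        delta = p - lig.origin
        length = float(np.linalg.norm(delta))
        eps = (length - lig.slack_length) / lig.slack_length
        f = float(_force_vec(eps, lig.stiffness, lig.toe_limit))
        if f == 0.0 or length == 0.0:
            continue
        u = delta / length
        for j, dT in enumerate(partials):
            dp = dT[:3, :3] @ lig.insertion + dT[:3, 3]
            grad[j] += f * float(u @ dp)

    pair = model.contact
    Rc, oc = pair.tibia_component_rotation, pair.tibia_component_origin
    for center, patch in zip(pair.sphere_centers, pair.patches):
        c_t = R.T @ (center - d)
        c = Rc.T @ (c_t - oc)
        _, dE_dc = _contact_energy_and_center_grads(pair, c, patch)
        if not dE_dc.any():
            continue
        for j, dT in enumerate(partials):
            dR, dd = dT[:3, :3], dT[:3, 3]
            dc_t = dR.T @ (center - d) + R.T @ (-dd)
            grad[j] += float(dE_dc @ (Rc.T @ dc_t))

    Fg = model.mass_kg * GRAVITY_M_S2
    for j, dT in enumerate(partials):
        dcom = dT[:3, :3] @ model.com_tibia + dT[:3, 3]
        grad[j] -= Fg * float(model.gravity_direction @ dcom)
    return grad
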