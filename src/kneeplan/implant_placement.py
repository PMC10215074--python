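"""Mechanical-alignment baseline and the 9-parameter implant placement.

The optimization searches over nine component position offsets relative
to a mechanically aligned (MA) implantation: six for the femoral
component (AP/LM/PD translations, FE/EI/VV rotations) and three
rotations for the tibial component (its translations are kept fixed).

Sign conventions follow the surgical-planning convention for component
offsets: positive values are posterior, medial and proximal
translations, and flexion, internal and varus rotations of the
components.  This differs from the kinematic reporting convention
(anterior/lateral/external positive); converters are applied at this
interface, never implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .knee_model import KneeModel, ContactSurfacePair, TibialPatch

__all__ = ["ImplantPlacement", "PlacementBounds", "PlacementBoundsError",
           "ma_baseline", "apply_placement", "ImplantDesign"]

PARAM_NAMES = ("fem_ap", "fem_lm", "fem_pd", "fem_fe", "fem_ei", "fem_vv",
               "tib_fe", "tib_ei", "tib_vv")


@dataclass(frozen=True)
class ImplantPlacement:
    """The 9-vector x of component offsets relative to MA.

    Translations in mm (femoral only), rotations in degrees.  Component
    convention: positive = posterior / medial / proximal translation,
    flexion / internal / varus rotation.
    """

    fem_ap: float = 0.0
    fem_lm: float = 0.0
    fem_pd: float = 0.0
    fem_fe: float = 0.0
    fem_ei: float = 0.0
    fem_vv: float = 0.0
    tib_fe: float = 0.0
    tib_ei: float = 0.0
    tib_vv: float = 0.0

    def as_array(self) -> np.ndarray:
        """Parameters in the canonical column order (femoral AP..VV, tibial FE..VV)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ImplantPlacement":
        x = np.asarray(x, dtype=float).reshape(9)
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})

    def __neg__(self) -> "ImplantPlacement":
        return ImplantPlacement.from_array(-self.as_array())

    def is_zero(self) -> bool:
        return not self.as_array().any()


@dataclass(frozen=True)
class PlacementBounds:
    """Box bounds on the placement vector, relative to MA.

    Defaults: femoral translations +/-6 mm; femoral FE +/-3 deg (kept
    narrow to avoid anterior notching of the femoral cortex), femoral
    EI/VV +/-6 deg; tibial FE/EI/VV +/-6 deg.
    """

    lower: np.ndarray = field(default_factory=lambda: np.array(
        [-6.0, -6.0, -6.0, -3.0, -6.0, -6.0, -6.0, -6.0, -6.0]))
    upper: np.ndarray = field(default_factory=lambda: np.array(
        [6.0, 6.0, 6.0, 3.0, 6.0, 6.0, 6.0, 6.0, 6.0]))

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, float).reshape(9)
        up = np.asarray(self.upper, float).reshape(9)
        if not np.all(lo < up):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def half_width(self) -> np.ndarray:
        return 0.5 * (self.upper - self.lower)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.upper + self.lower)

    def contains(self, x: ImplantPlacement, strict: bool = False) -> bool:
        v = x.as_array()
        if strict:
            return bool(np.all(v > self.lower) and np.all(v < self.upper))
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def check(self, x: ImplantPlacement) -> None:
        v = x.as_array()
        for name, val, lo, up in zip(PARAM_NAMES, v, self.lower, self.upper):
            if val < lo or val > up:
                raise PlacementBoundsError(
                    f"{name}={val:g} outside [{lo:g}, {up:g}]", name)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Map parameter space to [-1, 1]^9."""
        return (np.asarray(x, float) - self.center) / self.half_width

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return self.center + np.asarray(z, float) * self.half_width


class PlacementBoundsError(ValueError):
    def __init__(self, msg: str, parameter: str):
        super().__init__(msg)
        self.parameter = parameter


@dataclass(frozen=True)
class ImplantDesign:
    """Surrogate geometry of the cruciate-retaining implant (one size).

    Single-radius sagittal femoral profile (the condylar spheres are
    reused from the native model for congruence) on a dished insert
    with neutral slope at MA.  ``insert_curv_x/z`` are the dish
    curvatures (1/mm), ``stiffness`` the contact law coefficient.
    """

    insert_curv_x: float = 0.012
    insert_curv_z: float = 0.014
    stiffness: float = 400.0
    exponent: float = 2.0


def _rot_z(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _component_rotation(fe: float, ei: float, vv: float) -> np.ndarray:
    """Intrinsic FE -> EI -> VV rotation of a component (degrees, component signs).

    Positive FE flexes the component about the mediolateral z axis: the
    articular face tips so its posterior edge drops, which for the
    tibial component adds posterior slope.  Positive EI rotates the
    component internally and positive VV into varus, for a right knee
    with x anterior, y proximal, z lateral.
    """
    return (_rot_z(math.radians(fe))
            @ _rot_y(math.radians(ei))
            @ _rot_x(math.radians(vv)))


def _component_translation(ap: float, lm: float, pd: float) -> np.ndarray:
    """Component-convention translation -> canonical frame (x ant, y prox, z lat)."""
    return np.array([-ap, pd, -lm])


def ma_baseline(model: KneeModel, insert_thickness: float = 9.0,
                design: ImplantDesign = ImplantDesign()) -> KneeModel:
    """Implant a pre-diseased knee according to mechanical alignment (x = 0).

    Replaces the native articular surfaces with the implant surrogate:
    component axes aligned with the mechanical axes (neutral VV/EI, zero
    tibial slope), joint line restored by matching the composite
    resection and implant thickness, ACL removed (cruciate-retaining
    design; the ACL is resected at surgery), other ligaments untouched.
    """
    if insert_thickness <= 0.0:
        raise ValueError("insert thickness must be > 0")
    if "ACL" not in model.ligament_names:
        raise ValueError("model is already implanted (no ACL)")
    native = model.contact
    patches = tuple(
        TibialPatch(y0=p.y0, slope_x=0.0,
                    curv_x=design.insert_curv_x, curv_z=design.insert_curv_z,
                    x_center=0.0, z_center=p.z_center)
        for p in native.patches)
    contact = ContactSurfacePair(
        sphere_centers=native.sphere_centers.copy(),
        sphere_radius=native.sphere_radius,
        patches=patches,
        stiffness=design.stiffness,
        exponent=design.exponent,
        working_range_mm=native.working_range_mm,
    )
    ligaments = tuple(l for l in model.ligaments if l.name != "ACL")
    return replace(model, contact=contact, ligaments=ligaments)


def _component_origin(contact: ContactSurfacePair) -> np.ndarray:
    """Reference point for component rotations: center of the joint line."""
    y0 = float(np.mean([p.y0 for p in contact.patches]))
    return np.array([0.0, y0, 0.0])


def apply_placement(implanted: KneeModel, x: ImplantPlacement,
                    bounds: PlacementBounds | None = None) -> KneeModel:
    """Apply the 9-parameter offset x to an MA-implanted model.

    The femoral component surfaces are rigidly transformed by the six
    femoral parameters about the femoral component frame; the tibial
    component surfaces are rotated by the three tibial parameters about
    the tibial component frame.  Bone-attached ligament points are
    unchanged.  ``x`` must lie within bounds (default surgical bounds).
    """
    bounds = bounds if bounds is not None else PlacementBounds()
    bounds.check(x)
    if "ACL" in implanted.ligament_names:
        raise ValueError("apply_placement expects an implanted (MA baseline) model")
    contact = implanted.contact
    if x.is_zero():
        return implanted
    origin = _component_origin(contact)

    # femoral component: rotate about the component frame, then translate
    Rf = _component_rotation(x.fem_fe, x.fem_ei, x.fem_vv)
    tf = _component_translation(x.fem_ap, x.fem_lm, x.fem_pd)
    centers = (contact.sphere_centers - origin) @ Rf.T + origin + tf

    # tibial component: pure rotation about the component frame
    Rt = _component_rotation(x.tib_fe, x.tib_ei, x.tib_vv)
    # surface coords s map to the tibial frame via p = Rt (s - o) + o
    Rc = contact.tibia_component_rotation @ Rt
    oc = (contact.tibia_component_origin
          + contact.tibia_component_rotation @ (origin - Rt @ origin))

    new_contact = replace(contact, sphere_centers=centers,
                          tibia_component_rotation=Rc,
                          tibia_component_origin=oc)
    return implanted.replace_contact(new_contact)


def placement_row(x: ImplantPlacement) -> dict:
    """Placement as a flat record in the canonical table column order."""
    return {n: getattr(x, n) for n in PARAM_NAMES}
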