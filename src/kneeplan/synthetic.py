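"""Synthetic patients: knee models and hidden-truth planning scenarios.

Patient-specific knee models in the clinic come from segmented CT and
cartilage imaging; this module replaces that pipeline with a
parametric generator so the whole planning chain is testable without
any patient data.  A generated knee has the same structure the
analysis assumes: eight named ligament bundles at anatomically
plausible attachment sites (epicondyles, intercondylar walls, plateau
rims, fibular head), per-condyle articular surfaces with a posterior
tibial slope (default 5 deg, a typical pre-diseased value), anatomical
frames, and the hanging-shank mass properties.

Ligament slack lengths are calibrated from per-bundle reference
strains at the zero joint-coordinate pose at full extension, the
package's slack-length convention; ligament pretension then holds the
joint surfaces in compression, which is what couples implant position
to kinematics and strains.

``make_hidden_truth`` builds parameter-recovery scenarios: the
reference curves are simulated at a known placement x*, so the global
objective minimum is at x* by construction and optimizer acceptance is
uncontaminated by model mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .forward_sim import SimulationTrace, simulate_extension, SolverSettings
from .implant_placement import (ImplantPlacement, PlacementBounds, ma_baseline,
                                apply_placement)
from .kinematics import AnatomicalFrame
from .knee_model import (KneeModel, LigamentBundle, ContactSurfacePair,
                         TibialPatch, LIGAMENT_NAMES)

__all__ = ["PatientSpec", "Scenario", "generate_knee", "make_hidden_truth",
           "generate_cohort", "CANONICAL_ATTACHMENTS"]

# canonical right-knee attachment sites (mm): femoral frame origin at the
# mid-transepicondylar point, x anterior, y proximal, z lateral; the joint
# line sits near y = -21.  Values are representative of adult anatomy and
# kept near-isometric about the flexion axis so strains stay physiologic
# over the 60 deg arc.
CANONICAL_ATTACHMENTS: dict[str, tuple[tuple[float, float, float],
                                       tuple[float, float, float]]] = {
    #        femoral origin            tibial insertion
    "ACL":  ((-6.93, 0.90, 8.0),    (10.0, -24.0, 2.0)),
    "PCL":  ((2.64, -11.64, -8.0),  (-27.0, -25.0, -3.0)),
    "dMCL": ((-0.36, 0.25, -42.0),  (-3.0, -32.0, -33.0)),
    "sMCL": ((-1.93, 0.99, -44.0),  (4.0, -80.0, -26.0)),
    "LCL":  ((-0.53, 0.43, 44.0),   (-8.0, -50.0, 41.0)),
    "ALL":  ((0.16, 0.0, 43.0),     (19.0, -33.0, 29.0)),
    "OPL":  ((0.99, -2.52, 12.0),   (-24.0, -30.0, -14.0)),
    "PC":   ((1.92, -5.56, 0.0),    (-26.0, -30.0, 0.0)),
}

#: linear-region stiffness (N per unit strain), Blankevoort-type magnitudes
DEFAULT_STIFFNESS: dict[str, float] = {
    "ACL": 5000.0, "PCL": 9000.0, "dMCL": 2000.0, "sMCL": 2750.0,
    "LCL": 2000.0, "ALL": 1000.0, "OPL": 1500.0, "PC": 2500.0,
}

#: reference strains at the zero pose in extension (slack-length calibration)
DEFAULT_REFERENCE_STRAINS: dict[str, float] = {
    "ACL": 0.02, "PCL": -0.02, "dMCL": 0.02, "sMCL": 0.025,
    "LCL": 0.025, "ALL": 0.015, "OPL": 0.02, "PC": 0.02,
}


@dataclass(frozen=True)
class PatientSpec:
    """Generator parameters for one synthetic patient.

    ``scale`` multiplies all canonical geometry (1.0 is an average adult
    knee, condylar spacing 44 mm); ``reference_strains`` calibrate the
    slack lengths; ``attachment_jitter_mm`` is the s.d. of the random
    offset applied to every attachment point; ``tibial_slope_deg`` is
    the native posterior slope.
    """

    seed: int = 0
    scale: float = 1.0
    reference_strains: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_STRAINS))
    attachment_jitter_mm: float = 0.35
    tibial_slope_deg: float = 5.0
    condyle_offset_mm: float = 22.0
    sphere_radius_mm: float = 21.0
    joint_line_y_mm: float = -21.5
    native_curv_x: float = 0.006
    native_curv_z: float = 0.010
    contact_stiffness: float = 300.0
    shank_mass_kg: float = 4.0
    shank_com_mm: tuple = (0.0, -250.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0.0:
            raise ValueError("scale must be > 0")
        missing = set(LIGAMENT_NAMES) - set(self.reference_strains)
        if missing:
            raise ValueError(f"reference strains missing for {sorted(missing)}")
        for name, eps in self.reference_strains.items():
            if not (-0.05 < eps < 0.10):
                raise ValueError(f"reference strain for {name} outside (-0.05, 0.10)")


def generate_knee(spec: PatientSpec) -> KneeModel:
    """Deterministically generate a pre-diseased knee model from a spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.scale
    jitter = spec.attachment_jitter_mm

    ligaments = []
    for name in LIGAMENT_NAMES:
        fem, tib = CANONICAL_ATTACHMENTS[name]
        origin = s * np.array(fem) + jitter * rng.standard_normal(3)
        insertion = s * np.array(tib) + jitter * rng.standard_normal(3)
        # slack length from the reference strain at the zero pose at extension
        length0 = float(np.linalg.norm(insertion - origin))
        eps_ref = spec.reference_strains[name]
        ligaments.append(LigamentBundle(
            name=name, origin=origin, insertion=insertion,
            stiffness=DEFAULT_STIFFNESS[name],
            slack_length=length0 / (1.0 + eps_ref)))

    zc = s * spec.condyle_offset_mm
    y0 = s * spec.joint_line_y_mm
    slope = math.tan(math.radians(spec.tibial_slope_deg))
    patches = (TibialPatch(y0=y0, slope_x=slope, curv_x=spec.native_curv_x,
                           curv_z=spec.native_curv_z, x_center=0.0, z_center=-zc),
               TibialPatch(y0=y0, slope_x=slope, curv_x=spec.native_curv_x,
                           curv_z=spec.native_curv_z, x_center=0.0, z_center=zc))
    contact = ContactSurfacePair(
        sphere_centers=np.array([[0.0, 0.0, -zc], [0.0, 0.0, zc]]),
        sphere_radius=s * spec.sphere_radius_mm,
        patches=patches,
        stiffness=spec.contact_stiffness)

    return KneeModel(
        femur_frame=AnatomicalFrame.identity(),
        tibia_frame=AnatomicalFrame.identity(),
        ligaments=tuple(ligaments),
        contact=contact,
        mass_kg=spec.shank_mass_kg,
        com_tibia=s * np.array(spec.shank_com_mm),
        gravity_direction=np.array([0.0, -1.0, 0.0]))


@dataclass(frozen=True)
class Scenario:
    """A hidden-truth planning scenario for optimizer validation."""

    model: KneeModel               # pre-diseased knee
    ma_model: KneeModel            # MA-implanted baseline
    reference: SimulationTrace     # simulated at the hidden placement
    x_star: ImplantPlacement


def make_hidden_truth(spec: PatientSpec, x_star: ImplantPlacement,
                      bounds: PlacementBounds | None = None,
                      t: int = 60,
                      settings: SolverSettings = SolverSettings()) -> Scenario:
    """Scenario whose reference curves come from a known placement x*.

    By construction the objective's global minimum is at x = x_star (up
    to solver noise).  x_star must be strictly inside the bounds.
    """
    bounds = bounds if bounds is not None else PlacementBounds()
    if not bounds.contains(x_star, strict=True):
        raise ValueError("x_star must lie strictly inside the placement bounds")
    model = generate_knee(spec)
    ma = ma_baseline(model)
    reference = simulate_extension(apply_placement(ma, x_star, bounds), t=t,
                                   settings=settings)
    return Scenario(model=model, ma_model=ma, reference=reference,
                    x_star=x_star)


def generate_cohort(n: int, base_spec: PatientSpec = PatientSpec(),
                    seed: int = 0) -> list[PatientSpec]:
    """n reproducible patient specs jittered around a base spec."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    scales = 1.0 + 0.03 * rng.standard_normal(n)
    slopes = base_spec.tibial_slope_deg + rng.uniform(-1.0, 1.0, size=n)
    if n == 1:
        return [replace(base_spec, seed=int(seeds[0]))]
    return [replace(base_spec, seed=int(seeds[i]),
                    scale=base_spec.scale * float(scales[i]),
                    tibial_slope_deg=float(slopes[i]))
            for i in range(n)]
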