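"""Quasi-static simulation of the unloaded knee-extension trial.

Flexion is prescribed by a motion driver from 60 deg to 0 deg; at each
flexion angle the remaining five tibiofemoral coordinates (AP, LM, PD
translations, EI and VV rotations) settle where the generalized forces
from ligaments, articular contact and gravity balance.  Because the
trial is unloaded and slow, each step is an independent static
equilibrium: the solver minimizes the total potential energy of the
configuration and verifies the force residual afterwards.

Residual convention: the equilibrium residual is the Euclidean norm of
the five generalized forces, with the two moment components converted
to force units through a 40 mm lever arm.  A converged step must fall
below 5 N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .kinematics import Pose6, jcs_transform, POSE_CSV_COLUMNS
from .knee_model import (KneeModel, _energy_vec, _force_vec,
                         _contact_energy_and_center_grads, GRAVITY_M_S2)

__all__ = ["SolverSettings", "SimulationTrace", "solve_quasi_static",
           "simulate_extension"]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class SolverSettings:
    """Equilibrium-solver contract and numerical knobs.

    ``residual_tol_N`` is the convergence contract on the generalized
    force residual; ``lever_arm_mm`` converts moment residuals (N*mm)
    into force units for that norm.  The inner minimization is driven
    far tighter than the contract so that traces are reproducible to
    solver precision.
    """

    residual_tol_N: float = 5.0
    lever_arm_mm: float = 40.0
    max_iter: int = 200
    gtol: float = 1e-9


@dataclass(frozen=True)
class SimulationTrace:
    """Kinematics, strains and residuals sampled over the flexion arc."""

    flexion_deg: np.ndarray           # (t,), strictly decreasing 60 -> 0
    poses: tuple[Pose6, ...]          # one per sample
    strains: np.ndarray               # (t, n_ligaments), unitless
    ligament_names: tuple[str, ...]
    residuals: np.ndarray             # (t,), N
    converged: np.ndarray             # (t,), bool

    def __post_init__(self) -> None:
        t = len(self.flexion_deg)
        if not (len(self.poses) == t == self.strains.shape[0]
                == len(self.residuals) == len(self.converged)):
            raise ValueError("trace arrays have inconsistent lengths")
        if t > 1 and not np.all(np.diff(self.flexion_deg) < 0):
            raise ValueError("flexion grid must be strictly decreasing")

    @property
    def t(self) -> int:
        return len(self.flexion_deg)

    def kinematics_array(self) -> np.ndarray:
        """(t, 5) array of the free coordinates [ap, lm, pd, ei, vv]."""
        return np.array([p.free_coords() for p in self.poses])

    def kinematics_frame(self):
        import pandas as pd
        k = self.kinematics_array()
        return pd.DataFrame(
            np.column_stack([self.flexion_deg, k]), columns=POSE_CSV_COLUMNS)

    def strains_frame(self):
        """Strains in percent, one column per ligament, canonical order."""
        import pandas as pd
        df = pd.DataFrame(100.0 * self.strains, columns=list(self.ligament_names))
        df.insert(0, "flexion_deg", self.flexion_deg)
        return df

    def strain_curve(self, name: str) -> np.ndarray:
        return self.strains[:, self.ligament_names.index(name)]

    def all_converged(self) -> bool:
        return bool(self.converged.all())


def _transform_partials(fe_deg: float, q: np.ndarray):
    """JCS transform and its analytic partials wrt (ap, lm, pd, ei, vv).

    Returns (R, d, dRs, dds) where dRs/dds stack the five partial
    derivatives of the rotation block and translation (angle partials
    per degree).  Mirrors :func:`kneeplan.kinematics.jcs_transform`.
    """
    ap, lm, pd, ei, vv = q
    a = -math.radians(fe_deg)
    b = math.radians(vv)
    c = -math.radians(ei)
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    Ry = np.array([[cc, 0.0, sc], [0.0, 1.0, 0.0], [-sc, 0.0, cc]])
    dRx = np.array([[0.0, 0.0, 0.0], [0.0, -sb, -cb], [0.0, cb, -sb]])
    dRy = np.array([[-sc, 0.0, cc], [0.0, 0.0, 0.0], [-cc, 0.0, -sc]])
    RzRx = Rz @ Rx
    R = RzRx @ Ry
    dR_vv = (Rz @ dRx @ Ry) * _DEG          # d/d(vv deg)
    dR_ei = -(RzRx @ dRy) * _DEG            # c = -ei
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R[:, 1].copy()
    v = np.array([e3[1], -e3[0], 0.0])      # e3 x e1
    n = math.hypot(v[0], v[1])
    e2 = v / n
    d = lm * e1 + ap * e2 + pd * e3

    de3_vv = dR_vv[:, 1]
    de3_ei = dR_ei[:, 1]

    def de2(de3):
        dv = np.array([de3[1], -de3[0], 0.0])
        dn = (v @ dv) / n
        return dv / n - v * (dn / (n * n))

    dRs = np.zeros((5, 3, 3))
    dRs[3] = dR_ei
    dRs[4] = dR_vv
    dds = np.empty((5, 3))
    dds[0] = e2
    dds[1] = e1
    dds[2] = e3
    dds[3] = ap * de2(de3_ei) + pd * de3_ei
    dds[4] = ap * de2(de3_vv) + pd * de3_vv
    return R, d, dRs, dds


class _Mechanics:
    """Vectorized potential/gradient evaluator for one model (internal).

    Precomputes ligament attachment arrays so each evaluation is a
    handful of small matrix products; used by the equilibrium solver.
    """

    def __init__(self, model: KneeModel):
        self.model = model
        ligs = model.ligaments
        self.origins = np.array([l.origin for l in ligs])
        self.insertions = np.array([l.insertion for l in ligs])
        self.k = np.array([l.stiffness for l in ligs])
        self.L0 = np.array([l.slack_length for l in ligs])
        self.eps_l = np.array([l.toe_limit for l in ligs])
        self.Fg = model.mass_kg * GRAVITY_M_S2
        self.g_dir = model.gravity_direction
        self.com = model.com_tibia

    def strains_at(self, pose: Pose6) -> np.ndarray:
        T = jcs_transform(pose)
        p = self.insertions @ T[:3, :3].T + T[:3, 3]
        lengths = np.linalg.norm(p - self.origins, axis=1)
        return (lengths - self.L0) / self.L0

    def energy_grad(self, fe: float, q: np.ndarray):
        """(E, dE/dq) with q = (ap, lm, pd, ei, vv); E in N*mm."""
        R, d, dRs, dds = _transform_partials(fe, q)
        grad = np.zeros(5)

        # ligaments
        p = self.insertions @ R.T + d
        delta = p - self.origins
        lengths = np.sqrt((delta * delta).sum(axis=1))
        eps = (lengths - self.L0) / self.L0
        E = float(_energy_vec(eps, self.k, self.eps_l, self.L0).sum())
        f = _force_vec(eps, self.k, self.eps_l)
        active = f > 0.0
        if active.any():
            fu = (f[active] / lengths[active])[:, None] * delta[active]
            ins = self.insertions[active]
            # dp_j = ins @ dR_j.T + dd_j ; grad_j = sum_i fu_i . dp_j_i
            dp = np.einsum('ik,jlk->jil', ins, dRs) + dds[:, None, :]
            grad += np.einsum('il,jil->j', fu, dp)

        # contact
        pair = self.model.contact
        Rc, oc = pair.tibia_component_rotation, pair.tibia_component_origin
        for center, patch in zip(pair.sphere_centers, pair.patches):
            cd = center - d
            c_t = R.T @ cd
            c = Rc.T @ (c_t - oc)
            Ec, dE_dc = _contact_energy_and_center_grads(pair, c, patch)
            E += Ec
            if dE_dc.any():
                g_t = Rc @ dE_dc          # gradient wrt c_t
                for j in range(5):
                    dc_t = dRs[j].T @ cd - R.T @ dds[j]
                    grad[j] += float(g_t @ dc_t)

        # gravity
        com_w = R @ self.com + d
        E -= self.Fg * float(self.g_dir @ com_w)
        dcom = np.einsum('k,jlk->jl', self.com, dRs) + dds
        grad -= self.Fg * (dcom @ self.g_dir)
        return E, grad

    def residual_norm(self, grad: np.ndarray, lever_arm_mm: float) -> float:
        """Mixed-unit gradient -> single force residual (N)."""
        r = grad.copy()
        r[3:] = r[3:] / _DEG / lever_arm_mm   # N*mm/deg -> N*mm/rad -> N
        return float(np.linalg.norm(r))


def _fd_hessian(mech: _Mechanics, fe: float, q: np.ndarray,
                h: float = 1e-5) -> np.ndarray:
    H = np.empty((5, 5))
    for j in range(5):
        qp, qm = q.copy(), q.copy()
        qp[j] += h
        qm[j] -= h
        H[j] = (mech.energy_grad(fe, qp)[1] - mech.energy_grad(fe, qm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def _newton_equilibrate(mech: _Mechanics, fe: float, q0: np.ndarray,
                        H0: np.ndarray | None, settings: SolverSettings,
                        inner_tol_N: float = 1e-8):
    """Damped Newton on the potential gradient with a carried-over Hessian.

    Warm starts along the flexion arc make the previous step's Hessian
    an excellent preconditioner; it is refreshed by finite differences
    of the analytic gradient only when progress stalls.  Returns
    (q, residual_N, H) with the residual in the 5 N contract's units.
    """
    q = q0.copy()
    E, g = mech.energy_grad(fe, q)
    H = H0
    fresh = False
    for _ in range(settings.max_iter):
        r = mech.residual_norm(g, settings.lever_arm_mm)
        if r < inner_tol_N:
            break
        if H is None:
            H = _fd_hessian(mech, fe, q)
            fresh = True
        try:
            dq = -np.linalg.solve(H + 1e-10 * np.eye(5), g)
        except np.linalg.LinAlgError:
            dq = -g
        gdq = g @ dq
        if gdq >= 0.0:                 # not a descent direction
            if not fresh:
                H, fresh = None, False
                continue
            dq = -g / max(1.0, np.linalg.norm(g))
            gdq = g @ dq
        if -gdq < 1e-11 * max(1.0, abs(E)):
            break                      # predicted decrease below fp precision
        # backtracking line search on the energy (fp-tolerant Armijo)
        alpha, ok = 1.0, False
        for _ls in range(20):
            E_new, g_new = mech.energy_grad(fe, q + alpha * dq)
            if E_new <= E + 1e-4 * alpha * gdq + 1e-12 * max(1.0, abs(E)):
                ok = True
                break
            alpha *= 0.5
        if not ok:
            if not fresh:
                H, fresh = None, False
                continue
            break
        s = alpha * dq
        y = g_new - g
        q, E, g = q + s, E_new, g_new
        fresh = False
        # BFGS update keeps the carried Hessian current between refreshes
        sy = s @ y
        if H is not None and sy > 1e-12:
            Hs = H @ s
            H = H + np.outer(y, y) / sy - np.outer(Hs, Hs) / (s @ Hs)
    # gradient-only Newton polish: energy differences hit floating-point
    # precision long before the gradient does, so finish on the residual
    r = mech.residual_norm(g, settings.lever_arm_mm)
    if H is not None:
        for _ in range(10):
            if r < 1e-8:
                break
            try:
                dq = -np.linalg.solve(H + 1e-10 * np.eye(5), g)
            except np.linalg.LinAlgError:
                break
            g_new = mech.energy_grad(fe, q + dq)[1]
            r_new = mech.residual_norm(g_new, settings.lever_arm_mm)
            if r_new >= r:
                break
            q, g, r = q + dq, g_new, r_new
    return q, r, H


def solve_quasi_static(model: KneeModel, flexion_deg: float,
                       guess: Pose6 | None = None,
                       settings: SolverSettings = SolverSettings(),
                       _mech: _Mechanics | None = None):
    """Equilibrate the five free coordinates at a prescribed flexion angle.

    Returns ``(pose, residual_norm_N, converged)``.  The pose keeps
    ``fe`` at the prescribed angle; the free coordinates minimize the
    total potential, and ``converged`` reports whether the generalized
    force residual meets the 5 N contract.  Deterministic given model,
    flexion and guess.
    """
    mech = _mech if _mech is not None else _Mechanics(model)
    q0 = (guess.free_coords() if guess is not None else np.zeros(5))

    q, rnorm, _ = _newton_equilibrate(mech, flexion_deg, q0, None, settings)
    if rnorm >= settings.residual_tol_N:
        q, rnorm = _minimize_fallback(mech, flexion_deg, (q, q0, np.zeros(5)),
                                      q, rnorm, settings)
    pose = Pose6(fe=flexion_deg).with_free_coords(q)
    return pose, rnorm, rnorm < settings.residual_tol_N


def _minimize_fallback(mech: _Mechanics, flexion_deg: float, starts,
                       best_q: np.ndarray, best_r: float,
                       settings: SolverSettings):
    """Energy-minimization rescue when the Newton iteration stalls."""

    def fun(q):
        return mech.energy_grad(flexion_deg, q)

    for q_start in starts:
        res = minimize(fun, q_start, jac=True, method="L-BFGS-B",
                       options={"maxiter": 4 * settings.max_iter,
                                "ftol": 1e-18, "gtol": settings.gtol})
        r = mech.residual_norm(fun(res.x)[1], settings.lever_arm_mm)
        if r < best_r:
            best_q, best_r = res.x, r
        if best_r < settings.residual_tol_N:
            break
    return best_q, best_r


def simulate_extension(model: KneeModel, t: int = 60,
                       start_deg: float = 60.0, end_deg: float = 0.0,
                       settings: SolverSettings = SolverSettings(),
                       guess: Pose6 | None = None) -> SimulationTrace:
    """Simulate knee extension on a uniform t-sample flexion grid.

    The grid includes both endpoints (default 60 deg ... 0 deg, step
    60/59).  Each step is warm-started from the previous solution; a
    step that fails to meet the residual contract is flagged but the
    trace always completes.
    """
    if t < 2:
        raise ValueError("need at least 2 samples")
    mech = _Mechanics(model)
    grid = np.linspace(start_deg, end_deg, t)
    poses: list[Pose6] = []
    strains = np.empty((t, len(model.ligaments)))
    residuals = np.empty(t)
    converged = np.empty(t, dtype=bool)
    prev = guess
    H = None
    for i, fe in enumerate(grid):
        try:
            q0 = (prev.free_coords() if prev is not None else np.zeros(5))
            q, rnorm, H = _newton_equilibrate(mech, float(fe), q0, H, settings)
            if rnorm >= settings.residual_tol_N:
                q, rnorm = _minimize_fallback(mech, float(fe),
                                              (q, q0, np.zeros(5)),
                                              q, rnorm, settings)
                H = None
            pose = Pose6(fe=float(fe)).with_free_coords(q)
            ok = rnorm < settings.residual_tol_N
        except (ValueError, FloatingPointError):
            pose = (prev if prev is not None else Pose6(fe=float(fe)))
            pose = Pose6(fe=float(fe)).with_free_coords(pose.free_coords())
            rnorm, ok, H = float("inf"), False, None
        poses.append(pose)
        strains[i] = mech.strains_at(pose)
        residuals[i] = rnorm
        converged[i] = ok
        prev = pose
    return SimulationTrace(flexion_deg=grid, poses=tuple(poses),
                           strains=strains,
                           ligament_names=model.ligament_names,
                           residuals=residuals, converged=converged)
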