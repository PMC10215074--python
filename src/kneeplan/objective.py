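"""Surgical-target objectives and the implant-position optimization.

The planner minimizes a weighted quadratic mismatch between implanted
and pre-diseased curves over the flexion arc,

    J(x) = sum_i w_i * (1/t) * sum_theta (y_implanted_i(theta; x)
                                          - y_reference_i(theta))**2 + P,

where the variables y_i are tibiofemoral kinematic coordinates and/or
ligament strains, t is the number of flexion samples, and P collects
penalties: 10^3 is added when any sample's equilibrium residual exceeds
the 5 N tolerance (only dynamically consistent simulations count), and,
for the peak-constrained target, another 10^3 when any ligament strain
exceeds its pre-diseased peak.

Five surgical targets instantiate the variable set and weights:

* ST1 - kinematics only (AP, LM, PD, EI, VV), equal weights;
* ST2 - ligament strains only (7 retained ligaments), equal weights;
* ST3 - ST2 with an eight-fold weight on the collaterals (sMCL, dMCL, LCL);
* ST4 - ST2 plus the pre-diseased peak-strain penalty;
* ST5 - kinematics + strains, each block rescaled so that the two
  contribute equally to the objective at the MA baseline.

The search over the 9 placement parameters runs CMA-ES in
bound-normalized coordinates; among near-optimal solutions the one
closest to MA is selected for clinical applicability.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .cmaes import cma_minimize
from .forward_sim import SimulationTrace
from .implant_placement import ImplantPlacement, PlacementBounds
from .knee_model import STRAIN_OBJECTIVE_NAMES

__all__ = ["SurgicalTarget", "ObjectiveSpec", "ObjectiveBreakdown",
           "CandidateRecord", "OptimizationResult", "objective_value",
           "make_target", "optimize", "select_clinical",
           "KINEMATIC_VARIABLES"]

KINEMATIC_VARIABLES = ("ap", "lm", "pd", "ei", "vv")
PENALTY_DEFAULT = 1.0e3
COLLATERALS = ("sMCL", "dMCL", "LCL")


class SurgicalTarget(enum.Enum):
    ST1 = "kinematics"
    ST2 = "strains"
    ST3 = "strains_collateral_weighted"
    ST4 = "strains_peak_constrained"
    ST5 = "combined"


@dataclass(frozen=True)
class ObjectiveSpec:
    """Fully specified objective: variables, weights, penalties, reference."""

    variables: tuple[str, ...]
    weights: np.ndarray
    reference: SimulationTrace
    penalty: float = PENALTY_DEFAULT
    residual_tol_N: float = 5.0
    peak_thresholds: dict | None = None     # ligament -> max pre-diseased strain
    target: SurgicalTarget | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float).reshape(len(self.variables))
        if np.any(w < 0.0):
            raise ValueError("weights must be nonnegative")
        if self.penalty <= 0.0:
            raise ValueError("penalty must be > 0")
        object.__setattr__(self, "weights", w)

    @property
    def t(self) -> int:
        return self.reference.t


@dataclass(frozen=True)
class ObjectiveBreakdown:
    value: float
    mismatch: float                 # penalty-free weighted sum
    per_variable: np.ndarray        # w_i * mean squared deviation, per variable
    residual_penalty: bool
    peak_penalty: bool


def _variable_curve(trace: SimulationTrace, var: str) -> np.ndarray:
    if var in KINEMATIC_VARIABLES:
        k = trace.kinematics_array()
        return k[:, KINEMATIC_VARIABLES.index(var)]
    return trace.strain_curve(var)


def objective_value(trace: SimulationTrace, spec: ObjectiveSpec,
                    return_breakdown: bool = False):
    """Evaluate the surgical-target objective for an implanted trace.

    ``trace`` is the simulated implanted knee at some placement x;
    deviations are taken against ``spec.reference`` on the same flexion
    grid.  Each triggered penalty class adds ``spec.penalty`` once.
    """
    ref = spec.reference
    if trace.t != ref.t or not np.allclose(trace.flexion_deg, ref.flexion_deg,
                                           atol=1e-9):
        raise ValueError("implanted and reference traces are on different "
                         "flexion grids")
    per_var = np.empty(len(spec.variables))
    for i, var in enumerate(spec.variables):
        dev = _variable_curve(trace, var) - _variable_curve(ref, var)
        per_var[i] = spec.weights[i] * float(np.mean(dev ** 2))
    mismatch = float(per_var.sum())

    residual_penalty = bool((~trace.converged).any()
                            or (trace.residuals >= spec.residual_tol_N).any())
    peak_penalty = False
    if spec.peak_thresholds is not None:
        for name, peak in spec.peak_thresholds.items():
            if np.any(trace.strain_curve(name) > peak):
                peak_penalty = True
                break
    value = mismatch
    if residual_penalty:
        value += spec.penalty
    if peak_penalty:
        value += spec.penalty
    if return_breakdown:
        return ObjectiveBreakdown(value=value, mismatch=mismatch,
                                  per_variable=per_var,
                                  residual_penalty=residual_penalty,
                                  peak_penalty=peak_penalty)
    return value


def objective_of_placement(x: ImplantPlacement, spec: ObjectiveSpec,
                           simulator, bounds: PlacementBounds | None = None,
                           **kw):
    """Objective for a placement: simulate the implanted knee, then score.

    ``simulator`` maps an ImplantPlacement to a SimulationTrace; ``x``
    must lie within ``bounds`` (default surgical bounds).
    """
    (bounds if bounds is not None else PlacementBounds()).check(x)
    return objective_value(simulator(x), spec, **kw)


def make_target(target: SurgicalTarget, ma_trace: SimulationTrace | None,
                pre_trace: SimulationTrace,
                penalty: float = PENALTY_DEFAULT) -> ObjectiveSpec:
    """Build the ObjectiveSpec for one of the five surgical targets.

    ``pre_trace`` supplies the reference curves (and, for ST4, the
    per-ligament peak thresholds).  ``ma_trace`` is required only for
    ST5, whose block weights are normalized so that the kinematic and
    strain blocks contribute 0.5 each at the MA baseline.
    """
    strain_vars = STRAIN_OBJECTIVE_NAMES
    if target is SurgicalTarget.ST1:
        return ObjectiveSpec(KINEMATIC_VARIABLES, np.ones(5), pre_trace,
                             penalty=penalty, target=target)
    if target is SurgicalTarget.ST2:
        return ObjectiveSpec(strain_vars, np.ones(7), pre_trace,
                             penalty=penalty, target=target)
    if target is SurgicalTarget.ST3:
        w = np.array([8.0 if v in COLLATERALS else 1.0 for v in strain_vars])
        return ObjectiveSpec(strain_vars, w, pre_trace,
                             penalty=penalty, target=target)
    if target is SurgicalTarget.ST4:
        peaks = {name: float(pre_trace.strain_curve(name).max())
                 for name in strain_vars}
        return ObjectiveSpec(strain_vars, np.ones(7), pre_trace,
                             penalty=penalty, peak_thresholds=peaks,
                             target=target)
    if target is SurgicalTarget.ST5:
        if ma_trace is None:
            raise ValueError("ST5 needs the MA baseline trace for normalization")
        variables = KINEMATIC_VARIABLES + strain_vars
        unit = ObjectiveSpec(variables, np.ones(12), pre_trace, penalty=penalty)
        bd = objective_value(ma_trace, unit, return_breakdown=True)
        kin = float(bd.per_variable[:5].sum())
        strn = float(bd.per_variable[5:].sum())
        if kin <= 0.0 or strn <= 0.0:
            raise ValueError("degenerate MA baseline: a block has zero deviation")
        w = np.concatenate([np.full(5, 0.5 / kin), np.full(7, 0.5 / strn)])
        return ObjectiveSpec(variables, w, pre_trace,
                             penalty=penalty, target=target)
    raise ValueError(target)


@dataclass(frozen=True)
class CandidateRecord:
    x: ImplantPlacement
    value: float
    residual_penalty: bool
    peak_penalty: bool

    @property
    def feasible(self) -> bool:
        return not (self.residual_penalty or self.peak_penalty)


@dataclass
class OptimizationResult:
    """Solution space of one CMA-ES run over the placement parameters."""

    candidates: list[CandidateRecord]
    best: CandidateRecord
    bounds: PlacementBounds
    seed: int
    n_generations: int
    stop_reason: str
    selected: ImplantPlacement | None = None

    def solution_space_frame(self):
        """All candidates as a DataFrame (9 parameters + objective + flags)."""
        import pandas as pd
        from .implant_placement import PARAM_NAMES
        rows = [{**dict(zip(PARAM_NAMES, c.x.as_array())),
                 "objective": c.value, "feasible": c.feasible}
                for c in self.candidates]
        return pd.DataFrame(rows)


def optimize(spec: ObjectiveSpec, bounds: PlacementBounds, simulator,
             seed: int = 0, popsize: int = 16, sigma0: float = 0.25,
             max_evals: int = 2000, ftarget: float | None = None,
             stagnation_gens: int = 60) -> OptimizationResult:
    """CMA-ES search for the optimal implant placement.

    ``simulator`` maps an :class:`ImplantPlacement` to the implanted
    :class:`SimulationTrace`.  The search runs in bound-normalized
    coordinates from the MA start (x = 0) with step size ``sigma0``
    (default a quarter of the normalized half-width); all evaluated
    candidates are recorded as the solution space.  MA itself is always
    evaluated, so the best objective never exceeds the MA objective.
    """
    records: list[CandidateRecord] = []

    def eval_placement(x_arr: np.ndarray) -> CandidateRecord:
        x = ImplantPlacement.from_array(x_arr)
        bd = objective_value(simulator(x), spec, return_breakdown=True)
        rec = CandidateRecord(x=x, value=bd.value,
                              residual_penalty=bd.residual_penalty,
                              peak_penalty=bd.peak_penalty)
        records.append(rec)
        return rec

    z0_ma = bounds.normalize(np.zeros(9))
    eval_placement(np.zeros(9))       # MA is part of the solution space

    def fun(z: np.ndarray) -> float:
        return eval_placement(bounds.denormalize(z)).value

    res = cma_minimize(fun, z0_ma, sigma0=sigma0, popsize=popsize,
                       bounds=(-np.ones(9), np.ones(9)), seed=seed,
                       max_evals=max_evals, ftarget=ftarget,
                       stagnation_gens=stagnation_gens)
    best = min(records, key=lambda r: r.value)
    if not any(r.feasible for r in records):
        import warnings
        warnings.warn("all evaluated candidates triggered penalties; "
                      "best objective includes penalty terms", stacklevel=2)
    return OptimizationResult(candidates=records, best=best, bounds=bounds,
                              seed=seed, n_generations=res.n_generations,
                              stop_reason=res.stop_reason)


def select_clinical(result: OptimizationResult,
                    tol_rel: float = 0.05) -> ImplantPlacement:
    """Pick the near-optimal candidate with the least deviation from MA.

    Among candidates whose objective is within ``(1 + tol_rel)`` of the
    best, returns the one minimizing the root-sum-square of the
    bound-normalized parameters (mm and degrees made commensurate by
    each parameter's bound half-width).  Ties break by evaluation order.
    """
    if not result.candidates:
        raise ValueError("empty optimization result")
    cutoff = (1.0 + tol_rel) * result.best.value
    hw = result.bounds.half_width
    best_dev = math.inf
    chosen = None
    for rec in result.candidates:
        if rec.value <= cutoff:
            dev = float(np.linalg.norm(rec.x.as_array() / hw))
            if dev < best_dev:
                best_dev = dev
                chosen = rec
    result.selected = chosen.x
    return chosen.x
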