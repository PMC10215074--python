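"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES following Hansen's tutorial
formulation: rank-based recombination of the best half of each
population, cumulative step-size adaptation, and rank-one plus rank-mu
covariance updates.  Box constraints are handled by repair: candidates
are clipped to the box for evaluation and a quadratic distance penalty
is added to the fitness of the unclipped sample, which keeps the
distribution update unbiased while making infeasible regions
unattractive.

This is a general minimizer; the implant-placement search uses it in
bound-normalized [-1, 1] coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CMAES", "CmaResult", "cma_minimize"]


@dataclass
class CmaResult:
    xbest: np.ndarray
    fbest: float
    n_evals: int
    n_generations: int
    stop_reason: str
    history_x: np.ndarray      # all evaluated (clipped) candidates, (N, n)
    history_f: np.ndarray      # raw objective value per candidate


class CMAES:
    """Ask/tell CMA-ES with box repair.  Minimizes."""

    def __init__(self, x0, sigma0: float, popsize: int | None = None,
                 bounds: tuple[np.ndarray, np.ndarray] | None = None,
                 seed: int | None = None,
                 boundary_penalty: float = 1e4):
        self.mean = np.asarray(x0, dtype=float).copy()
        n = self.mean.size
        self.n = n
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)
        self.bounds = bounds
        self.boundary_penalty = boundary_penalty

        self.lam = popsize if popsize is not None else 4 + int(3 * math.log(n))
        self.mu = self.lam // 2
        w = math.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / (self.weights ** 2).sum()

        self.cs = (self.mueff + 2.0) / (n + self.mueff + 5.0)
        self.ds = 1.0 + 2.0 * max(0.0, math.sqrt((self.mueff - 1.0) / (n + 1.0)) - 1.0) + self.cs
        self.cc = (4.0 + self.mueff / n) / (n + 4.0 + 2.0 * self.mueff / n)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1.0 - self.c1,
                       2.0 * (self.mueff - 2.0 + 1.0 / self.mueff) / ((n + 2.0) ** 2 + self.mueff))
        self.chiN = math.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.generation = 0

    # -- sampling ---------------------------------------------------------

    def ask(self) -> np.ndarray:
        """Sample a population; rows are raw (unclipped) candidates."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z * self.D @ self.B.T          # y ~ N(0, C)
        self._y = y
        return self.mean + self.sigma * y

    def repair(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Clip to the box; return (clipped X, penalty per row)."""
        if self.bounds is None:
            return X, np.zeros(len(X))
        lo, hi = self.bounds
        Xc = np.clip(X, lo, hi)
        pen = self.boundary_penalty * ((X - Xc) ** 2).sum(axis=1)
        return Xc, pen

    def tell(self, X: np.ndarray, f_penalized: np.ndarray) -> None:
        """Update the distribution from raw candidates and their fitness."""
        idx = np.argsort(f_penalized, kind="stable")[: self.mu]
        y_sel = self._y[idx]
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w

        # cumulative step-size adaptation
        C_inv_half = self.B @ np.diag(1.0 / self.D) @ self.B.T
        self.ps = ((1.0 - self.cs) * self.ps
                   + math.sqrt(self.cs * (2.0 - self.cs) * self.mueff) * (C_inv_half @ y_w))
        ps_norm = np.linalg.norm(self.ps)
        hsig = ps_norm / math.sqrt(
            1.0 - (1.0 - self.cs) ** (2 * (self.generation + 1))) / self.chiN \
            < 1.4 + 2.0 / (self.n + 1.0)
        self.pc = ((1.0 - self.cc) * self.pc
                   + (math.sqrt(self.cc * (2.0 - self.cc) * self.mueff) * y_w if hsig else 0.0))

        # covariance update (rank-one + rank-mu)
        delta_hsig = (1.0 - float(hsig)) * self.cc * (2.0 - self.cc)
        rank_mu = (self.weights[:, None, None] * (y_sel[:, :, None] * y_sel[:, None, :])).sum(0)
        self.C = ((1.0 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc) + delta_hsig * self.C)
                  + self.cmu * rank_mu)

        self.sigma *= math.exp((self.cs / self.ds) * (ps_norm / self.chiN - 1.0))
        self.generation += 1

        # refresh eigendecomposition (cheap at these dimensions)
        C = (self.C + self.C.T) / 2.0
        eigvals, self.B = np.linalg.eigh(C)
        self.D = np.sqrt(np.maximum(eigvals, 1e-30))


def cma_minimize(fun, x0, sigma0: float, popsize: int = 16,
                 bounds: tuple[np.ndarray, np.ndarray] | None = None,
                 seed: int | None = None, max_evals: int = 2000,
                 ftarget: float | None = None,
                 stagnation_gens: int = 60) -> CmaResult:
    """Minimize ``fun`` with CMA-ES; every evaluated candidate is recorded.

    Termination: evaluation budget, ``ftarget`` reached, step size
    collapse, or no improvement of the best value over
    ``stagnation_gens`` generations.
    """
    es = CMAES(x0, sigma0, popsize=popsize, bounds=bounds, seed=seed)
    hist_x: list[np.ndarray] = []
    hist_f: list[float] = []
    fbest = math.inf
    xbest = np.asarray(x0, float).copy()
    last_improvement = 0
    stop = "max_evals"
    while len(hist_f) < max_evals:
        X_raw = es.ask()
        X, pen = es.repair(X_raw)
        f = np.array([fun(x) for x in X])
        for x, fv in zip(X, f):
            hist_x.append(x.copy())
            hist_f.append(float(fv))
        gen_best = int(np.argmin(f))
        if f[gen_best] < fbest:
            fbest = float(f[gen_best])
            xbest = X[gen_best].copy()
            last_improvement = es.generation
        es.tell(X_raw, f + pen)
        if ftarget is not None and fbest <= ftarget:
            stop = "ftarget"
            break
        if es.sigma < 1e-12:
            stop = "sigma_collapse"
            break
        if es.generation - last_improvement > stagnation_gens:
            stop = "stagnation"
            break
    return CmaResult(xbest=xbest, fbest=fbest, n_evals=len(hist_f),
                     n_generations=es.generation, stop_reason=stop,
                     history_x=np.array(hist_x), history_f=np.array(hist_f))
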