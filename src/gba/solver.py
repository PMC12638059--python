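"""Balanced-growth optimization.

The decision variable is the growth-scaled flux vector ``xi = v / mu``
(g/L).  Under balanced growth every internal concentration is produced at
the rate it is diluted (``M_int v = mu c``), which makes

* the internal concentration vector linear in the decision:
  ``c = M_int @ xi``;
* the total-density constraint linear: ``sum(c) = rho``;
* the growth rate an explicit function of the decision:
  ``mu(xi) = c_P / sum_a xi_a * tau_a(a, c)``,

since total protein ``P = sum_a p_a = mu * sum_a xi_a tau_a`` must equal the
last entry of ``c``.  The program solved per condition is

    maximize    mu(xi)
    subject to  sum(M_int @ xi) = rho
                (M_int @ xi)_i >= 0          for every internal i
                p_a = mu xi_a tau_a >= 0     for every reaction a
                xi_a >= 0                    for irreversible a

via SLSQP (default) or an augmented-Lagrangian outer loop with an L-BFGS-B
inner solver, with deterministic multistart and warm starting across
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import InfeasibleModelError
from .kinetics import TurnoverContext, turnover_times
from .model_core import ConditionSet, GBAModel

__all__ = ["SolverOptions", "GrowthSolution", "growth_rate",
           "choose_initial_point", "solve_condition", "solve_all"]

logger = logging.getLogger("gba.solver")

#: objective value handed to the minimizer for infeasible mu evaluations
_PENALTY = 1e6

_BACKENDS = ("slsqp", "lbfgs", "mma")


@dataclass
class SolverOptions:
    """Knobs for the per-condition optimization."""

    solver: str = "slsqp"       # slsqp | lbfgs | mma
    n_starts: int = 10
    seed: int = 42
    ftol: float = 1e-9          # relative objective tolerance
    ctol: float = 1e-8          # constraint tolerance (relative to rho)
    maxiter: int = 2000

    def __post_init__(self):
        if self.solver not in _BACKENDS:
            raise ValueError(
                f"unknown solver {self.solver!r}; choose from {_BACKENDS}")

    def to_dict(self) -> dict:
        return {"solver": self.solver, "n_starts": self.n_starts,
                "seed": self.seed, "ftol": self.ftol, "ctol": self.ctol,
                "maxiter": self.maxiter}


@dataclass
class GrowthSolution:
    """Optimal balanced-growth state for one condition."""

    mu: float
    xi: np.ndarray
    v: np.ndarray
    c: np.ndarray
    p: np.ndarray
    phi: np.ndarray
    converged: bool
    constraint_residuals: dict = field(default_factory=dict)
    solver_used: str = "slsqp"
    n_iterations: int = 0
    condition_label: str = ""


def _check_condition(rho: float, a) -> tuple[float, np.ndarray]:
    a = np.atleast_1d(np.asarray(a, dtype=float))
    return float(rho), a


def growth_rate(model: GBAModel, condition, xi) -> float:
    """Balanced growth rate mu(xi) = c_P / sum(xi * tau) at this condition.

    Returns NaN (non-finite sentinel, treated as infeasible) when the
    protein-cost denominator is non-positive or undefined.
    """
    rho, a = _check_condition(*condition)
    xi = np.asarray(xi, dtype=float)
    c = model.M_int @ xi
    ctx = TurnoverContext(a, c)
    tau = turnover_times(model, ctx)
    terms = np.where(xi == 0.0, 0.0, xi * tau)
    denom = float(np.sum(terms))
    if not np.isfinite(denom) or denom <= 0.0:
        return float("nan")
    return float(c[-1]) / denom


def _column_import(model: GBAModel) -> np.ndarray:
    """Net internal mass created per unit flux of each column (1^T M_int)."""
    return np.asarray(model.M_int).sum(axis=0)


def _require_importable(model: GBAModel) -> None:
    imp = _column_import(model)
    irrev = model.irreversible
    if not (np.any(imp[irrev] > 0) or np.any(imp[~irrev] != 0)):
        raise InfeasibleModelError(
            "no reaction imports net mass: the density constraint "
            "sum(c) = rho > 0 is unreachable")


def choose_initial_point(model: GBAModel, condition, seed: int) -> np.ndarray:
    """Deterministic strictly positive start, rescaled so the density
    equality holds exactly.

    A random positive concentration target ``c*`` on the density simplex is
    drawn and ``xi`` is fit to it by non-negative least squares, which keeps
    the start away from the clamped (zero-concentration) region where the
    objective is nearly flat.
    """
    rho, _ = _check_condition(*condition)
    _require_importable(model)
    rng = np.random.default_rng(seed)
    M_int = np.asarray(model.M_int, dtype=float)
    imp = M_int.sum(axis=0)
    n_int = M_int.shape[0]
    for _ in range(100):
        c_target = rho * rng.dirichlet(np.ones(n_int))
        xi, _ = optimize.nnls(M_int, c_target)
        xi = np.maximum(xi, 1e-6 * rho)   # strictly positive start
        s = float(imp @ xi)
        if s > 0:
            return xi * (rho / s)
        # fall back to a raw log-uniform draw
        xi = 10.0 ** rng.uniform(-2.0, 0.0, model.n_reactions)
        s = float(imp @ xi)
        if s > 0:
            return xi * (rho / s)
    raise InfeasibleModelError("could not draw a start with positive net import")


def _make_objective(model: GBAModel, rho: float, a: np.ndarray):
    def neg_mu(z: np.ndarray) -> float:
        mu = growth_rate(model, (rho, a), rho * z)
        if not np.isfinite(mu):
            return _PENALTY
        return -mu
    return neg_mu


def _residuals(model: GBAModel, rho: float, a: np.ndarray, xi: np.ndarray,
               mu: float) -> dict:
    c = model.M_int @ xi
    ctx = TurnoverContext(a, c)
    tau = turnover_times(model, ctx)
    p = np.where(xi == 0.0, 0.0, mu * xi * tau)
    v = mu * xi
    return {
        "density": abs(float(np.sum(c)) - rho),
        "min_concentration": float(np.min(c)),
        "min_protein": float(np.min(p)) if np.all(np.isfinite(p)) else float("-inf"),
        "protein_closure": abs(float(np.sum(p)) - float(c[-1])),
        "dilution": float(np.max(np.abs(model.M_int @ v - mu * c))),
    }


def _is_converged(res_ok: bool, mu: float, resid: dict, rho: float,
                  ctol: float) -> bool:
    tol = ctol * rho
    return (res_ok and np.isfinite(mu) and mu > 0
            and resid["density"] <= max(tol, 1e-6 * rho)
            and resid["min_concentration"] >= -max(tol, 1e-9)
            and resid["min_protein"] >= -max(tol, 1e-9))


def _solve_slsqp(neg_mu, cons_eq, cons_ineqs, bounds, z0, options):
    constraints = [{"type": "eq", "fun": cons_eq}]
    constraints += [{"type": "ineq", "fun": g} for g in cons_ineqs]
    res = optimize.minimize(
        neg_mu, z0, method="SLSQP", bounds=bounds, constraints=constraints,
        options={"ftol": options.ftol, "maxiter": options.maxiter,
                 "eps": 1e-7})
    return res.x, bool(res.success), int(res.get("nit", 0))


def _solve_auglag(neg_mu, cons_eq, cons_ineqs, bounds, z0, options):
    """Augmented-Lagrangian outer loop, L-BFGS-B inner solver."""
    lam_eq = 0.0
    lam_in = np.zeros(len(cons_ineqs))
    mu_pen = 10.0
    z = np.array(z0, dtype=float)
    prev_viol = np.inf
    total_it = 0
    for _ in range(30):
        def lagrangian(zz):
            h = cons_eq(zz)
            val = neg_mu(zz) + lam_eq * h + 0.5 * mu_pen * h * h
            for lam, g in zip(lam_in, cons_ineqs):
                # inequality g(z) >= 0; violation measure s = max(0, lam - mu*g)
                s = max(0.0, lam - mu_pen * g(zz))
                val += (s * s - lam * lam) / (2.0 * mu_pen)
            return val

        res = optimize.minimize(
            lagrangian, z, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter,
                     "ftol": options.ftol, "gtol": 1e-10, "eps": 1e-8})
        z = res.x
        total_it += int(res.get("nit", 0))
        h = cons_eq(z)
        gvals = np.array([g(z) for g in cons_ineqs])
        viol = max(abs(h), float(np.max(-np.minimum(gvals, 0.0), initial=0.0)))
        lam_eq += mu_pen * h
        lam_in = np.maximum(0.0, lam_in - mu_pen * gvals)
        if viol <= options.ctol and res.success:
            return z, True, total_it
        if viol > 0.25 * prev_viol:
            mu_pen = min(mu_pen * 10.0, 1e10)
        prev_viol = viol
    return z, viol <= 10 * options.ctol, total_it


def solve_condition(model: GBAModel, condition, options: SolverOptions | None = None,
                    warm_start: np.ndarray | None = None,
                    condition_label: str = "") -> GrowthSolution:
    """Maximize the balanced growth rate for one (rho, a) condition.

    Runs a deterministic multistart and returns the best converged result
    (or, failing that, the best iterate with ``converged=False``).
    """
    options = options or SolverOptions()
    rho, a = _check_condition(*condition)
    _require_importable(model)

    M_int = np.asarray(model.M_int, dtype=float)
    irrev = model.irreversible
    neg_mu = _make_objective(model, rho, a)

    def cons_eq(z):
        return float(np.sum(M_int @ z)) - 1.0

    cons_ineqs = []
    for i in range(M_int.shape[0]):
        cons_ineqs.append(lambda z, i=i: float(M_int[i] @ z))
    # protein non-negativity only binds for reversible reactions; for
    # irreversible ones xi >= 0 and tau >= 0 already force p >= 0
    for j in np.nonzero(~irrev)[0]:
        def p_nonneg(z, j=j):
            xi = rho * z
            c = M_int @ xi
            tau = turnover_times(model, TurnoverContext(a, c))
            mu = growth_rate(model, (rho, a), xi)
            if not np.isfinite(mu):
                return -1.0
            return mu * xi[j] * tau[j] / rho
        cons_ineqs.append(p_nonneg)

    bounds = [(0.0, None) if irrev[j] else (None, None)
              for j in range(model.n_reactions)]

    starts: list[np.ndarray] = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float) / rho)
    for k in range(options.n_starts):
        starts.append(choose_initial_point(model, (rho, a),
                                           options.seed + k) / rho)

    backend = _solve_slsqp if options.solver == "slsqp" else _solve_auglag
    best = None  # (key, xi, mu, resid, ok, nit)
    for idx, z0 in enumerate(starts):
        try:
            z, ok, nit = backend(neg_mu, cons_eq, cons_ineqs, bounds, z0,
                                 options)
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        xi = rho * np.asarray(z, dtype=float)
        mu = growth_rate(model, (rho, a), xi)
        if not np.isfinite(mu):
            mu = float("nan")
        resid = _residuals(model, rho, a, xi, mu if np.isfinite(mu) else 0.0)
        conv = _is_converged(ok, mu, resid, rho, options.ctol)
        # converged results first, then higher mu, then lower residual,
        # then earlier start
        key = (0 if conv else 1,
               -(mu if np.isfinite(mu) else -np.inf),
               resid["density"], idx)
        if best is None or key < best[0]:
            best = (key, xi, mu, resid, conv, nit)

    if best is None:
        raise InfeasibleModelError("all multistart attempts failed")
    _, xi, mu, resid, conv, nit = best
    return _assemble(model, rho, a, xi, mu, conv, resid, options.solver,
                     nit, condition_label)


def _assemble(model, rho, a, xi, mu, converged, resid, solver_used, nit,
              condition_label) -> GrowthSolution:
    c = model.M_int @ xi
    ctx = TurnoverContext(a, c)
    tau = turnover_times(model, ctx)
    mu_eff = mu if np.isfinite(mu) else 0.0
    p = np.where(xi == 0.0, 0.0, mu_eff * xi * tau)
    v = mu_eff * xi
    P = float(c[-1])
    phi = p / P if P > 0 else np.zeros_like(p)
    return GrowthSolution(
        mu=float(mu_eff), xi=xi, v=v, c=c, p=p, phi=phi,
        converged=bool(converged), constraint_residuals=resid,
        solver_used=solver_used, n_iterations=int(nit),
        condition_label=condition_label)


def solve_all(model: GBAModel, conditions: ConditionSet,
              options: SolverOptions | None = None,
              progress=None) -> list[GrowthSolution]:
    """Solve every condition in column order, warm-starting each condition
    from the previous converged optimum.

    ``progress``: optional callback ``(index, n_conditions, solution)``;
    log lines are emitted either way.  Per-condition failures are recorded
    in the corresponding solution and do not stop the sweep.
    """
    options = options or SolverOptions()
    solutions: list[GrowthSolution] = []
    warm = None
    n = conditions.n_conditions
    for k in range(n):
        label = conditions.condition_labels[k]
        rho, a = conditions.condition(k)
        try:
            sol = solve_condition(model, (rho, a), options, warm_start=warm,
                                  condition_label=label)
        except InfeasibleModelError as exc:
            sol = GrowthSolution(
                mu=0.0, xi=np.zeros(model.n_reactions),
                v=np.zeros(model.n_reactions),
                c=np.zeros(model.n_internal),
                p=np.zeros(model.n_reactions),
                phi=np.zeros(model.n_reactions),
                converged=False,
                constraint_residuals={"error": str(exc)},
                solver_used=options.solver, condition_label=label)
        if sol.converged:
            warm = sol.xi
        logger.info("condition %d/%d (%s): mu = %.6g /h, converged = %s",
                    k + 1, n, label, sol.mu, sol.converged)
        if progress is not None:
            progress(k, n, sol)
        solutions.append(sol)
    return solutions
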