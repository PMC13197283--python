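"""Healthy-liver calibration against clinical flow targets.

The free parameters are the terminal lumen diameters of the HA, PV and HV
trees and the lumped sinusoid conductance c_sin; the targets are a total
liver inflow of 1300 ml/min with the portal vein supplying 970 ml/min
under the healthy pressure boundary conditions (77 / 5 mmHg).  The
objective is the sum of squared relative errors of (total flow, PV flow).

The optimizer is a seeded derivative-free scheme: a Latin-hypercube
exploration of the bound box followed by bounded Nelder–Mead refinement
from the best point, within a fixed evaluation budget.  The calibration
runs on one fixed network realization, so the objective is deterministic
and repeated runs with the same seed produce identical traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import units
from .cirrhosis import C_SIN0_CLINICAL

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "calibration_objective",
    "calibrate_healthy",
]

# published healthy optima: terminal lumen diameters (um) and c_sin
_PUBLISHED_OPTIMUM = {
    "d_term_ha_um": 2 * 2.61,
    "d_term_pv_um": 2 * 67.5,
    "d_term_hv_um": 2 * 75.3,
    "c_sin_clinical": C_SIN0_CLINICAL,
}

PARAM_NAMES = tuple(_PUBLISHED_OPTIMUM)


def default_bounds(low: float = 0.5, high: float = 2.0) -> dict:
    """Bounds bracketing the published optima by a configurable factor."""
    return {k: (low * v, high * v) for k, v in _PUBLISHED_OPTIMUM.items()}


def reduced_scale_problem(seed: int = 0, budget: int = 50) -> "CalibrationProblem":
    """Calibration preset for conductance-preserving desk-scale models.

    c_sin is held at the printed healthy reference c0_sin (it anchors the
    whole cirrhosis parameterization), so only the three terminal lumen
    diameters are free.  A reduced-scale tree realizes fewer branching
    generations than the full organ and is therefore intrinsically more
    conductive at matched terminal radius, which pushes the PV/HV optima
    below half their full-scale values; the lower bracket is widened to
    0.2x accordingly (the upper stays at 2x).
    """
    bounds = default_bounds(low=0.2)
    bounds.pop("c_sin_clinical")
    return CalibrationProblem(bounds=bounds, budget=budget, seed=seed)


@dataclass(frozen=True)
class CalibrationProblem:
    """Targets, bounds and budget of the healthy calibration."""

    target_total_mlmin: float = 1300.0
    target_pv_mlmin: float = 970.0
    bounds: dict = field(default_factory=default_bounds)
    budget: int = 50
    n_init: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.target_total_mlmin <= 0 or self.target_pv_mlmin <= 0:
            raise ValueError("flow targets must be positive")
        if self.budget < 2:
            raise ValueError("budget must allow at least two evaluations")
        unknown = set(self.bounds) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown calibration parameters: {sorted(unknown)}")


@dataclass
class CalibrationResult:
    """Best parameters, objective trace and achieved flows."""

    params: dict
    objective: float
    trace: list  # best-so-far objective after each evaluation
    achieved_total_mlmin: float
    achieved_pv_mlmin: float
    n_evaluations: int
    converged: bool


def _apply_params(model, values: dict):
    radii = {}
    if "d_term_ha_um" in values:
        radii["HA"] = values["d_term_ha_um"] / 2.0 * units.UM_TO_M
    if "d_term_pv_um" in values:
        radii["PV"] = values["d_term_pv_um"] / 2.0 * units.UM_TO_M
    if "d_term_hv_um" in values:
        radii["HV"] = values["d_term_hv_um"] / 2.0 * units.UM_TO_M
    model.update_parameters(
        terminal_radius_full=radii or None,
        c_sin_clinical=values.get("c_sin_clinical"),
    )


def calibration_objective(params: dict, model, problem: CalibrationProblem) -> float:
    """Sum of squared relative flow errors for one parameter set.

    Rebuilds the model's conductances with the candidate parameters and
    solves under the healthy pressure boundary conditions; solver failures
    return a large penalty.
    """
    from .hemodynamics import SolverError

    _apply_params(model, params)
    try:
        res = model.solve()
    except SolverError as exc:  # pragma: no cover - defensive
        logger.warning("solver failure during calibration: %s", exc)
        return 1e6
    e_total = (res.q_liver - problem.target_total_mlmin) / problem.target_total_mlmin
    e_pv = (res.q_pv - problem.target_pv_mlmin) / problem.target_pv_mlmin
    return float(e_total**2 + e_pv**2)


def minimize_derivative_free(objective, bounds: dict, budget: int, n_init: int, seed: int):
    """Seeded LHS exploration + bounded Nelder–Mead within ``budget`` calls.

    Generic scalar minimizer over a box; returns (best_x dict, best_f,
    best-so-far trace, n_evaluations).
    """
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    # search in normalized log coordinates: the parameters are strictly
    # positive scales spanning decades, over which the response is much
    # closer to polynomial in log space
    log_lo, log_hi = np.log(lo), np.log(hi)

    def to_x(u):
        return np.exp(log_lo + np.clip(u, 0.0, 1.0) * (log_hi - log_lo))

    trace = []
    best = {"u": None, "f": np.inf}
    n_eval = 0

    def evaluate(u):
        nonlocal n_eval
        x = to_x(u)
        f = objective(dict(zip(names, x)))
        n_eval += 1
        if f < best["f"]:
            best["f"] = f
            best["u"] = np.clip(np.array(u), 0.0, 1.0)
        trace.append(best["f"])
        return f

    n_init = min(n_init, budget - 1)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    points = sampler.random(n=n_init)
    # geometric center of the box (the published optimum scaled into the
    # default bounds) is always evaluated first
    for u in np.vstack([np.full(len(names), 0.5), points]):
        evaluate(u)
        if n_eval >= budget:
            break

    remaining = budget - n_eval
    if remaining > len(names) + 1:
        optimize.minimize(
            evaluate,
            best["u"],
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(names),
            options={
                "maxfev": remaining,
                "xatol": 1e-6,
                "fatol": 1e-12,
                "initial_simplex": _simplex_around(best["u"], 0.12),
            },
        )
    return dict(zip(names, to_x(best["u"]))), best["f"], trace, n_eval


def _simplex_around(u0: np.ndarray, step: float) -> np.ndarray:
    """Initial Nelder–Mead simplex centred on ``u0`` inside the unit box."""
    d = u0.size
    simplex = np.tile(u0, (d + 1, 1))
    for i in range(d):
        delta = step if u0[i] + step <= 1.0 else -step
        simplex[i + 1, i] = np.clip(u0[i] + delta, 0.0, 1.0)
    return simplex


def calibrate_healthy(model, problem: CalibrationProblem | None = None) -> CalibrationResult:
    """Optimize terminal diameters and c_sin to hit the clinical targets.

    The model must be a healthy-stage :class:`~hepaflow.model.LiverModel`
    (pressure boundary conditions); its network realization is built once
    and reused for every objective evaluation, and the model is left at
    the best parameters found.
    """
    if problem is None:
        problem = CalibrationProblem()
    model.network  # force one build; reused across evaluations

    def objective(values):
        return calibration_objective(values, model, problem)

    # restrict to the bounded parameters only
    params, f_best, trace, n_eval = minimize_derivative_free(
        objective, problem.bounds, problem.budget, problem.n_init, problem.seed
    )
    _apply_params(model, params)
    res = model.solve()
    improved = len(trace) > 1 and trace[-1] < trace[0]
    if not improved:
        logger.warning("calibration budget exhausted without improvement")
    return CalibrationResult(
        params=params,
        objective=f_best,
        trace=trace,
        achieved_total_mlmin=res.q_liver,
        achieved_pv_mlmin=res.q_pv,
        n_evaluations=n_eval,
        converged=improved,
    )
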