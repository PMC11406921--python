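"""Linear-programming core: FBA, parsimonious FBA, flux variability analysis.

All three solve variants of

    max  c.v   s.t.  S.v = 0,  lb <= v <= ub

with scipy's HiGHS backend.  pFBA adds a second stage: holding the
objective at (a fraction of) its optimum, minimize total absolute flux
sum_j |v_j|, linearized by splitting every reaction into non-negative
forward/backward halves.  FVA reports, per reaction, the attainable flux
range over the (near-)optimal solution set, which is how degenerate
alternative optima are made explicit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import StoichiometricModel, stoichiometric_matrix

__all__ = ["SolverConfig", "FluxSolution", "SolverError", "fba", "pfba", "fva"]


class SolverError(RuntimeError):
    """The LP backend failed in a way that is not a clean infeasible/unbounded."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs; none of these are biological parameters.

    feas_tol      -- primal feasibility tolerance handed to the backend and
                     used when checking |S.v|.
    opt_fraction  -- fraction of the FBA optimum that pFBA/FVA must retain
                     (1.0 = hold the exact optimum, up to feas_tol).
    zero_cut      -- magnitude below which a flux is reported as exactly 0
                     in downstream tables; suppresses solver noise.
    """

    feas_tol: float = 1e-9
    opt_fraction: float = 1.0
    zero_cut: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.feas_tol > 0 and self.zero_cut > 0):
            raise ValueError("feas_tol and zero_cut must be positive")
        if not (0 < self.opt_fraction <= 1):
            raise ValueError("opt_fraction must be in (0, 1]")


@dataclass
class FluxSolution:
    """Raw output of one FBA/pFBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)
    total_abs_flux: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}

_HIGHS_OPTS = {
    "presolve": True,
    "disp": False,
}


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds, feas_tol):
    opts = dict(_HIGHS_OPTS)
    opts["primal_feasibility_tolerance"] = max(feas_tol, 1e-10)
    opts["dual_feasibility_tolerance"] = max(feas_tol, 1e-10)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=opts)
    if res.status not in _STATUS:
        raise SolverError(f"LP backend failure: {res.message}")
    return res


def _arrays(model: StoichiometricModel):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    c = np.zeros(len(model.reactions))
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rid, w in model.objective.items():
        c[idx[rid]] = w
    return S, lb, ub, c


def fba(model: StoichiometricModel, config: Optional[SolverConfig] = None) -> FluxSolution:
    """Maximize the model objective subject to steady state and bounds."""
    config = config or SolverConfig()
    if not model.objective:
        raise ValueError(f"model {model.id!r} has an empty objective")
    model.validate()
    S, lb, ub, c = _arrays(model)
    b_eq = np.zeros(S.shape[0])
    res = _solve(-c, S, b_eq, None, None, list(zip(lb, ub)), config.feas_tol)
    status = _STATUS[res.status]
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes=dict(zip(model.reaction_ids, map(float, v))),
    )


def _split_bounds(lb: np.ndarray, ub: np.ndarray):
    """Forward/backward half bounds so that v = v+ - v- spans [lb, ub]."""
    n = lb.size
    fwd_lb, fwd_ub = np.zeros(n), np.zeros(n)
    bwd_lb, bwd_ub = np.zeros(n), np.zeros(n)
    for j in range(n):
        if lb[j] >= 0:  # strictly forward
            fwd_lb[j], fwd_ub[j] = lb[j], ub[j]
        elif ub[j] <= 0:  # strictly backward
            bwd_lb[j], bwd_ub[j] = -ub[j], -lb[j]
        else:  # reversible
            fwd_ub[j] = ub[j]
            bwd_ub[j] = -lb[j]
    return fwd_lb, fwd_ub, bwd_lb, bwd_ub


def pfba(model: StoichiometricModel, config: Optional[SolverConfig] = None) -> FluxSolution:
    """Parsimonious FBA: minimal total |flux| among (near-)optimal solutions.

    Stage 1 is plain FBA; stage 2 minimizes sum(v+ + v-) on the
    irreversibly-split network subject to the stage-1 objective held at
    >= opt_fraction * optimum.  Fluxes are reported on the original,
    unsplit reactions.
    """
    config = config or SolverConfig()
    first = fba(model, config)
    if not first.optimal:
        return first
    opt = first.objective_value

    S, lb, ub, c = _arrays(model)
    m, n = S.shape
    fwd_lb, fwd_ub, bwd_lb, bwd_ub = _split_bounds(lb, ub)
    # variables x = [v+, v-]; v = v+ - v-
    S2 = np.hstack([S, -S])
    b_eq = np.zeros(m)
    c2 = np.ones(2 * n)
    # hold objective: c.(v+ - v-) >= opt_fraction*opt - feas_tol
    thresh = config.opt_fraction * opt - config.feas_tol - 1e-9 * abs(opt)
    A_ub = np.concatenate([-c, c])[None, :]
    b_ub = np.array([-thresh])
    bounds = list(zip(np.concatenate([fwd_lb, bwd_lb]),
                      np.concatenate([fwd_ub, bwd_ub])))
    res = _solve(c2, S2, b_eq, A_ub, b_ub, bounds, config.feas_tol)
    status = _STATUS[res.status]
    if status != "optimal":
        # the held-objective constraint cannot make a feasible model infeasible
        # beyond numerics; report faithfully rather than guessing
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x[:n] - res.x[n:]
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes=dict(zip(model.reaction_ids, map(float, v))),
        total_abs_flux=float(np.sum(np.abs(v))),
    )


def fva(
    model: StoichiometricModel,
    reaction_ids: Optional[Sequence[str]] = None,
    config: Optional[SolverConfig] = None,
    opt_fraction: Optional[float] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux range per reaction over the near-optimal solution set.

    The set is {v : S.v=0, bounds, c.v >= opt_fraction * optimum}; with
    opt_fraction 1.0 this is the optimal face, and a zero-width range
    means the flux is uniquely determined at optimality.  Passing
    ``opt_fraction=0`` here drops the objective constraint entirely and
    reports the full feasible range.
    """
    config = config or SolverConfig()
    if opt_fraction is None:
        opt_fraction = config.opt_fraction
    if not (0 <= opt_fraction <= 1):
        raise ValueError("opt_fraction must be in [0, 1]")
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    unknown = [rid for rid in reaction_ids if rid not in idx]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")

    first = fba(model, config)
    if not first.optimal:
        raise SolverError(f"FVA requires an optimal FBA solve, got {first.status}")
    opt = first.objective_value

    S, lb, ub, c = _arrays(model)
    b_eq = np.zeros(S.shape[0])
    if opt_fraction > 0:
        thresh = opt_fraction * opt - config.feas_tol - 1e-9 * abs(opt)
        A_ub, b_ub = -c[None, :], np.array([-thresh])
    else:
        A_ub, b_ub = None, None
    bounds = list(zip(lb, ub))

    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        j = idx[rid]
        obj = np.zeros(len(model.reactions))
        obj[j] = 1.0
        lo = _solve(obj, S, b_eq, A_ub, b_ub, bounds, config.feas_tol)
        hi = _solve(-obj, S, b_eq, A_ub, b_ub, bounds, config.feas_tol)
        if _STATUS[lo.status] != "optimal" or _STATUS[hi.status] != "optimal":
            raise SolverError(f"FVA subproblem for {rid!r} not optimal")
        ranges[rid] = (float(lo.x[j]), float(hi.x[j]))
    return ranges
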