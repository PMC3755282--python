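"""Flux balance analysis: linear programming over a GEM.

Solves  optimize c'v  s.t.  S v = 0,  l <= v <= u  with the HiGHS
solver behind :func:`scipy.optimize.linprog`.  Feasibility tolerance is
1e-9; steady state is verified to 1e-6 after solving.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .core import GEM, ConfigurationError, FluxDistribution, MetabolicTask

__all__ = ["solve_lp", "solve_fba", "check_tasks", "STEADY_STATE_TOL"]

STEADY_STATE_TOL = 1e-6
_FEAS_TOL = 1e-9


def solve_lp(c, A_eq, b_eq, bounds, sense: str = "min", A_ub=None, b_ub=None):
    """Thin wrapper around linprog(HiGHS) returning (x, objective, status).

    ``sense`` is "min" or "max"; status is one of optimal / infeasible /
    unbounded / failed.
    """
    c = np.asarray(c, dtype=float)
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL,
                 "dual_feasibility_tolerance": _FEAS_TOL},
    )
    if res.status == 0:
        return res.x, float(c @ res.x), "optimal"
    if res.status == 2:
        return None, np.nan, "infeasible"
    if res.status == 3:
        return None, np.nan, "unbounded"
    return None, np.nan, "failed"


def solve_fba(
    model: GEM,
    objective: str,
    direction: str = "max",
    fixed: dict[str, float] | None = None,
) -> FluxDistribution:
    """Optimize one reaction flux subject to steady state and bounds.

    Parameters
    ----------
    model : GEM
    objective : reaction id to optimize.
    direction : "max" or "min".
    fixed : reaction fluxes to pin (must lie within the reaction bounds).

    Returns a :class:`FluxDistribution`; infeasible/unbounded problems
    are reported through its ``status``, not raised.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    rxn_ids = model.reaction_ids
    jpos = {r: j for j, r in enumerate(rxn_ids)}
    if objective not in jpos:
        raise ConfigurationError(f"unknown objective reaction {objective!r}")

    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    for rid, value in (fixed or {}).items():
        j = jpos.get(rid)
        if j is None:
            raise ConfigurationError(f"unknown fixed reaction {rid!r}")
        lb, ub = bounds[j]
        if not (lb - _FEAS_TOL <= value <= ub + _FEAS_TOL):
            raise ConfigurationError(
                f"fixed value {value} for {rid} outside bounds [{lb}, {ub}]"
            )
        bounds[j] = (value, value)

    S = model.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    c[jpos[objective]] = 1.0
    x, obj, status = solve_lp(c, S, np.zeros(S.shape[0]), bounds, sense=direction)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=np.nan, status=status)

    resid = np.abs(S @ x).max() if S.size else 0.0
    if resid > STEADY_STATE_TOL:
        raise RuntimeError(f"steady-state residual {resid:.2e} exceeds tolerance")
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, x))),
        objective_value=obj,
        status="optimal",
    )


def check_tasks(model: GEM, tasks: list[MetabolicTask]) -> dict[str, bool]:
    """Evaluate metabolic tasks: pass iff, with uptake allowed only for
    the task's required inputs, every required output can be exported at
    positive flux.

    Input/output metabolites are addressed through the model's exchange
    reactions; ids that do not resolve raise :class:`ConfigurationError`.
    """
    exch_by_met = {
        model.exchanged_metabolite(r): r for r in model.exchange_reactions
    }
    results: dict[str, bool] = {}
    for task in tasks:
        for met_id in [*task.required_inputs, *task.required_outputs]:
            if met_id not in exch_by_met:
                raise ConfigurationError(
                    f"task {task.task_id}: metabolite {met_id!r} has no exchange "
                    f"reaction in {model.species_id}"
                )
        # close all uptakes except the allowed inputs
        saved = {}
        for met_id, rxn in exch_by_met.items():
            saved[rxn.id] = (rxn.lower_bound, rxn.upper_bound)
            if met_id not in task.required_inputs:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
        try:
            ok = True
            for met_id in task.required_outputs:
                sol = solve_fba(model, exch_by_met[met_id].id, "max")
                if not sol.optimal or sol.objective_value <= STEADY_STATE_TOL:
                    # unbounded export still demonstrates producibility
                    if sol.status != "unbounded":
                        ok = False
                        break
            results[task.task_id] = ok
        finally:
            for rid, (lb, ub) in saved.items():
                rxn = model.reaction(rid)
                rxn.lower_bound, rxn.upper_bound = lb, ub
    return results
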