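"""Independent LP oracles for cross-checking the package's solvers.

Two routes, both independent of scipy's HiGHS (the implementation path):

* :func:`enumerate_lp` — exhaustive basic-feasible-solution enumeration
  for tiny LPs (the optimum of a bounded feasible LP is attained at a
  basic solution: a maximal linearly independent set of columns solves
  the equalities with every other variable at a finite bound).
* :func:`glpk_solve` — the GLPK simplex code through optlang, an
  entirely separate LP implementation.
"""

from itertools import combinations, product

import numpy as np


def enumerate_lp(c, A_eq, bounds, sense="min", tol=1e-9):
    """Brute-force optimum of  opt c'x  s.t.  A_eq x = 0,  l <= x <= u.

    Enumerates every choice of basic columns (size = rank of A_eq) and
    every assignment of the remaining variables to a finite bound.
    Suitable only for ~12 columns or fewer.  Returns (x*, objective) or
    (None, None) if infeasible.
    """
    c = np.asarray(c, dtype=float)
    A = np.atleast_2d(np.asarray(A_eq, dtype=float))
    n = A.shape[1]
    r = np.linalg.matrix_rank(A)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)

    best_x, best_obj = None, None
    sign = 1.0 if sense == "min" else -1.0
    for basic in combinations(range(n), r):
        B = A[:, basic]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        # each nonbasic variable sits at one of its finite bounds
        choices = []
        ok = True
        for j in nonbasic:
            opts = [v for v in (lo[j], hi[j]) if np.isfinite(v)]
            if not opts:
                ok = False
                break
            choices.append(sorted(set(opts)))
        if not ok:
            continue
        for assignment in product(*choices):
            x = np.empty(n)
            for j, v in zip(nonbasic, assignment):
                x[j] = v
            rhs = -A[:, nonbasic] @ np.array(assignment) if nonbasic else np.zeros(A.shape[0])
            xb, residuals, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if np.linalg.norm(A[:, basic] @ xb - rhs) > tol:
                continue
            for idx, j in enumerate(basic):
                x[j] = xb[idx]
            if (x < lo - tol).any() or (x > hi + tol).any():
                continue
            if np.abs(A @ x).max() > tol:
                continue
            obj = float(c @ x)
            if best_obj is None or sign * obj < sign * best_obj - 1e-15:
                best_obj, best_x = obj, x.copy()
    return best_x, best_obj


def glpk_solve(c, A_eq, bounds, sense="min", A_ub=None, b_ub=None):
    """Solve an LP with GLPK (optlang interface). Returns (status, obj, x)."""
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    c = np.asarray(c, dtype=float)
    A = np.atleast_2d(np.asarray(A_eq, dtype=float))
    n = A.shape[1]
    xs = []
    for j, (lb, ub) in enumerate(bounds):
        xs.append(Variable(f"x{j}",
                           lb=None if not np.isfinite(lb) else lb,
                           ub=None if not np.isfinite(ub) else ub))
    m = Model()
    cons = []
    for i in range(A.shape[0]):
        expr = sum(float(A[i, j]) * xs[j] for j in range(n) if A[i, j] != 0)
        if isinstance(expr, (int, float)):
            continue
        cons.append(Constraint(expr, lb=0, ub=0))
    if A_ub is not None:
        A_ub = np.atleast_2d(np.asarray(A_ub, dtype=float))
        for i in range(A_ub.shape[0]):
            expr = sum(float(A_ub[i, j]) * xs[j] for j in range(n) if A_ub[i, j] != 0)
            if isinstance(expr, (int, float)):
                continue
            cons.append(Constraint(expr, ub=float(b_ub[i])))
    m.add(cons)
    obj_expr = sum(float(c[j]) * xs[j] for j in range(n) if c[j] != 0)
    m.objective = Objective(obj_expr, direction="min" if sense == "min" else "max")
    status = m.optimize()
    if status != "optimal":
        return status, None, None
    x = np.array([v.primal for v in xs])
    return status, float(c @ x), x


def alpha_objective_glpk(model, abundances, diet):
    """Independent computation of the alpha-problem optimum.

    Rebuilds the LP from the community matrix and the documented
    semantics (biomass fixed to abundance, member bounds scaled by
    abundance, dietary draws capped by availability, free metabolites
    unbounded) and solves it with GLPK.
    """
    bounds = []
    c = np.zeros(model.n_cols)
    for j, lab in enumerate(model.col_labels):
        if lab[0] == "member":
            gem = model.members[lab[1]][0]
            x_s = abundances.get(gem.species_id, 0.0)
            rxn = gem.reaction(lab[2])
            if rxn.id == gem.biomass_reaction_id:
                bounds.append((x_s, x_s))
            else:
                bounds.append((rxn.lower_bound * x_s, rxn.upper_bound * x_s))
        elif lab[0] == "diet":
            met = lab[1]
            if met in model.free_ids:
                bounds.append((0.0, np.inf))
            else:
                bounds.append((0.0, float(diet.get(met, 0.0))))
                if met in diet:
                    c[j] = 1.0
        else:
            bounds.append((0.0, np.inf))
    status, obj, _ = glpk_solve(c, model.community_matrix.toarray(), bounds, "min")
    return status, obj


def beta_objective_glpk(model, diet, fixed_uptake):
    """Independent computation of the beta-problem optimum via GLPK."""
    bounds = []
    c = np.zeros(model.n_cols)
    for j, lab in enumerate(model.col_labels):
        if lab[0] == "member":
            gem = model.members[lab[1]][0]
            rxn = gem.reaction(lab[2])
            bounds.append((rxn.lower_bound, rxn.upper_bound))
            if rxn.id == gem.biomass_reaction_id:
                c[j] = 1.0
        elif lab[0] == "diet":
            met = lab[1]
            if met in fixed_uptake:
                bounds.append((float(fixed_uptake[met]), float(fixed_uptake[met])))
            elif met in model.free_ids:
                bounds.append((0.0, np.inf))
            else:
                bounds.append((0.0, float(diet.get(met, 0.0))))
        else:
            # fixed uptake means consumed, not passed through
            if lab[1] in fixed_uptake:
                bounds.append((0.0, 0.0))
            else:
                bounds.append((0.0, np.inf))
    status, obj, _ = glpk_solve(c, model.community_matrix.toarray(), bounds, "max")
    return status, obj
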