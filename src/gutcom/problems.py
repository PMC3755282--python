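"""The two community optimization problems.

* **alpha-problem** — given the diet and the biomass concentration of
  every species, predict the community secretion profile: fix each
  member's biomass-reaction flux to its measured abundance and minimize
  the total dietary substrate draw.
* **beta-problem** — given the diet, predict the species abundances and
  the secretion profile: fix the uptake of the stated substrate(s) and
  maximize the summed community biomass.

Both are linear programs over the community matrix in concentration
units (umol/g cecal; biomass in mg DW/g cecal).  Alternative optima in
the secretion vector are resolved by a second lexicographic stage that
minimizes total lumen secretion at the optimal primary objective, so
reported profiles are reproducible.

The module follows the estimator/results convention: build an
:class:`AlphaProblem` or :class:`BetaProblem` from the data, call
``fit()``, inspect the returned results object (``summary()``,
``secretion``, ``abundances`` ...).  ``solve_alpha`` / ``solve_beta``
are functional shortcuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityModel, SecretionProfile, apply_absorption
from .core import ConfigurationError, FluxDistribution, ValidationError
from .fba import STEADY_STATE_TOL, solve_lp

__all__ = [
    "AlphaProblem",
    "BetaProblem",
    "AlphaResults",
    "BetaResults",
    "solve_alpha",
    "solve_beta",
    "split_substrate",
]

_INF = np.inf
_TOL = 1e-9


# ---------------------------------------------------------------------------
# shared LP assembly


def _diet_bounds(model: CommunityModel, diet: dict[str, float]) -> dict[str, tuple[float, float]]:
    # diet metabolites no member can access are simply inaccessible and
    # are ignored (a feed is a property of the environment, not the model)
    for met, avail in diet.items():
        if avail < 0:
            raise ValidationError(f"diet availability for {met} must be >= 0")
    out = {}
    for met in model.lumen_metabolites:
        if met in model.free_ids:
            out[met] = (0.0, _INF)
        else:
            out[met] = (0.0, float(diet.get(met, 0.0)))
    return out


def _share_cap_rows(model: CommunityModel, diet: dict[str, float]):
    """Inequality rows capping each member's consumption of each dietary
    substrate at share x availability.  Exact because toy substrate
    consumers are irreversible (consumption-only columns)."""
    if not model.substrate_shares:
        return None, None
    shares = model.substrate_shares
    total = sum(shares.values())
    if total > 1.0 + _TOL or any(s < 0 for s in shares.values()):
        raise ValidationError(f"substrate shares must be >= 0 and sum <= 1, got {shares}")
    M = model.community_matrix.tocsc()
    rows, rhs = [], []
    for sp, share in shares.items():
        i, _ = model.member(sp)
        cols = model.member_columns(i)
        for met, avail in diet.items():
            if met in model.free_ids:
                continue
            r = model.lumen_row(met)
            row = np.zeros(model.n_cols)
            for j in cols:
                coef = M[r, j]
                if coef < 0:
                    row[j] = -coef
            if row.any():
                rows.append(row)
                rhs.append(share * float(avail))
    if not rows:
        return None, None
    return np.array(rows), np.array(rhs)


def _two_stage(model, c1, sense1, bounds, A_ub=None, b_ub=None):
    """Optimize c1, then minimize total non-free secretion at that optimum."""
    S = model.community_matrix.toarray()
    b_eq = np.zeros(model.n_rows)
    x, z1, status = solve_lp(c1, S, b_eq, bounds, sense=sense1,
                             A_ub=A_ub, b_ub=b_ub)
    if status != "optimal":
        return None, np.nan, status
    c2 = np.zeros(model.n_cols)
    for j, lab in enumerate(model.col_labels):
        if lab[0] == "secr" and lab[1] not in model.free_ids:
            c2[j] = 1.0
    # pin the primary objective with a one-sided slack
    sign = 1.0 if sense1 == "min" else -1.0
    A2 = np.vstack([A_ub, sign * np.asarray(c1)[None, :]]) if A_ub is not None \
        else sign * np.asarray(c1)[None, :]
    b2 = np.concatenate([b_ub, [sign * z1 + 1e-9 * max(1.0, abs(z1))]]) if b_ub is not None \
        else np.array([sign * z1 + 1e-9 * max(1.0, abs(z1))])
    res = __import__("scipy.optimize", fromlist=["linprog"]).linprog(
        c2, A_ub=A2, b_ub=b2, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 0:
        x = res.x
    resid = np.abs(S @ x).max()
    if resid > STEADY_STATE_TOL:
        raise RuntimeError(f"steady-state residual {resid:.2e} exceeds tolerance")
    return x, z1, "optimal"


def _flux_distribution(model: CommunityModel, x, objective) -> FluxDistribution:
    fluxes = {}
    for j, lab in enumerate(model.col_labels):
        if lab[0] == "member":
            gem, prefix = model.members[lab[1]]
            fluxes[prefix + lab[2]] = float(x[j])
        elif lab[0] == "diet":
            fluxes[f"DIET_{lab[1]}"] = float(x[j])
        else:
            fluxes[f"SECR_{lab[1]}"] = float(x[j])
    return FluxDistribution(fluxes=fluxes, objective_value=objective, status="optimal")


def _secretion_from_solution(model, x, absorption, diet):
    cpos = model.column_index()
    raw = {}
    for met in model.lumen_metabolites:
        if met in model.free_ids:
            continue
        raw[met] = max(float(x[cpos[("secr", met)]]), 0.0)
    M = model.community_matrix.tocsc()
    lumen = set(model.lumen_metabolites)
    consumed: dict[str, dict[str, float]] = {}
    for i, (gem, _) in enumerate(model.members):
        per = {}
        for met in diet:
            if met in model.free_ids or met not in lumen:
                continue
            r = model.lumen_row(met)
            tot = 0.0
            for j in model.member_columns(i):
                coef = M[r, j]
                if coef < 0:
                    tot += -coef * x[j]
            per[met] = float(tot)
        consumed[gem.species_id] = per
    totals = {sp: sum(v.values()) for sp, v in consumed.items()}
    profile = apply_absorption(raw, absorption, substrate_consumed=totals)
    return profile, consumed


# ---------------------------------------------------------------------------
# alpha


@dataclass
class AlphaSolution:
    secretion: SecretionProfile | None
    substrate_consumed: dict[str, dict[str, float]]
    flux: FluxDistribution | None
    objective_value: float
    status: str
    infeasible_species: list[str] = field(default_factory=list)


class AlphaResults:
    """Results of a fitted alpha-problem."""

    def __init__(self, problem: "AlphaProblem", solution: AlphaSolution):
        self.problem = problem
        self.model = problem.model
        self.secretion = solution.secretion
        self.substrate_consumed = solution.substrate_consumed
        self.flux = solution.flux
        self.objective_value = solution.objective_value
        self.status = solution.status
        self.infeasible_species = solution.infeasible_species

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def summary(self) -> str:
        lines = ["alpha-problem (diet + abundances -> secretion)",
                 "=" * 48,
                 f"status:               {self.status}"]
        if not self.optimal:
            if self.infeasible_species:
                lines.append(f"infeasible species:   {', '.join(self.infeasible_species)}")
            return "\n".join(lines)
        lines += [
            f"total substrate draw: {self.objective_value:.4f} umol/g cecal",
            "",
            "abundances (fixed, mg DW/g cecal):",
        ]
        for sp, x in self.problem.abundances.items():
            lines.append(f"  {sp:<8} {x:.4f}")
        lines += ["", "secretion profile (umol/g cecal):",
                  "  metabolite   produced   absorbed      fecal"]
        for _, row in self.secretion.to_frame().iterrows():
            lines.append(f"  {row.metabolite:<10} {row.produced:>9.4f} "
                         f"{row.absorbed:>10.4f} {row.fecal:>10.4f}")
        lines += ["", "dietary substrate consumed per species (umol/g cecal):"]
        for sp, per in self.substrate_consumed.items():
            per_s = ", ".join(f"{m}={v:.4f}" for m, v in per.items())
            lines.append(f"  {sp:<8} {per_s}")
        return "\n".join(lines)


class AlphaProblem:
    """Minimize dietary substrate draw at fixed species abundances.

    Parameters
    ----------
    model : CommunityModel
    abundances : {species_id: mg DW/g cecal}; every listed species must
        be a community member; members not listed default to 0.
    diet : {lumen metabolite: available umol/g cecal}.
    absorption : {metabolite: absorbed fraction in [0,1]}.
    """

    def __init__(self, model: CommunityModel, abundances: dict[str, float],
                 diet: dict[str, float], absorption: dict[str, float] | None = None):
        self.model = model
        self.abundances = dict(abundances)
        self.diet = dict(diet)
        self.absorption = dict(absorption or {})
        for sp, x in self.abundances.items():
            model.member(sp)  # raises ConfigurationError if unknown
            if x < 0:
                raise ValidationError(f"abundance of {sp} must be >= 0")

    def _bounds(self, abundances: dict[str, float]):
        model = self.model
        dietb = _diet_bounds(model, self.diet)
        bounds: list[tuple[float, float]] = []
        for lab in model.col_labels:
            if lab[0] == "member":
                i = lab[1]
                gem = model.members[i][0]
                x_s = abundances.get(gem.species_id, 0.0)
                rxn = gem.reaction(lab[2])
                if rxn.id == gem.biomass_reaction_id:
                    bounds.append((x_s, x_s))
                else:
                    bounds.append((rxn.lower_bound * x_s, rxn.upper_bound * x_s))
            elif lab[0] == "diet":
                bounds.append(dietb[lab[1]])
            else:
                bounds.append((0.0, _INF))
        return bounds

    def _objective(self):
        c = np.zeros(self.model.n_cols)
        for j, lab in enumerate(self.model.col_labels):
            if lab[0] == "diet" and lab[1] in self.diet and lab[1] not in self.model.free_ids:
                c[j] = 1.0
        return c

    def fit(self) -> AlphaResults:
        model = self.model
        bounds = self._bounds(self.abundances)
        A_ub, b_ub = _share_cap_rows(model, self.diet)
        x, z, status = _two_stage(model, self._objective(), "min", bounds, A_ub, b_ub)
        if status != "optimal":
            bad = self._diagnose() if status == "infeasible" else []
            sol = AlphaSolution(None, {}, None, np.nan, status, bad)
            return AlphaResults(self, sol)
        profile, consumed = _secretion_from_solution(model, x, self.absorption, self.diet)
        flux = _flux_distribution(model, x, z)
        sol = AlphaSolution(profile, consumed, flux, float(z), "optimal")
        return AlphaResults(self, sol)

    def _diagnose(self) -> list[str]:
        """Identify species whose abundance alone is unachievable."""
        bad = []
        for sp, x_s in self.abundances.items():
            if x_s == 0:
                continue
            solo = {sp: x_s}
            bounds = self._bounds(solo)
            S = self.model.community_matrix.toarray()
            _, _, status = solve_lp(np.zeros(self.model.n_cols), S,
                                    np.zeros(self.model.n_rows), bounds)
            if status != "optimal":
                bad.append(sp)
        return bad


# ---------------------------------------------------------------------------
# beta


@dataclass
class BetaSolution:
    abundances: dict[str, float]
    secretion: SecretionProfile | None
    flux: FluxDistribution | None
    objective_value: float
    status: str


class BetaResults:
    """Results of a fitted beta-problem."""

    def __init__(self, problem: "BetaProblem", solution: BetaSolution):
        self.problem = problem
        self.model = problem.model
        self.abundances = solution.abundances
        self.secretion = solution.secretion
        self.flux = solution.flux
        self.objective_value = solution.objective_value
        self.status = solution.status

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def total_dietary_draw(self) -> float:
        return sum(v for k, v in self.flux.fluxes.items()
                   if k.startswith("DIET_") and
                   k.removeprefix("DIET_") not in self.model.free_ids)

    def summary(self) -> str:
        lines = ["beta-problem (diet -> abundances + secretion)",
                 "=" * 48,
                 f"status:              {self.status}"]
        if not self.optimal:
            return "\n".join(lines)
        lines += [f"total biomass:       {self.objective_value:.4f} mg DW/g cecal",
                  "",
                  "predicted abundances (mg DW/g cecal):"]
        for sp, x in self.abundances.items():
            lines.append(f"  {sp:<8} {x:.4f}")
        lines += ["", "secretion profile (umol/g cecal):",
                  "  metabolite   produced   absorbed      fecal"]
        for _, row in self.secretion.to_frame().iterrows():
            lines.append(f"  {row.metabolite:<10} {row.produced:>9.4f} "
                         f"{row.absorbed:>10.4f} {row.fecal:>10.4f}")
        return "\n".join(lines)


class BetaProblem:
    """Maximize total community biomass at fixed substrate uptake.

    ``fixed_uptake`` pins the dietary draw of the stated substrates
    (umol/g cecal); remaining diet metabolites stay capped by their
    availability.
    """

    def __init__(self, model: CommunityModel, diet: dict[str, float],
                 fixed_uptake: dict[str, float],
                 absorption: dict[str, float] | None = None):
        self.model = model
        self.diet = dict(diet)
        self.fixed_uptake = dict(fixed_uptake)
        self.absorption = dict(absorption or {})
        for met, val in self.fixed_uptake.items():
            if met not in self.diet:
                raise ValidationError(f"fixed uptake metabolite {met!r} is not a diet substrate")
            if val > self.diet[met] + _TOL:
                raise ValidationError(
                    f"fixed uptake of {met} ({val}) exceeds diet availability "
                    f"({self.diet[met]})"
                )
            if val < 0:
                raise ValidationError(f"fixed uptake of {met} must be >= 0")

    def _bounds(self):
        model = self.model
        dietb = _diet_bounds(model, self.diet)
        bounds = []
        for lab in model.col_labels:
            if lab[0] == "member":
                gem = model.members[lab[1]][0]
                rxn = gem.reaction(lab[2])
                bounds.append((rxn.lower_bound, rxn.upper_bound))
            elif lab[0] == "diet":
                met = lab[1]
                if met in self.fixed_uptake:
                    v = float(self.fixed_uptake[met])
                    bounds.append((v, v))
                else:
                    bounds.append(dietb[met])
            else:
                # fixed uptake means consumed: the drawn substrate may not
                # simply flow back out of the lumen
                if lab[1] in self.fixed_uptake:
                    bounds.append((0.0, 0.0))
                else:
                    bounds.append((0.0, _INF))
        return bounds

    def fit(self) -> BetaResults:
        model = self.model
        c = np.zeros(model.n_cols)
        for j, lab in enumerate(model.col_labels):
            if lab[0] == "member":
                gem = model.members[lab[1]][0]
                if lab[2] == gem.biomass_reaction_id:
                    c[j] = 1.0
        A_ub, b_ub = _share_cap_rows(model, self.diet)
        x, z, status = _two_stage(model, c, "max", self._bounds(), A_ub, b_ub)
        if status != "optimal":
            return BetaResults(self, BetaSolution({}, None, None, np.nan, status))
        cpos = model.column_index()
        abundances = {}
        for gem, _ in model.members:
            j = cpos[("member", model.member(gem.species_id)[0], gem.biomass_reaction_id)]
            abundances[gem.species_id] = float(x[j])
        profile, _ = _secretion_from_solution(model, x, self.absorption, self.diet)
        flux = _flux_distribution(model, x, z)
        return BetaResults(self, BetaSolution(abundances, profile, flux, float(z), "optimal"))


# ---------------------------------------------------------------------------
# functional interface


def solve_alpha(model: CommunityModel, abundances: dict[str, float],
                diet: dict[str, float],
                absorption: dict[str, float] | None = None) -> AlphaResults:
    """Solve the alpha-problem; see :class:`AlphaProblem`."""
    return AlphaProblem(model, abundances, diet, absorption).fit()


def solve_beta(model: CommunityModel, diet: dict[str, float],
               fixed_uptake: dict[str, float],
               absorption: dict[str, float] | None = None) -> BetaResults:
    """Solve the beta-problem; see :class:`BetaProblem`."""
    return BetaProblem(model, diet, fixed_uptake, absorption).fit()


def split_substrate(model: CommunityModel, shares: dict[str, float]) -> CommunityModel:
    """Return a community whose members' dietary substrate consumption is
    capped at share x availability (umol/g cecal)."""
    if any(s < 0 for s in shares.values()):
        raise ValidationError("substrate shares must be >= 0")
    if sum(shares.values()) > 1.0 + _TOL:
        raise ValidationError(f"substrate shares sum to {sum(shares.values())} > 1")
    for sp in shares:
        model.member(sp)
    return model.with_shares(shares)
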