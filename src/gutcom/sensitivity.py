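"""Robustness and optimization scans.

The sensitivity coefficient S measures how strongly a prediction depends
on a measured constraint: the mean over a perturbation grid of
(relative output change) / (relative constraint change).  Because both
community problems are linear programs whose only inhomogeneous
constraints are the perturbed ones (away from binding diet caps), S is
1 exactly — a relative error in the measured biomass propagates one-to-
one into the predicted SCFA concentrations.

Also provides the butyrate optimization scans: varying acetate/glucan
availability for the butyrate producer, and varying the
saccharolytic:butyrogenic abundance ratio in a two-species community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityModel, build_community
from .core import GEM, ConfigurationError
from .problems import AlphaProblem, BetaProblem

__all__ = [
    "SensitivityResult",
    "sensitivity_coefficient",
    "scan_butyrate_uptake",
    "scan_abundance_ratio",
    "DEFAULT_DELTAS",
]

#: Symmetric default perturbation grid (relative changes).
DEFAULT_DELTAS = (-0.2, -0.1, 0.1, 0.2)

_SCFA = ("ac", "prop", "but")


@dataclass
class SensitivityResult:
    baseline: float
    grid: pd.DataFrame          # columns: delta, constraint_value, output, feasible
    S: float                    # mean relative-change ratio; NaN if undefined
    constraint: str
    output: str
    excluded: list[float] = field(default_factory=list)


def _output_value(results, output: str) -> float:
    if output == "objective":
        return float(results.objective_value)
    if output == "total_scfa":
        return float(sum(results.secretion.produced.get(m, 0.0) for m in _SCFA))
    if output == "biomass":
        return float(sum(results.abundances.values()))
    if output.startswith("secretion:"):
        return float(results.secretion.produced.get(output.split(":", 1)[1], 0.0))
    raise ConfigurationError(f"unknown output identifier {output!r}")


def sensitivity_coefficient(
    problem: str,
    model: CommunityModel,
    constraint: str,
    deltas=DEFAULT_DELTAS,
    output: str = "total_scfa",
    *,
    abundances: dict[str, float] | None = None,
    diet: dict[str, float],
    absorption: dict[str, float] | None = None,
    fixed_uptake: dict[str, float] | None = None,
) -> SensitivityResult:
    """Perturb one constraint by each relative delta and re-solve.

    ``problem`` is "alpha" or "beta".  Constraint identifiers:

    * "biomass" — scale all fixed abundances (alpha);
    * "abundance:<species>" — scale one species' abundance (alpha);
    * "uptake:<metabolite>" — scale one fixed uptake (beta); "glucan" is
      shorthand for "uptake:glucan".

    Output identifiers: "objective", "total_scfa", "biomass",
    "secretion:<metabolite>".  Infeasible grid points are flagged and
    excluded from S; S is NaN when the baseline output is 0.
    """
    if problem not in ("alpha", "beta"):
        raise ConfigurationError(f"problem must be 'alpha' or 'beta', got {problem!r}")

    def solve(scale_map) -> object:
        if problem == "alpha":
            ab = dict(abundances or {})
            for sp in ab:
                ab[sp] *= scale_map.get(sp, scale_map.get("*", 1.0))
            return AlphaProblem(model, ab, diet, absorption).fit()
        fu = dict(fixed_uptake or {})
        for met in fu:
            fu[met] *= scale_map.get(met, scale_map.get("*", 1.0))
        return BetaProblem(model, diet, fu, absorption).fit()

    if problem == "alpha":
        if constraint == "biomass":
            target = "*"
        elif constraint.startswith("abundance:"):
            target = constraint.split(":", 1)[1]
            if target not in (abundances or {}):
                raise ConfigurationError(f"no baseline abundance for {target!r}")
        else:
            raise ConfigurationError(f"alpha constraint {constraint!r} not recognized")
    else:
        target = "glucan" if constraint == "glucan" else constraint.split(":", 1)[-1]
        if target not in (fixed_uptake or {}):
            raise ConfigurationError(f"no fixed uptake for {target!r}")

    base = solve({})
    if not base.optimal:
        raise ConfigurationError("baseline problem infeasible")
    y0 = _output_value(base, output)

    rows, ratios, excluded = [], [], []
    for d in deltas:
        res = solve({target: 1.0 + d})
        feasible = res.optimal
        y = _output_value(res, output) if feasible else np.nan
        rows.append((d, 1.0 + d, y, feasible))
        if not feasible:
            excluded.append(d)
        elif y0 > 0:
            ratios.append(((y - y0) / y0) / d)
    grid = pd.DataFrame(rows, columns=["delta", "constraint_scale", "output", "feasible"])
    S = float(np.mean(ratios)) if (ratios and y0 > 0) else float("nan")
    return SensitivityResult(baseline=y0, grid=grid, S=S,
                             constraint=constraint, output=output, excluded=excluded)


def scan_butyrate_uptake(
    model: GEM,
    acetate_range,
    glucan_range,
    absorption: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Growth-maximizing scan for the butyrate producer.

    For each (acetate cap, glucan cap) grid point, maximize biomass with
    dietary availability capped at those values and record the biomass
    and the butyrate produced.  Returns a DataFrame with columns
    acetate, glucan, biomass, butyrate, feasible.
    """
    acetate_range = list(acetate_range)
    glucan_range = list(glucan_range)
    if not acetate_range or not glucan_range:
        raise ConfigurationError("scan ranges must be non-empty")
    if any(v < 0 for v in [*acetate_range, *glucan_range]):
        raise ConfigurationError("scan range values must be >= 0")
    shared = [m.id for m in model.metabolites
              if m.compartment == "e" and m.id != "biomass"]
    com = build_community([model], shared=shared)
    rows = []
    for g in glucan_range:
        for a in acetate_range:
            diet = {"glucan": float(g), "ac": float(a)}
            res = BetaProblem(com, diet, {}, absorption).fit()
            if res.optimal:
                rows.append((a, g, res.objective_value,
                             res.secretion.produced.get("but", 0.0), True))
            else:
                rows.append((a, g, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["acetate", "glucan", "biomass", "butyrate", "feasible"])


def scan_abundance_ratio(
    model: CommunityModel,
    ratios,
    diet: dict[str, float],
    absorption: dict[str, float] | None = None,
    producer: str = "ere",
    partner: str = "bth",
) -> pd.DataFrame:
    """Butyrate output across saccharolytic:butyrogenic abundance ratios.

    ``ratios`` is an iterable of (partner_abundance, producer_abundance)
    pairs, e.g. (x_bth, x_ere).  The alpha-problem is solved per pair;
    infeasible pairs are flagged.  Returns columns x_<partner>,
    x_<producer>, butyrate_produced, butyrate_fecal, feasible.
    """
    rows = []
    for x_p, x_q in ratios:
        res = AlphaProblem(model, {partner: float(x_p), producer: float(x_q)},
                           diet, absorption).fit()
        if res.optimal:
            rows.append((x_p, x_q, res.secretion.produced.get("but", 0.0),
                         res.secretion.fecal.get("but", 0.0), True))
        else:
            rows.append((x_p, x_q, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=[f"x_{partner}", f"x_{producer}",
                                       "butyrate_produced", "butyrate_fecal", "feasible"])
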