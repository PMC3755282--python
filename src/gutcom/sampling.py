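"""Random sampling of the steady-state flux polytope and
transcriptional-regulation calls.

The feasible set {v : S v = 0, l <= v <= u} is parametrized on an
orthonormal basis of the null space of S (with fixed fluxes folded into
the affine offset) and sampled with artificial-centering hit-and-run:
directions are drawn towards previously accepted samples relative to
their running center, which adapts the proposal to elongated polytopes.
Warm-up samples are discarded and the chain is thinned.

Between two conditions (for example mono- versus co-colonization, with
exchange fluxes pinned to the respective alpha-problem solutions), a
reaction's flux change is scored as P(v_b > v_a) over paired samples; a
reaction is called *transcriptionally* regulated when both the flux
change and the gene-expression change mapped through its gene rule are
significant and concordant in sign, and *metabolically* regulated when
the flux changes without expression support.
"""

from __future__ import annotations

import ast
import hashlib
import json
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .core import GEM, ConfigurationError, ValidationError
from .reporter import ExpressionTable, bh_correct

__all__ = [
    "FluxSample",
    "prepare_sampling_model",
    "sample_fluxes",
    "classify_regulation",
]

_FEAS_TOL = 1e-6


def prepare_sampling_model(
    model: GEM,
    exchange_fluxes: dict[str, float],
    band: float = 0.05,
) -> GEM:
    """Constrain a model for sampling.

    Internal reversible reaction bounds are relaxed to +/-inf (removing
    the arbitrary +/-1000 box, which otherwise shapes the sampled
    distribution); exchange reactions named in ``exchange_fluxes`` are
    pinned to the given value within a relative band of +/-``band``
    (default 5%), keeping the polytope full-dimensional.  Raises
    :class:`ValidationError` naming the binding exchange constraint(s)
    if the result is infeasible.
    """
    import copy

    m = copy.deepcopy(model)
    for rxn in m.reactions:
        if rxn.is_exchange:
            continue
        if rxn.lower_bound < 0:
            rxn.lower_bound = -np.inf
        if rxn.upper_bound > 0:
            rxn.upper_bound = np.inf
    for rid, v in exchange_fluxes.items():
        rxn = m.reaction(rid)
        if not np.isfinite(v):
            raise ValidationError(f"exchange flux for {rid} must be finite")
        lo, hi = sorted((v * (1 - band), v * (1 + band)))
        rxn.lower_bound, rxn.upper_bound = lo, hi

    if not _is_feasible(m):
        binding = []
        for rid in exchange_fluxes:
            probe = copy.deepcopy(m)
            rxn = probe.reaction(rid)
            rxn.lower_bound, rxn.upper_bound = -np.inf, np.inf
            if _is_feasible(probe):
                binding.append(rid)
        raise ValidationError(
            "model infeasible after fixing exchange fluxes; binding "
            f"constraints: {binding or sorted(exchange_fluxes)}"
        )
    return m


def _is_feasible(model: GEM) -> bool:
    S = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(np.zeros(len(bounds)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    return res.status == 0


@dataclass
class FluxSample:
    """A matrix of feasible steady-state flux vectors for one condition."""

    condition: str
    reaction_ids: list[str]
    samples: np.ndarray      # n_samples x n_reactions
    seed: int
    warmup: int
    thin: int
    model_hash: str = ""

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> pd.Series:
        return pd.Series(self.samples.mean(axis=0) if self.n else
                         np.full(len(self.reaction_ids), np.nan),
                         index=self.reaction_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def save(self, prefix: str) -> tuple[str, str]:
        """Persist as <prefix>.tsv plus a <prefix>.json sidecar."""
        tsv, sidecar = f"{prefix}.tsv", f"{prefix}.json"
        self.to_frame().to_csv(tsv, sep="\t", index=False, float_format="%.10g")
        with open(sidecar, "w") as fh:
            json.dump({"condition": self.condition, "seed": self.seed,
                       "n": self.n, "warmup": self.warmup, "thin": self.thin,
                       "model_hash": self.model_hash}, fh, indent=2)
        return tsv, sidecar


def _model_hash(model: GEM) -> str:
    payload = json.dumps(
        [[r.id, sorted(r.stoichiometry.items()),
          repr(r.lower_bound), repr(r.upper_bound)] for r in model.reactions],
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sample_fluxes(
    model: GEM,
    n: int,
    seed: int,
    condition: str = "",
    warmup: int = 1000,
    thin: int = 10,
) -> FluxSample:
    """Artificial-centering hit-and-run over the flux polytope.

    Requires the polytope to be bounded after exchange fixing; unbounded
    directions are detected beforehand and reported with the reactions
    involved.  Deterministic for a given seed.  Every returned sample is
    verified against S v = 0 and the bounds at 1e-6.
    """
    rxn_ids = model.reaction_ids
    nr = len(rxn_ids)
    if n == 0:
        return FluxSample(condition, rxn_ids, np.empty((0, nr)), seed, warmup, thin,
                          _model_hash(model))

    S = model.stoichiometric_matrix()
    lo = np.array([r.lower_bound for r in model.reactions])
    hi = np.array([r.upper_bound for r in model.reactions])
    fixed = np.isclose(lo, hi)

    # particular solution honoring the equalities
    bounds = list(zip(lo, hi))
    res = linprog(np.zeros(nr), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise ValidationError("model infeasible; cannot sample")
    v0 = res.x

    A = np.vstack([S] + [np.eye(nr)[fixed]]) if fixed.any() else S
    N = null_space(A)
    if N.size == 0 or N.shape[1] == 0:
        samples = np.tile(v0, (n, 1))
        return FluxSample(condition, rxn_ids, samples, seed, warmup, thin,
                          _model_hash(model))

    # inequalities in null-space coordinates: G y <= h
    G_rows, h_rows, row_rxn = [], [], []
    for j in range(nr):
        if fixed[j]:
            continue
        nj = N[j]
        if np.abs(nj).max() < 1e-12:
            continue
        if np.isfinite(hi[j]):
            G_rows.append(nj)
            h_rows.append(hi[j] - v0[j])
            row_rxn.append(rxn_ids[j])
        if np.isfinite(lo[j]):
            G_rows.append(-nj)
            h_rows.append(v0[j] - lo[j])
            row_rxn.append(rxn_ids[j])
    G = np.array(G_rows)
    h = np.array(h_rows)
    d = N.shape[1]

    # boundedness: every null-space coordinate must be bounded above and below
    unbounded: set[str] = set()
    for k in range(d):
        for sense in (1.0, -1.0):
            c = np.zeros(d)
            c[k] = sense
            r = linprog(c, A_ub=G, b_ub=h, bounds=[(None, None)] * d, method="highs")
            if r.status == 3:
                mask = np.abs(N[:, k]) > 1e-9
                unbounded |= {rxn_ids[j] for j in np.where(mask)[0]}
    if unbounded:
        raise ValidationError(
            f"flux polytope unbounded along reactions: {sorted(unbounded)}")

    # interior start: Chebyshev center of {G y <= h}
    norms = np.linalg.norm(G, axis=1)
    c = np.zeros(d + 1)
    c[-1] = -1.0
    Ach = np.hstack([G, norms[:, None]])
    r = linprog(c, A_ub=Ach, b_ub=h, bounds=[(None, None)] * d + [(0, None)],
                method="highs")
    if r.status != 0 or r.x[-1] <= 1e-12:
        raise ValidationError("flux polytope has no interior; cannot sample")
    y = r.x[:-1]

    rng = np.random.default_rng(seed)
    total_steps = warmup + n * thin
    kept = np.empty((n, d))
    store: list[np.ndarray] = [y.copy()]
    center = y.copy()
    n_store = 0
    eps = 1e-12
    for step in range(total_steps):
        if n_store < max(2 * d, 10):
            direction = rng.standard_normal(d)
        else:
            pick = store[rng.integers(0, len(store))]
            direction = pick - center
            if np.linalg.norm(direction) < 1e-14:
                direction = rng.standard_normal(d)
        direction /= np.linalg.norm(direction)
        gd = G @ direction
        slack = h - G @ y
        with np.errstate(divide="ignore"):
            ratios = slack / gd
        t_hi = ratios[gd > eps].min(initial=np.inf)
        t_lo = ratios[gd < -eps].max(initial=-np.inf)
        if not (np.isfinite(t_hi) and np.isfinite(t_lo)) or t_hi <= t_lo:
            continue
        y = y + rng.uniform(t_lo, t_hi) * direction
        n_store += 1
        center += (y - center) / (n_store + 1)
        if len(store) < 1000:
            store.append(y.copy())
        else:
            store[rng.integers(0, 1000)] = y.copy()
        if step >= warmup and (step - warmup) % thin == 0:
            kept[(step - warmup) // thin] = y

    V = v0[None, :] + kept @ N.T
    # feasibility assertions on every sample
    resid = np.abs(V @ S.T).max() if S.size else 0.0
    if resid > _FEAS_TOL:
        raise RuntimeError(f"sample steady-state residual {resid:.2e}")
    lo_ok = (V >= lo[None, :] - _FEAS_TOL).all()
    hi_ok = (V <= hi[None, :] + _FEAS_TOL).all()
    if not (lo_ok and hi_ok):
        raise RuntimeError("sampled fluxes violate bounds beyond tolerance")
    V = np.clip(V, lo[None, :], hi[None, :])
    return FluxSample(condition, rxn_ids, V, seed, warmup, thin, _model_hash(model))


# ---------------------------------------------------------------------------
# regulation calls


def _rule_p_direction(rule: str, p_by_gene, dir_by_gene):
    """Map gene-level (p, direction) through a Boolean rule.

    OR picks the most significant branch (min p), AND the least (max p);
    the direction follows the chosen branch.  Genes without data count
    as p = 1 (no evidence).
    """
    tree = ast.parse(rule.replace(" AND ", " and ").replace(" OR ", " or "),
                     mode="eval")

    def ev(node):
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.BoolOp):
            vals = [ev(v) for v in node.values]
            if isinstance(node.op, ast.Or):
                return min(vals, key=lambda t: t[0])
            return max(vals, key=lambda t: t[0])
        if isinstance(node, ast.Name):
            return (p_by_gene.get(node.id, 1.0), dir_by_gene.get(node.id, "up"))
        raise ValidationError(f"unsupported gene rule syntax in {rule!r}")

    return ev(tree)


def classify_regulation(
    a: FluxSample,
    b: FluxSample,
    expr,
    gene_rules: dict[str, str] | GEM,
    flux_band: tuple[float, float] = (0.05, 0.95),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call per-reaction regulation between conditions a and b.

    Flux-change score: P(v_b > v_a) over paired samples (ties count
    half), significant outside ``flux_band``.  Expression change per
    reaction: gene p-values mapped through the gene rule (OR = min p,
    AND = max p), BH-corrected across reactions, significant below
    ``alpha``.  Classes: transcriptionally up-/down-regulated (both
    significant, concordant sign), metabolically regulated (flux only),
    unchanged.  Reactions without a gene rule are flagged and never
    classed transcriptional.
    """
    if a.reaction_ids != b.reaction_ids:
        raise ValidationError("flux samples cover different reaction universes")
    if isinstance(gene_rules, GEM):
        gene_rules = {r.id: r.gene_rule for r in gene_rules.reactions}
    expr = expr if isinstance(expr, ExpressionTable) else ExpressionTable.from_frame(expr)
    p_by_gene = expr.p_map()
    dir_by_gene = expr.direction_map()

    n = min(a.n, b.n)
    va, vb = a.samples[:n], b.samples[:n]
    gt = (vb > va).mean(axis=0)
    ties = (vb == va).mean(axis=0)
    p_up = gt + 0.5 * ties

    rows = []
    for j, rid in enumerate(a.reaction_ids):
        rule = gene_rules.get(rid, "")
        if rule:
            ep, ed = _rule_p_direction(rule, p_by_gene, dir_by_gene)
        else:
            ep, ed = np.nan, ""
        rows.append({
            "reaction": rid,
            "p_flux_up": float(p_up[j]),
            "flux_delta": float(vb[:, j].mean() - va[:, j].mean()),
            "expr_p": ep,
            "expr_direction": ed,
            "has_gene_rule": bool(rule),
        })
    calls = pd.DataFrame(rows)
    with_rule = calls["has_gene_rule"]
    adj = np.full(len(calls), np.nan)
    if with_rule.any():
        adj[with_rule.to_numpy()] = bh_correct(calls.loc[with_rule, "expr_p"])
    calls["expr_p_adj"] = adj

    lo_band, hi_band = flux_band

    def classify(row) -> str:
        flux_sig = row.p_flux_up > hi_band or row.p_flux_up < lo_band
        if not flux_sig:
            return "unchanged"
        flux_dir = "up" if row.p_flux_up > hi_band else "down"
        expr_sig = row.has_gene_rule and np.isfinite(row.expr_p_adj) \
            and row.expr_p_adj < alpha
        if expr_sig and row.expr_direction == flux_dir:
            return f"transcriptionally {flux_dir}-regulated"
        return "metabolically regulated"

    calls["call"] = calls.apply(classify, axis=1)
    return calls
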