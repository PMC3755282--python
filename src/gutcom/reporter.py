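"""Reporter metabolites and reporter subnetworks.

Scores metabolite neighborhoods of a metabolic network for coordinated
transcriptional change.  Each gene's differential-expression p-value is
converted to a normal score z_g = Phi^-1(1 - p); a metabolite touched by
k scored genes (through the gene rules of the reactions it participates
in) receives

    Z_raw = (1/sqrt(k)) * sum z_g

which is corrected against the background distribution of random size-k
gene sets sampled from the same score pool:

    Z_corrected = (Z_raw - mu_k) / sigma_k,   reporter_p = 1 - Phi(Z_corrected).

Direction classes come from re-running the scoring on one-sided p-value
sets derived from the reported direction of change.  Reporter
subnetworks are connected reaction sets with a high size-normalized
aggregate gene score, found by greedy expansion from top-scoring seed
reactions after removal of highly connected (cofactor-like) metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import GEM, ConfigurationError, ValidationError, genes_in_rule

__all__ = [
    "ExpressionTable",
    "ReporterResult",
    "ReporterAnalysis",
    "Subnetwork",
    "bh_correct",
    "gene_metabolite_map",
    "reporter_metabolites",
    "reporter_subnetworks",
    "P_FLOOR",
]

#: p-values are clamped to [P_FLOOR, 1 - P_FLOOR] before Phi^-1.
P_FLOOR = 1e-15


@dataclass
class ExpressionTable:
    """Gene-level differential expression for one pairwise comparison.

    ``data`` columns: gene, p_value (in (0,1]), direction ("up"/"down"),
    optional lfc.
    """

    data: pd.DataFrame
    comparison: str = ""

    def __post_init__(self) -> None:
        df = self.data
        for col in ("gene", "p_value", "direction"):
            if col not in df.columns:
                raise ValidationError(f"expression table missing column {col!r}")
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()[:5]
            raise ValidationError(f"duplicate gene ids in expression table: {dups}")
        p = df["p_value"].to_numpy(dtype=float)
        if (p <= 0).any() or (p > 1).any():
            raise ValidationError("p-values must lie in (0, 1]")
        bad = set(df["direction"]) - {"up", "down"}
        if bad:
            raise ValidationError(f"directions must be 'up'/'down', got {sorted(bad)}")
        if not self.comparison:
            self.comparison = df.attrs.get("comparison", "")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, comparison: str = "") -> "ExpressionTable":
        return cls(df.reset_index(drop=True), comparison)

    @classmethod
    def from_tsv(cls, path, comparison: str = "") -> "ExpressionTable":
        """Adapter for a DE table exported from any upstream tool; expects
        at least gene/p_value/direction columns (lfc optional)."""
        return cls(pd.read_csv(path, sep="\t"), comparison)

    def p_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene"], self.data["p_value"].astype(float)))

    def direction_map(self) -> dict[str, str]:
        return dict(zip(self.data["gene"], self.data["direction"]))

    def one_sided(self, direction: str) -> dict[str, float]:
        """One-sided p-values for a directional run: a gene changing in
        the requested direction gets p/2, the other direction 1 - p/2."""
        out = {}
        for g, p, d in zip(self.data["gene"], self.data["p_value"], self.data["direction"]):
            out[g] = p / 2 if d == direction else 1 - p / 2
        return out


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_metabolite_map(model: GEM) -> dict[str, frozenset[str]]:
    """Bipartite association: metabolite -> set of genes appearing in the
    gene rule of any reaction whose stoichiometry involves it."""
    out: dict[str, set[str]] = {}
    for rxn in model.reactions:
        genes = rxn.genes()
        if not genes:
            continue
        for met_id in rxn.stoichiometry:
            out.setdefault(met_id, set()).update(genes)
    return {m: frozenset(g) for m, g in out.items()}


def _z_scores(p_by_gene: dict[str, float]) -> dict[str, float]:
    return {g: float(norm.ppf(1.0 - np.clip(p, P_FLOOR, 1 - P_FLOOR)))
            for g, p in p_by_gene.items()}


def _score_metabolites(met_genes, z_by_gene, n_background, rng):
    """Raw and background-corrected reporter scores for every metabolite
    with >= 1 scored gene."""
    pool = np.array(sorted(z_by_gene), dtype=object)
    zpool = np.array([z_by_gene[g] for g in pool])
    rows = {}
    ks = set()
    scored = {}
    for met, genes in met_genes.items():
        gs = sorted(g for g in genes if g in z_by_gene)
        if not gs:
            continue
        k = len(gs)
        scored[met] = (k, sum(z_by_gene[g] for g in gs) / np.sqrt(k))
        ks.add(k)
    # background moments per distinct k from random size-k gene sets
    bg = {}
    for k in sorted(ks):
        idx = rng.integers(0, zpool.size, size=(n_background, k))
        samples = zpool[idx].sum(axis=1) / np.sqrt(k)
        bg[k] = (samples.mean(), samples.std(ddof=1))
    for met, (k, z_raw) in scored.items():
        mu, sd = bg[k]
        if sd > 1e-12:
            zc = (z_raw - mu) / sd
        else:
            # degenerate background (e.g. all p identical): no evidence
            # either way unless the raw score actually differs
            zc = 0.0 if abs(z_raw - mu) <= 1e-12 else np.sign(z_raw - mu) * np.inf
        rows[met] = (k, z_raw, zc, float(norm.sf(zc)))
    return rows


@dataclass
class ReporterResult:
    """Metabolite-level reporter scores, ranked by reporter_p."""

    table: pd.DataFrame  # metabolite, k, z_raw, z_corrected, reporter_p, direction
    comparison: str = ""

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def summary(self) -> str:
        lines = [f"reporter metabolites ({self.comparison or 'unnamed comparison'})",
                 "=" * 56,
                 f"{'metabolite':<14} {'k':>3} {'Z_raw':>8} {'Z_corr':>8} "
                 f"{'reporter_p':>11} direction"]
        for _, r in self.table.head(15).iterrows():
            lines.append(f"{r.metabolite:<14} {r.k:>3d} {r.z_raw:>8.3f} "
                         f"{r.z_corrected:>8.3f} {r.reporter_p:>11.3e} {r.direction}")
        return "\n".join(lines)


class ReporterAnalysis:
    """Reporter-metabolite scoring of an expression table on a GEM.

    Parameters
    ----------
    model : GEM with gene rules.
    expression : ExpressionTable (or a DataFrame with the same columns).
    n_background : random gene sets per distinct k for the background
        correction (default 10000).
    seed : RNG seed; results are deterministic given the seed.
    """

    def __init__(self, model: GEM, expression, n_background: int = 10000,
                 seed: int = 0):
        self.model = model
        self.expression = (expression if isinstance(expression, ExpressionTable)
                           else ExpressionTable.from_frame(expression))
        self.n_background = int(n_background)
        self.seed = int(seed)
        overlap = set(self.expression.data["gene"]) & model.genes
        if not overlap:
            raise ConfigurationError(
                "no overlap between expression table genes and model genes")

    def fit(self) -> ReporterResult:
        met_genes = gene_metabolite_map(self.model)
        rng = np.random.default_rng(self.seed)
        two = _score_metabolites(met_genes, _z_scores(self.expression.p_map()),
                                 self.n_background, rng)
        up = _score_metabolites(met_genes, _z_scores(self.expression.one_sided("up")),
                                self.n_background, np.random.default_rng(self.seed + 1))
        down = _score_metabolites(met_genes, _z_scores(self.expression.one_sided("down")),
                                  self.n_background, np.random.default_rng(self.seed + 2))
        rows = []
        for met, (k, z_raw, zc, rp) in two.items():
            zc_up = up.get(met, (0, 0, -np.inf, 1))[2]
            zc_down = down.get(met, (0, 0, -np.inf, 1))[2]
            if norm.sf(zc_up) < 0.05 and norm.sf(zc_down) < 0.05:
                direction = "both"
            else:
                direction = "up" if zc_up >= zc_down else "down"
            rows.append((met, k, z_raw, zc, min(max(rp, P_FLOOR), 1 - P_FLOOR), direction))
        table = (pd.DataFrame(rows, columns=["metabolite", "k", "z_raw",
                                             "z_corrected", "reporter_p", "direction"])
                 .sort_values(["reporter_p", "metabolite"], kind="mergesort")
                 .reset_index(drop=True))
        return ReporterResult(table=table, comparison=self.expression.comparison)


def reporter_metabolites(model: GEM, expr, n_background: int = 10000,
                         seed: int = 0) -> ReporterResult:
    """Functional shortcut for :class:`ReporterAnalysis`."""
    return ReporterAnalysis(model, expr, n_background=n_background, seed=seed).fit()


# ---------------------------------------------------------------------------
# reporter subnetworks


@dataclass
class Subnetwork:
    reactions: list[str]
    metabolites: list[str]
    score: float
    connected: bool = True

    @property
    def size(self) -> int:
        return len(self.reactions)


def _reaction_graph(model: GEM, removed: set[str]) -> nx.Graph:
    g = nx.Graph()
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        g.add_node(rxn.id)
    by_met: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        for met in rxn.stoichiometry:
            if met in removed:
                continue
            by_met.setdefault(met, []).append(rxn.id)
    for met, rxns in by_met.items():
        for a in rxns:
            for b in rxns:
                if a < b:
                    g.add_edge(a, b, metabolite=met)
    return g


def reporter_subnetworks(
    model: GEM,
    gene_scores: dict[str, float],
    remove_cofactors: list[str] | None = None,
    max_size: int = 10,
    seed: int = 0,
    n_seeds: int = 5,
    score_threshold: float = 2.0,
    hub_fraction: float = 0.10,
    hub_min_count: int = 6,
) -> list[Subnetwork]:
    """Find connected reaction sets with high aggregate gene scores.

    Reactions are scored as the mean of their genes' Z scores; the
    subnetwork objective is sum(score)/sqrt(n).  Search: greedy expansion
    from the ``n_seeds`` top-scoring reactions over the reaction graph
    (reactions adjacent when they share a metabolite, after removing the
    explicit cofactor list plus any metabolite participating in more than
    ``hub_fraction`` of reactions and at least ``hub_min_count`` of
    them); growth stops at ``max_size`` or when
    no neighbor improves the objective.  Overlapping results are merged;
    only subnetworks with objective >= ``score_threshold`` are returned.
    Deterministic for a given seed (ties broken lexicographically).
    """
    for g, z in gene_scores.items():
        if not np.isfinite(z):
            raise ValidationError(f"gene score for {g} is not finite")
    removed = set()
    for met in remove_cofactors or []:
        if model.has_metabolite(met):
            removed.add(met)
        else:
            warnings.warn(f"cofactor id {met!r} not in model; ignored")
    n_internal = sum(1 for r in model.reactions if not r.is_exchange)
    participation: dict[str, int] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        for met in rxn.stoichiometry:
            participation[met] = participation.get(met, 0) + 1
    # automatic hub removal: the fraction rule targets genome-scale
    # networks; the absolute floor keeps tiny toy models intact
    removed |= {m for m, c in participation.items()
                if c > max(hub_fraction * n_internal, hub_min_count - 1)}

    graph = _reaction_graph(model, removed)
    if graph.number_of_nodes() == 0:
        warnings.warn("reaction graph empty after cofactor removal")
        return []

    rxn_score = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        genes = sorted(rxn.genes())
        zs = [gene_scores[g] for g in genes if g in gene_scores]
        rxn_score[rxn.id] = float(np.mean(zs)) if zs else 0.0

    def aggregate(members: set[str]) -> float:
        return sum(rxn_score[r] for r in members) / np.sqrt(len(members))

    seeds = sorted(rxn_score, key=lambda r: (-rxn_score[r], r))[:n_seeds]
    found: list[set[str]] = []
    for s in seeds:
        if rxn_score[s] <= 0:
            continue
        members = {s}
        current = aggregate(members)
        while len(members) < max_size:
            frontier = sorted(
                {nb for m in members for nb in graph.neighbors(m)} - members)
            best, best_score = None, current
            for nb in frontier:
                sc = aggregate(members | {nb})
                if sc > best_score + 1e-12:
                    best, best_score = nb, sc
            if best is None:
                break
            members.add(best)
            current = best_score
        if current >= score_threshold:
            found.append(members)

    # merge overlapping subnetworks
    merged: list[set[str]] = []
    for members in found:
        hit = None
        for existing in merged:
            if existing & members:
                hit = existing
                break
        if hit is None:
            merged.append(set(members))
        else:
            hit |= members
    out = []
    for members in merged:
        mets = sorted({met for r in members
                       for met in model.reaction(r).stoichiometry
                       if met not in removed})
        sub = graph.subgraph(members)
        out.append(Subnetwork(reactions=sorted(members), metabolites=mets,
                              score=aggregate(members),
                              connected=nx.is_connected(sub)))
    out.sort(key=lambda s: (-s.score, s.reactions))
    return out


def subnetwork_edge_list(model: GEM, sub: Subnetwork) -> pd.DataFrame:
    """Edge list (reaction_a, reaction_b, shared metabolite) of a subnetwork."""
    rows = []
    members = set(sub.reactions)
    for met in sub.metabolites:
        touching = [r for r in sub.reactions if met in model.reaction(r).stoichiometry]
        for a in touching:
            for b in touching:
                if a < b and a in members and b in members:
                    rows.append((a, b, met))
    return pd.DataFrame(rows, columns=["reaction_a", "reaction_b", "metabolite"])
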