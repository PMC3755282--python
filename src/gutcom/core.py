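"""Core data model for genome-scale metabolic models (GEMs).

A GEM is a stoichiometric network: metabolites partitioned into
compartments, reactions with flux bounds and Boolean gene rules, and one
designated biomass reaction.  Fluxes of single-species models carry units
of mmol/gDW/h; community-scaled fluxes (see :mod:`gutcom.community`)
carry concentration units of umol per gram of cecal content.

The default flux bound convention is +/-1000 mmol/gDW/h for reversible
reactions and [0, 1000] for irreversible ones; exchange reactions have a
single metabolite with coefficient -1, so positive exchange flux means
secretion into the environment.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "GEM",
    "FluxDistribution",
    "MetabolicTask",
    "ValidationError",
    "ConfigurationError",
    "evaluate_gene_rule",
    "genes_in_rule",
]

#: Default magnitude for unspecified flux bounds (mmol/gDW/h).
DEFAULT_BOUND = 1000.0


class ValidationError(ValueError):
    """A model object violates a structural invariant."""


class ConfigurationError(ValueError):
    """An identifier passed by the caller does not resolve in the model."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.name:
            self.name = self.id

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> frozenset[str]:
        return genes_in_rule(self.gene_rule)


_GENE_TOKEN = re.compile(r"[A-Za-z_][\w.\-]*")
_RULE_KEYWORDS = {"and", "or", "AND", "OR", "And", "Or"}


def genes_in_rule(rule: str) -> frozenset[str]:
    """Gene ids appearing in a Boolean gene-protein-reaction rule."""
    if not rule:
        return frozenset()
    return frozenset(t for t in _GENE_TOKEN.findall(rule) if t not in _RULE_KEYWORDS)


def evaluate_gene_rule(rule: str, active: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR rule as a pure Boolean expression.

    ``active`` is the set of gene ids considered present/on.  An empty
    rule evaluates True (no genetic requirement).
    """
    if not rule:
        return True
    expr = rule
    # longest-first so gene ids that prefix each other substitute safely
    for g in sorted(genes_in_rule(rule), key=len, reverse=True):
        expr = re.sub(rf"(?<![\w.\-]){re.escape(g)}(?![\w.\-])",
                      "True" if g in active else "False", expr)
    expr = re.sub(r"\bAND\b", "and", expr, flags=re.IGNORECASE)
    expr = re.sub(r"\bOR\b", "or", expr, flags=re.IGNORECASE)
    try:
        return bool(eval(expr, {"__builtins__": {}}, {}))  # noqa: S307 - sanitized
    except SyntaxError as exc:
        raise ValidationError(f"malformed gene rule {rule!r}") from exc


@dataclass
class GEM:
    """Single-species genome-scale metabolic model."""

    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str] = field(default_factory=set)
    biomass_reaction_id: str = ""
    maintenance_atp: float | None = None

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError(f"{self.species_id}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError(f"{self.species_id}: duplicate reaction ids")
        if not self.genes:
            self.genes = set().union(*(r.genes() for r in self.reactions)) if self.reactions else set()
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ConfigurationError(f"{self.species_id}: unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ConfigurationError(f"{self.species_id}: unknown reaction {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchanged_metabolite(self, rxn: Reaction) -> str:
        """The single metabolite of an exchange reaction."""
        if not rxn.is_exchange or len(rxn.stoichiometry) != 1:
            raise ValidationError(f"{rxn.id} is not a single-metabolite exchange")
        return next(iter(rxn.stoichiometry))

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ValidationError(
                        f"{self.species_id}: reaction {r.id} references unknown metabolite {met_id!r}"
                    )
            missing = r.genes() - self.genes
            if missing:
                raise ValidationError(
                    f"{self.species_id}: reaction {r.id} gene rule uses unknown genes {sorted(missing)}"
                )
        if self.biomass_reaction_id and self.biomass_reaction_id not in self._rxn_index:
            raise ValidationError(
                f"{self.species_id}: biomass reaction {self.biomass_reaction_id!r} not found"
            )

    # -- matrix view -----------------------------------------------------
    def stoichiometric_matrix(self):
        """Dense stoichiometric matrix S (metabolites x reactions)."""
        import numpy as np

        S = np.zeros((len(self.metabolites), len(self.reactions)))
        mpos = {m: i for i, m in enumerate(self.metabolite_ids)}
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                S[mpos[met_id], j] = coef
        return S

    def element_imbalances(self, tol: float = 1e-9) -> dict[str, dict[str, float]]:
        """Net elemental imbalance of every non-exchange reaction.

        Reactions touching a metabolite without a formula are skipped.
        Returns {reaction_id: {element: net}} for violations only.
        """
        bad: dict[str, dict[str, float]] = {}
        for r in self.reactions:
            if r.is_exchange:
                continue
            if any(self._met_index[m].formula is None for m in r.stoichiometry):
                continue
            net: dict[str, float] = {}
            for met_id, coef in r.stoichiometry.items():
                for el, cnt in (self._met_index[met_id].formula or {}).items():
                    net[el] = net.get(el, 0.0) + coef * cnt
            viol = {el: v for el, v in net.items() if abs(v) > tol}
            if viol:
                bad[r.id] = viol
        return bad

    def summary_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "n_metabolites": len(self.metabolites),
            "n_reactions": len(self.reactions),
            "n_genes": len(self.genes),
            "n_exchanges": len(self.exchange_reactions),
            "biomass_reaction": self.biomass_reaction_id,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2)


@dataclass
class FluxDistribution:
    """Solution of one LP over a stoichiometric model."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class MetabolicTask:
    """A qualitative capability check: with only ``required_inputs`` open
    for uptake, every ``required_outputs`` metabolite must be producible
    at positive flux."""

    task_id: str
    description: str
    required_inputs: list[str]
    required_outputs: list[str]

    def __post_init__(self) -> None:
        if not self.required_outputs:
            raise ValidationError(f"task {self.task_id}: required_outputs must be non-empty")

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetabolicTask":
        return cls(
            task_id=d["task_id"],
            description=d.get("description", ""),
            required_inputs=list(d.get("required_inputs", [])),
            required_outputs=list(d["required_outputs"]),
        )


def load_tasks(path) -> list[MetabolicTask]:
    """Read metabolic tasks from a YAML or JSON file (list of mappings)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Iterable):
        raise ValidationError(f"{path}: expected a list of task mappings")
    return [MetabolicTask.from_dict(d) for d in data]
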