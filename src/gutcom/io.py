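"""SBML input/output and tabular readers.

SBML (Level 2/3, FBC) is read and written through cobrapy; our GEM
dataclasses convert to and from :class:`cobra.Model`.  Reactions whose
bounds are absent in the file receive the +/-1000 mmol/gDW/h default.
Diet, abundance and absorption specifications are plain TSV/YAML.
"""

from __future__ import annotations

import os
import re
from typing import Mapping

import cobra
import pandas as pd

from .core import DEFAULT_BOUND, GEM, Metabolite, Reaction, ValidationError

__all__ = [
    "load_sbml",
    "write_sbml",
    "to_cobra",
    "from_cobra",
    "read_diet_tsv",
    "read_abundance_tsv",
    "read_absorption",
    "write_secretion_tsv",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def _parse_formula(formula: str | None) -> dict[str, float] | None:
    if not formula:
        return None
    out: dict[str, float] = {}
    for el, cnt in _FORMULA_TOKEN.findall(formula):
        out[el] = out.get(el, 0.0) + (float(cnt) if cnt else 1.0)
    return out or None


def _format_formula(formula: Mapping[str, float] | None) -> str:
    if not formula:
        return ""
    parts = []
    for el in sorted(formula):
        cnt = formula[el]
        if cnt == int(cnt):
            cnt_s = "" if cnt == 1 else str(int(cnt))
        else:
            cnt_s = f"{cnt:g}"
        parts.append(f"{el}{cnt_s}")
    return "".join(parts)


def to_cobra(model: GEM) -> cobra.Model:
    """Convert a GEM to a cobra.Model (ids, stoichiometry, bounds, GPRs)."""
    model.validate()
    if not model.reactions:
        raise ValidationError("refusing to write an empty model")
    cm = cobra.Model(model.species_id)
    cmets = {}
    for m in model.metabolites:
        cm_met = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment,
            formula=_format_formula(m.formula) or None,
        )
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({cmets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
        if r.subsystem:
            cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    if model.biomass_reaction_id:
        cm.objective = model.biomass_reaction_id
    return cm


def from_cobra(cm: cobra.Model, species_id: str | None = None) -> GEM:
    """Convert a cobra.Model to a GEM.

    The biomass reaction is taken from the cobra objective when it is a
    single reaction; exchange reactions are detected as single-metabolite
    boundary reactions.
    """
    mets = [
        Metabolite(m.id, name=m.name or m.id, compartment=m.compartment or "c",
                   formula=_parse_formula(m.formula))
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        lb = r.lower_bound if r.lower_bound is not None else -DEFAULT_BOUND
        ub = r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
        rxns.append(Reaction(
            id=r.id,
            name=r.name or r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(lb),
            upper_bound=float(ub),
            gene_rule=r.gene_reaction_rule or "",
            subsystem=r.subsystem or "",
            is_exchange=len(r.metabolites) == 1,
        ))
    biomass = ""
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if len(coeffs) == 1:
            biomass = next(iter(coeffs)).id
    except Exception:
        pass
    return GEM(
        species_id=species_id or cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        genes={g.id for g in cm.genes},
        biomass_reaction_id=biomass,
    )


def load_sbml(path: str | os.PathLike) -> GEM:
    """Read an SBML file (L2/L3, FBC accepted) into a GEM.

    Raises ``FileNotFoundError`` for a missing path and ``ValidationError``
    naming the problem for malformed files or duplicate identifiers.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # libsbml reports the offending element
        raise ValidationError(f"cannot parse SBML file {path!r}: {exc}") from exc
    return from_cobra(cm)


def write_sbml(model: GEM, path: str | os.PathLike) -> str:
    """Write a GEM to SBML L3+FBC; round-trips ids, stoichiometry, bounds
    and gene rules. Refuses structurally invalid or empty models."""
    cm = to_cobra(model)
    path = os.fspath(path)
    cobra.io.write_sbml_model(cm, path)
    return path


# ---------------------------------------------------------------------------
# tabular interfaces


def read_diet_tsv(path) -> dict[str, float]:
    """Diet TSV with columns metabolite_id, value (umol/g cecal)."""
    df = pd.read_csv(path, sep="\t")
    if "metabolite_id" not in df.columns or "value" not in df.columns:
        raise ValidationError(f"{path}: expected columns metabolite_id, value")
    return dict(zip(df["metabolite_id"].astype(str), df["value"].astype(float)))


def read_abundance_tsv(path) -> dict[str, float]:
    """Abundance TSV with columns species_id, value (mg DW/g cecal)."""
    df = pd.read_csv(path, sep="\t")
    if "species_id" not in df.columns or "value" not in df.columns:
        raise ValidationError(f"{path}: expected columns species_id, value")
    return dict(zip(df["species_id"].astype(str), df["value"].astype(float)))


def read_absorption(path) -> dict[str, float]:
    """Absorption fractions from YAML/JSON: {metabolite_id: fraction}."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping metabolite -> fraction")
    return {str(k): float(v) for k, v in data.items()}


def write_secretion_tsv(profile, path) -> None:
    """Write a SecretionProfile as TSV (metabolite, produced, absorbed, fecal)."""
    profile.to_frame().to_csv(path, sep="\t", index=False)
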