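"""Multi-species community models with a shared luminal compartment.

The community stoichiometric matrix is block-diagonal over the member
species' internal metabolites, with the members' extracellular versions
of each shared metabolite merged into a single lumen row.  Member-level
exchange reactions for shared metabolites are removed (their role is
taken over by community-level lumen exchange columns: one dietary-inflow
and one secretion-outflow column per lumen metabolite).

Fluxes of the community model are interpreted in the dilution-rate
formulation: every member flux is a specific rate (mmol/gDW/h) scaled by
that member's biomass concentration (mg DW/g cecal) and divided by the
cecal-content production rate D (normalized to 1/h), so one flux vector
lives entirely in umol/g cecal.  Because mg x mmol/gDW = umol/gDW x mg,
a biomass-reaction flux of x equals a biomass concentration of x mg
DW/g cecal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .core import GEM, ConfigurationError, ValidationError

__all__ = [
    "CommunityModel",
    "SecretionProfile",
    "build_community",
    "convert_abundance",
    "apply_absorption",
    "FREE_EXCHANGE_IDS",
    "E_COLI_CELL_DRY_WEIGHT_G",
]

#: Metabolites freely exchanged with the host environment (water and
#: bicarbonate-buffered CO2): unbounded inflow/outflow, never counted as
#: dietary substrate.
FREE_EXCHANGE_IDS = frozenset({"h2o", "co2"})

#: Total dry weight of one E. coli cell (g), used to convert colonization
#: levels reported as genome equivalents per gram of cecal content.
E_COLI_CELL_DRY_WEIGHT_G = 2.8e-13

_EXTRACELLULAR = {"e", "lumen", "extracellular"}


@dataclass
class SecretionProfile:
    """Per-metabolite produced/absorbed/fecal concentrations (umol/g cecal).

    ``produced`` is the gross community outflow from the lumen after all
    cross-feeding; conservation produced = absorbed + fecal holds exactly.
    """

    produced: dict[str, float]
    absorbed: dict[str, float]
    fecal: dict[str, float]
    substrate_consumed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, p in self.produced.items():
            a = self.absorbed.get(met, 0.0)
            f = self.fecal.get(met, 0.0)
            if p < -1e-9 or a < -1e-9 or f < -1e-9:
                raise ValidationError(f"negative secretion values for {met}")
            if abs(p - (a + f)) > 1e-9 * max(1.0, abs(p)):
                raise ValidationError(
                    f"{met}: produced {p} != absorbed {a} + fecal {f}"
                )

    def to_frame(self) -> pd.DataFrame:
        mets = sorted(self.produced)
        return pd.DataFrame({
            "metabolite": mets,
            "produced": [self.produced[m] for m in mets],
            "absorbed": [self.absorbed.get(m, 0.0) for m in mets],
            "fecal": [self.fecal.get(m, 0.0) for m in mets],
        })


@dataclass
class CommunityModel:
    """Block-combined species networks sharing a luminal compartment."""

    members: list[tuple[GEM, str]]                  # (model, namespace prefix)
    lumen_metabolites: list[str]
    community_matrix: sparse.csr_matrix
    row_labels: list[tuple]       # ("member", i, met_id) | ("lumen", met_id)
    col_labels: list[tuple]       # ("member", i, rxn_id) | ("diet", met) | ("secr", met)
    substrate_ids: set[str] = field(default_factory=set)
    free_ids: frozenset[str] = FREE_EXCHANGE_IDS
    substrate_shares: dict[str, float] | None = None
    dilution_mode: bool = True

    # ------------------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [gem.species_id for gem, _ in self.members]

    def member(self, species_id: str) -> tuple[int, GEM]:
        for i, (gem, _) in enumerate(self.members):
            if gem.species_id == species_id:
                return i, gem
        raise ConfigurationError(f"unknown community member {species_id!r}")

    @property
    def n_rows(self) -> int:
        return self.community_matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.community_matrix.shape[1]

    def column_index(self) -> dict[tuple, int]:
        return {lab: j for j, lab in enumerate(self.col_labels)}

    def member_columns(self, i: int) -> list[int]:
        return [j for j, lab in enumerate(self.col_labels)
                if lab[0] == "member" and lab[1] == i]

    def lumen_row(self, met_id: str) -> int:
        try:
            return self.row_labels.index(("lumen", met_id))
        except ValueError:
            raise ConfigurationError(f"{met_id!r} is not a lumen metabolite") from None

    def with_shares(self, shares: dict[str, float]) -> "CommunityModel":
        return replace(self, substrate_shares=dict(shares))

    def to_json_dump(self) -> dict:
        """Debug dump of the community structure."""
        M = self.community_matrix.tocoo()
        return {
            "members": [{"species": g.species_id, "prefix": p,
                         **g.summary_dict()} for g, p in self.members],
            "lumen_metabolites": list(self.lumen_metabolites),
            "shape": list(self.community_matrix.shape),
            "nnz": int(M.nnz),
            "substrate_shares": self.substrate_shares,
        }


def build_community(
    members: list[GEM],
    shared: set[str] | list[str],
    free_ids: frozenset[str] = FREE_EXCHANGE_IDS,
) -> CommunityModel:
    """Combine member GEMs into a community with a shared lumen.

    ``shared`` lists the extracellular metabolite ids merged into the
    lumen compartment.  Every shared id must exist in the extracellular
    compartment of at least one member.  Member reaction ids are
    namespaced with ``"<species_id>__"``.
    """
    if not members:
        raise ValidationError("community needs at least one member")
    prefixes = [g.species_id + "__" for g in members]
    if len(set(prefixes)) != len(prefixes):
        raise ValidationError("duplicate species ids among community members")

    shared = list(dict.fromkeys(shared))  # stable order
    for met_id in shared:
        found = any(
            g.has_metabolite(met_id)
            and g.metabolite(met_id).compartment in _EXTRACELLULAR
            for g in members
        )
        if not found:
            raise ConfigurationError(
                f"shared metabolite {met_id!r} absent from all members' "
                f"extracellular compartments"
            )
    shared_set = set(shared)
    # lumen rows always include the free metabolites present in any member
    lumen = [m for m in shared]
    for fid in sorted(free_ids):
        if fid not in shared_set and any(g.has_metabolite(fid) for g in members):
            lumen.append(fid)
            shared_set.add(fid)

    # deterministic lumen order: keep caller order, sorted for invariance
    lumen = sorted(lumen)

    row_labels: list[tuple] = []
    for i, gem in enumerate(members):
        for m in gem.metabolites:
            if m.id in shared_set and m.compartment in _EXTRACELLULAR:
                continue
            row_labels.append(("member", i, m.id))
    row_labels += [("lumen", m) for m in lumen]
    rpos = {lab: k for k, lab in enumerate(row_labels)}

    col_labels: list[tuple] = []
    data, ri, ci = [], [], []
    for i, gem in enumerate(members):
        for rxn in gem.reactions:
            if rxn.is_exchange:
                met_id = gem.exchanged_metabolite(rxn)
                if met_id in shared_set:
                    continue  # rewired to community lumen exchange
            j = len(col_labels)
            col_labels.append(("member", i, rxn.id))
            for met_id, coef in rxn.stoichiometry.items():
                comp = gem.metabolite(met_id).compartment
                if met_id in shared_set and comp in _EXTRACELLULAR:
                    row = rpos[("lumen", met_id)]
                else:
                    row = rpos[("member", i, met_id)]
                data.append(coef)
                ri.append(row)
                ci.append(j)
    for met_id in lumen:
        j = len(col_labels)
        col_labels.append(("diet", met_id))
        data.append(1.0)
        ri.append(rpos[("lumen", met_id)])
        ci.append(j)
        col_labels.append(("secr", met_id))
        data.append(-1.0)
        ri.append(rpos[("lumen", met_id)])
        ci.append(j + 1)

    M = sparse.csr_matrix(
        (data, (ri, ci)), shape=(len(row_labels), len(col_labels))
    )
    # merged rows may end up entirely untouched only if a shared id exists
    # but no member reaction uses it; flag that
    for met_id in lumen:
        row = M.getrow(rpos[("lumen", met_id)])
        if row.nnz <= 2:  # only the diet/secretion columns
            raise ConfigurationError(
                f"lumen metabolite {met_id!r} is neither producible nor "
                f"consumable by any member"
            )
    return CommunityModel(
        members=list(zip(members, prefixes)),
        lumen_metabolites=lumen,
        community_matrix=M,
        row_labels=row_labels,
        col_labels=col_labels,
        free_ids=frozenset(free_ids),
    )


def convert_abundance(
    genome_equivalents_per_g: float,
    cell_dry_weight_g: float = E_COLI_CELL_DRY_WEIGHT_G,
) -> float:
    """Convert colonization (genome equivalents/g cecal) to biomass
    concentration (g DW/g cecal), treating one genome equivalent as one
    cell of the given dry weight."""
    if genome_equivalents_per_g < 0 or cell_dry_weight_g < 0:
        raise ValidationError("abundance conversion inputs must be >= 0")
    return genome_equivalents_per_g * cell_dry_weight_g


def apply_absorption(
    raw: dict[str, float],
    absorption: dict[str, float],
    substrate_consumed: dict[str, float] | None = None,
) -> SecretionProfile:
    """Split gross produced concentrations into host-absorbed and fecal
    fractions.  Metabolites without a coefficient default to 0 absorption
    (all fecal); conservation produced = absorbed + fecal is exact."""
    for met, frac in absorption.items():
        if not (0.0 <= frac <= 1.0):
            raise ValidationError(f"absorption fraction for {met} outside [0,1]: {frac}")
    produced, absorbed, fecal = {}, {}, {}
    for met, p in raw.items():
        if p < -1e-9:
            raise ValidationError(f"negative produced amount for {met}: {p}")
        p = max(p, 0.0)
        frac = absorption.get(met, 0.0)
        produced[met] = p
        absorbed[met] = p * frac
        fecal[met] = p - p * frac
    return SecretionProfile(produced, absorbed, fecal,
                            substrate_consumed=dict(substrate_consumed or {}))
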