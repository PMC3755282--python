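"""Synthetic toy gut ecosystems.

Generates everything the pipeline needs without external downloads:

* three toy species GEMs reproducing the cross-feeding structure of the
  simplified gut community — a saccharolytic *B. thetaiotaomicron*-like
  fermenter (acetate/formate/propionate/succinate), a butyrogenic
  *E. rectale*-like fermenter (butyrate/CO2/H2, acetate consumer) and a
  *M. smithii*-like methanogen (H2/formate/acetate to CH4);
* diet, abundance and absorption fixtures matching the study conditions
  (glucan 31 and acetate 6 umol/g cecal in the feed; SCFA absorption
  acetate 60%, propionate 70%, butyrate 90%; beta-problem glucan fixed
  at 20 umol/g cecal);
* synthetic gene-level differential-expression tables with planted
  transcriptional signals around chosen metabolites.

All fermentation reactions are elementally balanced; redox (NAD/NADH)
and energy (ATP/ADP) carriers close the electron and energy balances so
that product mixes are forced by stoichiometry rather than chosen by
hand.  Flux units are mmol/gDW/h at the species level; biomass reaction
coefficients are umol of precursor per mg dry weight, so a biomass flux
of 1 corresponds to 1 mg DW in community (concentration) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GEM, Metabolite, Reaction, ValidationError, ConfigurationError

__all__ = [
    "ToyEcosystemSpec",
    "make_toy_gems",
    "make_fixtures",
    "make_expression",
    "DEFAULT_DIET",
    "DEFAULT_ABSORPTION",
    "BETA_GLUCAN_UPTAKE",
]

#: Feed composition, umol/g cecal content.
DEFAULT_DIET = {"glucan": 31.0, "ac": 6.0}

#: Fraction of each secreted SCFA absorbed through the gut wall.
DEFAULT_ABSORPTION = {"ac": 0.60, "prop": 0.70, "but": 0.90}

#: Glucan uptake fixed when solving the beta-problem (umol/g cecal).
BETA_GLUCAN_UPTAKE = 20.0


@dataclass
class ToyEcosystemSpec:
    """Parameters of the toy ecosystem.

    ``glucan_dp`` is the degree of polymerization of the dietary glucan
    pseudo-metabolite (hexose units per glucan).  ``biomass_hexose`` /
    ``biomass_acetate`` are carbon-precursor demands in umol per mg DW
    (about 0.5 mg carbon per mg DW); ``biomass_atp`` is the ATP demand in
    umol/mg DW, in the range reported for anaerobic growth.
    """

    species: tuple[str, ...] = ("bth", "ere", "msi")
    glucan_dp: int = 10
    biomass_hexose: float = 7.0    # Bth: umol hexose / mg DW
    biomass_acetate: float = 21.0  # Ere, Msi: umol acetate / mg DW
    biomass_atp: float = 40.0      # umol ATP / mg DW
    atp_yields: dict[str, float] = field(default_factory=lambda: {
        "glycolysis": 2.0,      # per hexose
        "acetate_kinase": 1.0,  # per pyruvate
        "pfl": 1.0,             # per pyruvate (acetate + formate branch)
        "acrylate": 1.0,        # per propionate
        "butyrate_kinase": 1.0, # per butyrate
        "methanogenesis": 1.0,  # per CH4 (H2/formate routes)
        "aceticlastic": 0.5,    # per CH4 from acetate
    })
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.species) - {"bth", "ere", "msi"}
        if unknown:
            raise ValidationError(f"unknown species {sorted(unknown)}")
        if self.glucan_dp < 1:
            raise ValidationError("glucan_dp must be >= 1")
        for name, y in [("biomass_hexose", self.biomass_hexose),
                        ("biomass_acetate", self.biomass_acetate),
                        ("biomass_atp", self.biomass_atp),
                        *self.atp_yields.items()]:
            if y <= 0:
                raise ValidationError(f"yield {name} must be > 0, got {y}")


def _shared_metabolites(dp: int) -> dict[str, Metabolite]:
    """Extracellular (lumen-shareable) metabolites with formulas."""
    return {
        "glucan": Metabolite("glucan", "glucan (hexose polymer)", "e",
                             {"C": 6.0 * dp, "H": 10.0 * dp + 2, "O": 5.0 * dp + 1}),
        "ac": Metabolite("ac", "acetate", "e", {"C": 2, "H": 4, "O": 2}),
        "prop": Metabolite("prop", "propionate", "e", {"C": 3, "H": 6, "O": 2}),
        "succ": Metabolite("succ", "succinate", "e", {"C": 4, "H": 6, "O": 4}),
        "but": Metabolite("but", "butyrate", "e", {"C": 4, "H": 8, "O": 2}),
        "form": Metabolite("form", "formate", "e", {"C": 1, "H": 2, "O": 2}),
        "h2": Metabolite("h2", "hydrogen", "e", {"H": 2}),
        "co2": Metabolite("co2", "carbon dioxide", "e", {"C": 1, "O": 2}),
        "ch4": Metabolite("ch4", "methane", "e", {"C": 1, "H": 4}),
        "h2o": Metabolite("h2o", "water", "e", {"H": 2, "O": 1}),
    }


def _currency() -> list[Metabolite]:
    # Reduced currency formulas: ATP/ADP carry no elements (energy only);
    # NADH carries the 2H it transfers relative to NAD.
    return [
        Metabolite("atp_c", "ATP", "c", {}),
        Metabolite("adp_c", "ADP", "c", {}),
        Metabolite("nad_c", "NAD+", "c", {}),
        Metabolite("nadh_c", "NADH", "c", {"H": 2}),
    ]


def _exchange(met_id: str, lb: float = -1000.0, ub: float = 1000.0) -> Reaction:
    return Reaction(f"EX_{met_id}", {met_id: -1.0}, name=f"{met_id} exchange",
                    lower_bound=lb, upper_bound=ub, is_exchange=True)


def _atpm() -> Reaction:
    # non-growth ATP maintenance: flexible sink so energy balance is an
    # inequality (production >= demand) rather than a forced equality
    return Reaction("ATPM", {"atp_c": -1, "adp_c": 1},
                    name="non-growth ATP maintenance", lower_bound=0,
                    subsystem="maintenance")


def _biomass_met(precursor_umol: float, c_per_umol: tuple[float, float, float]) -> Metabolite:
    c, h, o = c_per_umol
    return Metabolite("biomass", "biomass (1 mg DW)", "e",
                      {"C": c * precursor_umol, "H": h * precursor_umol,
                       "O": o * precursor_umol})


def _make_bth(spec: ToyEcosystemSpec) -> GEM:
    dp = spec.glucan_dp
    ay = spec.atp_yields
    shared = _shared_metabolites(dp)
    mets = [shared[k] for k in ("glucan", "ac", "prop", "succ", "form", "co2", "h2o")]
    mets += [
        Metabolite("glc_c", "hexose", "c", {"C": 6, "H": 12, "O": 6}),
        Metabolite("pyr_c", "pyruvate", "c", {"C": 3, "H": 4, "O": 3}),
        *_currency(),
        _biomass_met(spec.biomass_hexose, (6, 12, 6)),
    ]
    rxns = [
        Reaction("GLCH", {"glucan": -1, "h2o": -(dp - 1), "glc_c": dp},
                 name="glucan hydrolysis and uptake", lower_bound=0,
                 gene_rule="bg01 and bg02", subsystem="carbohydrate degradation"),
        Reaction("GLYC",
                 {"glc_c": -1, "adp_c": -ay["glycolysis"], "nad_c": -2,
                  "pyr_c": 2, "atp_c": ay["glycolysis"], "nadh_c": 2},
                 name="glycolysis", lower_bound=0,
                 gene_rule="(bg03 and bg04) or bg05", subsystem="glycolysis"),
        Reaction("PFL",
                 {"pyr_c": -1, "h2o": -1, "adp_c": -ay["pfl"],
                  "ac": 1, "form": 1, "atp_c": ay["pfl"]},
                 name="pyruvate formate-lyase branch (acetate + formate)",
                 lower_bound=0, gene_rule="bg06 and bg07", subsystem="fermentation"),
        Reaction("PRD",
                 {"pyr_c": -1, "nadh_c": -2, "adp_c": -ay["acrylate"],
                  "prop": 1, "h2o": 1, "nad_c": 2, "atp_c": ay["acrylate"]},
                 name="propionate production (acrylate route)", lower_bound=0,
                 gene_rule="bg08 and bg09", subsystem="fermentation"),
        Reaction("SUCS",
                 {"pyr_c": -1, "co2": -1, "nadh_c": -2,
                  "succ": 1, "h2o": 1, "nad_c": 2},
                 name="reductive succinate synthesis", lower_bound=0,
                 gene_rule="bg10 or bg11", subsystem="fermentation"),
        Reaction("BIOMASS_bth",
                 {"glc_c": -spec.biomass_hexose, "atp_c": -spec.biomass_atp,
                  "adp_c": spec.biomass_atp, "biomass": 1},
                 name="biomass synthesis", lower_bound=0, subsystem="biomass"),
        _atpm(),
        _exchange("glucan"), _exchange("ac"), _exchange("prop"),
        _exchange("succ"), _exchange("form"), _exchange("co2"),
        _exchange("h2o"), _exchange("biomass", lb=0),
    ]
    return GEM("bth", mets, rxns, biomass_reaction_id="BIOMASS_bth")


def _make_ere(spec: ToyEcosystemSpec) -> GEM:
    dp = spec.glucan_dp
    ay = spec.atp_yields
    shared = _shared_metabolites(dp)
    mets = [shared[k] for k in ("glucan", "ac", "but", "co2", "h2", "h2o")]
    mets += [
        Metabolite("glc_c", "hexose", "c", {"C": 6, "H": 12, "O": 6}),
        Metabolite("pyr_c", "pyruvate", "c", {"C": 3, "H": 4, "O": 3}),
        Metabolite("ac_c", "acetate (cytosolic)", "c", {"C": 2, "H": 4, "O": 2}),
        *_currency(),
        _biomass_met(spec.biomass_acetate, (2, 4, 2)),
    ]
    rxns = [
        Reaction("GLCH", {"glucan": -1, "h2o": -(dp - 1), "glc_c": dp},
                 name="glucan hydrolysis and uptake", lower_bound=0,
                 gene_rule="eg01 and eg02", subsystem="carbohydrate degradation"),
        Reaction("GLYC",
                 {"glc_c": -1, "adp_c": -ay["glycolysis"], "nad_c": -2,
                  "pyr_c": 2, "atp_c": ay["glycolysis"], "nadh_c": 2},
                 name="glycolysis", lower_bound=0,
                 gene_rule="eg03 or eg04", subsystem="glycolysis"),
        Reaction("PYK",
                 {"pyr_c": -1, "h2o": -1, "adp_c": -ay["acetate_kinase"],
                  "ac_c": 1, "co2": 1, "h2": 1, "atp_c": ay["acetate_kinase"]},
                 name="pyruvate oxidation to acetate (acetate kinase)",
                 lower_bound=0, gene_rule="eg05 and eg06", subsystem="fermentation"),
        Reaction("HYD", {"nadh_c": -1, "nad_c": 1, "h2": 1},
                 name="NADH-dependent hydrogenase", lower_bound=0,
                 gene_rule="eg07", subsystem="fermentation"),
        Reaction("BUTS",
                 {"ac_c": -2, "nadh_c": -2, "adp_c": -ay["butyrate_kinase"],
                  "but": 1, "h2o": 2, "nad_c": 2, "atp_c": ay["butyrate_kinase"]},
                 name="butyrate synthesis from acetate (CoA-transferase/kinase)",
                 lower_bound=0, gene_rule="eg08 and (eg09 or eg10)",
                 subsystem="fermentation"),
        Reaction("ACt", {"ac": -1, "ac_c": 1},
                 name="acetate transport", lower_bound=-1000,
                 gene_rule="eg11", subsystem="transport"),
        Reaction("BIOMASS_ere",
                 {"ac_c": -spec.biomass_acetate, "atp_c": -spec.biomass_atp,
                  "adp_c": spec.biomass_atp, "biomass": 1},
                 name="biomass synthesis", lower_bound=0, subsystem="biomass"),
        _atpm(),
        _exchange("glucan"), _exchange("ac"), _exchange("but"),
        _exchange("co2"), _exchange("h2"), _exchange("h2o"),
        _exchange("biomass", lb=0),
    ]
    return GEM("ere", mets, rxns, biomass_reaction_id="BIOMASS_ere")


def _make_msi(spec: ToyEcosystemSpec) -> GEM:
    ay = spec.atp_yields
    shared = _shared_metabolites(spec.glucan_dp)
    mets = [shared[k] for k in ("ac", "form", "h2", "co2", "ch4", "h2o")]
    mets += [
        Metabolite("ac_c", "acetate (cytosolic)", "c", {"C": 2, "H": 4, "O": 2}),
        Metabolite("atp_c", "ATP", "c", {}),
        Metabolite("adp_c", "ADP", "c", {}),
        _biomass_met(spec.biomass_acetate, (2, 4, 2)),
    ]
    rxns = [
        Reaction("ACt", {"ac": -1, "ac_c": 1},
                 name="acetate transport", lower_bound=-1000,
                 gene_rule="mg01", subsystem="transport"),
        Reaction("HMG",
                 {"h2": -4, "co2": -1, "adp_c": -ay["methanogenesis"],
                  "ch4": 1, "h2o": 2, "atp_c": ay["methanogenesis"]},
                 name="hydrogenotrophic methanogenesis", lower_bound=0,
                 gene_rule="mg02 and mg03", subsystem="methanogenesis"),
        Reaction("FMG",
                 {"form": -4, "adp_c": -ay["methanogenesis"],
                  "ch4": 1, "co2": 3, "h2o": 2, "atp_c": ay["methanogenesis"]},
                 name="formatotrophic methanogenesis", lower_bound=0,
                 gene_rule="mg04 and mg05", subsystem="methanogenesis"),
        Reaction("AMG",
                 {"ac_c": -1, "adp_c": -ay["aceticlastic"],
                  "ch4": 1, "co2": 1, "atp_c": ay["aceticlastic"]},
                 name="aceticlastic methanogenesis", lower_bound=0,
                 gene_rule="mg06 or mg07", subsystem="methanogenesis"),
        Reaction("BIOMASS_msi",
                 {"ac_c": -spec.biomass_acetate, "atp_c": -spec.biomass_atp,
                  "adp_c": spec.biomass_atp, "biomass": 1},
                 name="biomass synthesis", lower_bound=0, subsystem="biomass"),
        _atpm(),
        _exchange("ac"), _exchange("form"), _exchange("h2"),
        _exchange("co2"), _exchange("ch4"), _exchange("h2o"),
        _exchange("biomass", lb=0),
    ]
    return GEM("msi", mets, rxns, biomass_reaction_id="BIOMASS_msi")


_BUILDERS = {"bth": _make_bth, "ere": _make_ere, "msi": _make_msi}


def make_toy_gems(spec: ToyEcosystemSpec | None = None) -> dict[str, GEM]:
    """Build the toy species models and verify elemental balance.

    Raises :class:`ValidationError` listing element imbalances if the
    spec's yields produce an unbalanced network.
    """
    spec = spec or ToyEcosystemSpec()
    gems = {sp: _BUILDERS[sp](spec) for sp in spec.species}
    problems = {}
    for sp, gem in gems.items():
        bad = gem.element_imbalances()
        if bad:
            problems[sp] = bad
    if problems:
        raise ValidationError(f"unbalanced toy reactions: {problems}")
    return gems


def make_fixtures() -> tuple[dict[str, float], dict[str, dict[str, float]], dict[str, float]]:
    """Diet, abundance scenarios and absorption fractions.

    Returns ``(diet, abundance_scenarios, absorption)`` where the diet is
    {glucan: 31, acetate: 6} umol/g cecal, absorption is {acetate: 0.60,
    propionate: 0.70, butyrate: 0.90} and the abundance scenarios cover
    mono-, two- and three-member communities (mg DW/g cecal).
    """
    abundances = {
        "bth_mono": {"bth": 1.2},
        "ere_mono": {"ere": 0.2},
        "msi_mono": {"msi": 0.05},  # within what the feed's acetate can sustain
        "bth_ere": {"bth": 1.2, "ere": 0.2},
        "bth_msi": {"bth": 1.2, "msi": 0.08},
        "bth_ere_msi": {"bth": 1.2, "ere": 0.2, "msi": 0.08},
    }
    return dict(DEFAULT_DIET), abundances, dict(DEFAULT_ABSORPTION)


def make_expression(
    model: GEM,
    planted: dict[str, float],
    n_null_genes: int = 200,
    seed: int = 0,
    comparison: str = "synthetic",
    planted_p: float | None = None,
) -> pd.DataFrame:
    """Synthetic gene-level differential-expression table.

    Genes associated with a planted metabolite draw p-values from
    Beta(1/(1+|effect|), 1), which concentrates near zero for large
    effect sizes; the sign of the effect sets the direction.  All other
    model genes plus ``n_null_genes`` filler genes draw p ~ U(0,1) with
    random direction.  Deterministic for a given seed.

    ``planted_p`` switches the planted genes from the Beta draw to that
    exact p-value (a fixed-strength signal for recovery experiments; the
    Beta draw is heavy-tailed, so individual planted genes can otherwise
    land anywhere in (0,1)).

    Returns a DataFrame with columns gene, p_value, direction, lfc and
    attribute ``attrs['comparison']``.
    """
    from .reporter import gene_metabolite_map

    rng = np.random.default_rng(seed)
    met_genes = gene_metabolite_map(model)
    for met in planted:
        if met not in {m.id for m in model.metabolites}:
            raise ConfigurationError(f"planted metabolite {met!r} not in model")

    signal: dict[str, float] = {}
    for met, effect in planted.items():
        for g in sorted(met_genes.get(met, ())):
            if abs(effect) > abs(signal.get(g, 0.0)):
                signal[g] = effect

    rows = []
    all_genes = sorted(model.genes) + [f"null_{i:04d}" for i in range(n_null_genes)]
    for g in all_genes:
        effect = signal.get(g, 0.0)
        if effect:
            if planted_p is not None:
                p = float(planted_p)
            else:
                p = float(rng.beta(1.0 / (1.0 + abs(effect)), 1.0))
            direction = "up" if effect > 0 else "down"
            lfc = float(np.sign(effect) * rng.normal(abs(effect) / 2, 0.25))
        else:
            p = float(rng.uniform())
            direction = "up" if rng.uniform() < 0.5 else "down"
            lfc = float(rng.normal(0, 0.25))
        rows.append((g, min(max(p, 1e-300), 1.0), direction, lfc))
    df = pd.DataFrame(rows, columns=["gene", "p_value", "direction", "lfc"])
    df.attrs["comparison"] = comparison
    return df
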