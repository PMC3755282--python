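import numpy as np
import pandas as pd
import pytest

import gutcom as gc
from gutcom.core import ConfigurationError, ValidationError
from gutcom.reporter import (
    ExpressionTable,
    ReporterAnalysis,
    bh_correct,
    gene_metabolite_map,
    reporter_metabolites,
    reporter_subnetworks,
)


class TestBHCorrection:
    def test_hand_computed_step_up(self):
        # step-up: p_(i) * n/i = .04, .04, .04, .04 -> monotone min = .04
        assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_mixed_case(self):
        # n=3: raw p*n/i = .03, .03, .9; running min from the top: .03,.03,.9
        assert bh_correct([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_all_ones_unchanged(self):
        assert bh_correct([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_correct([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_correct([0.0, 0.5])
        with pytest.raises(ValidationError):
            bh_correct([0.5, 1.5])


class TestGeneMetaboliteMap:
    def test_enumerated_associations_on_toy_model(self, toy_gems):
        mapping = gene_metabolite_map(toy_gems["ere"])
        # cytosolic acetate touches pyruvate oxidation, butyrate synthesis,
        # transport and biomass (no genes on biomass)
        assert mapping["ac_c"] == frozenset(
            {"eg05", "eg06", "eg08", "eg09", "eg10", "eg11"})
        # lumen acetate: transport only (exchanges carry no genes)
        assert mapping["ac"] == frozenset({"eg11"})

    def test_metabolite_with_no_gene_associated_reaction_absent(self, toy_gems):
        mapping = gene_metabolite_map(toy_gems["msi"])
        assert "biomass" not in mapping  # only biomass/exchange touch it

    def test_gene_counted_once_per_metabolite(self, toy_gems):
        mapping = gene_metabolite_map(toy_gems["ere"])
        assert isinstance(mapping["ac_c"], frozenset)


class TestExpressionTable:
    def test_validation(self):
        with pytest.raises(ValidationError, match="p-values"):
            ExpressionTable(pd.DataFrame(
                {"gene": ["a"], "p_value": [0.0], "direction": ["up"]}))
        with pytest.raises(ValidationError, match="duplicate"):
            ExpressionTable(pd.DataFrame(
                {"gene": ["a", "a"], "p_value": [0.5, 0.5],
                 "direction": ["up", "down"]}))

    def test_one_sided_conversion(self):
        t = ExpressionTable(pd.DataFrame(
            {"gene": ["a", "b"], "p_value": [0.04, 0.04],
             "direction": ["up", "down"]}))
        assert t.one_sided("up") == {"a": 0.02, "b": 0.98}


class TestReporterMetabolites:
    def test_planted_signal_recovered_rank_one(self, toy_gems):
        model = toy_gems["ere"]
        expr = gc.make_expression(model, {"but": 8.0}, n_null_genes=150, seed=11)
        res = reporter_metabolites(model, expr, n_background=2000, seed=0)
        assert res.table["metabolite"].iloc[0] == "but"
        assert res.table["direction"].iloc[0] == "up"

    def test_all_k_zero_metabolites_excluded(self, toy_gems):
        model = toy_gems["ere"]
        expr = gc.make_expression(model, {}, n_null_genes=50, seed=0)
        res = reporter_metabolites(model, expr, n_background=500, seed=0)
        assert "biomass" not in set(res.table["metabolite"])
        assert (res.table["k"] >= 1).all()

    def test_no_false_reporters_under_flat_null(self, toy_gems):
        """With every gene at p = 0.5 no metabolite should stand out."""
        model = toy_gems["ere"]
        genes = sorted(model.genes) + [f"null_{i}" for i in range(100)]
        expr = pd.DataFrame({"gene": genes, "p_value": 0.5,
                             "direction": ["up"] * len(genes)})
        res = reporter_metabolites(model, expr, n_background=10000, seed=0)
        assert (res.table["z_corrected"].abs() <= 3).all()

    def test_invariant_to_gene_order_and_metabolite_relabeling(self, toy_gems):
        model = toy_gems["ere"]
        expr = gc.make_expression(model, {"but": 5.0}, n_null_genes=80, seed=5)
        shuffled = expr.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = reporter_metabolites(model, expr, n_background=1000, seed=0)
        b = reporter_metabolites(model, shuffled, n_background=1000, seed=0)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_background_null_calibration(self, toy_gems):
        """Under the global null, corrected scores are ~N(0,1): pooled
        over replicates, mean within +/-0.05 and SD within [0.9, 1.1]."""
        model = toy_gems["ere"]
        zs = []
        # metabolite scores within one replicate share genes and are
        # correlated; pooling many replicates stabilizes the moments
        for rep in range(200):
            expr = gc.make_expression(model, {}, n_null_genes=120, seed=100 + rep)
            res = reporter_metabolites(model, expr, n_background=1500, seed=rep)
            zs.extend(res.table["z_corrected"].tolist())
        zs = np.array(zs)
        assert abs(zs.mean()) <= 0.05
        assert 0.9 <= zs.std(ddof=1) <= 1.1

    def test_no_gene_overlap_is_configuration_error(self, toy_gems):
        expr = pd.DataFrame({"gene": ["foreign_1", "foreign_2"],
                             "p_value": [0.5, 0.5],
                             "direction": ["up", "up"]})
        with pytest.raises(ConfigurationError, match="overlap"):
            ReporterAnalysis(toy_gems["ere"], expr)

    def test_deterministic_given_seed(self, toy_gems):
        model = toy_gems["ere"]
        expr = gc.make_expression(model, {"but": 5.0}, n_null_genes=50, seed=2)
        a = reporter_metabolites(model, expr, n_background=1000, seed=42)
        b = reporter_metabolites(model, expr, n_background=1000, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestReporterSubnetworks:
    def _scores(self, model, up_genes, z=5.0):
        return {g: (z if g in up_genes else 0.0) for g in model.genes}

    def test_planted_pathway_recovered_and_rest_excluded(self, toy_gems):
        model = toy_gems["ere"]
        # up-score the butyrate branch, leave carbohydrate degradation at 0
        but_genes = {"eg08", "eg09", "eg10", "eg05", "eg06"}
        cofactors = ["atp_c", "adp_c", "nad_c", "nadh_c", "h2o"]
        subs = reporter_subnetworks(model, self._scores(model, but_genes),
                                    remove_cofactors=cofactors,
                                    max_size=4, seed=0)
        assert subs, "expected at least one subnetwork"
        members = set(subs[0].reactions)
        assert "BUTS" in members and "PYK" in members
        assert "GLCH" not in members

    def test_uniform_zero_scores_give_no_subnetworks(self, toy_gems):
        model = toy_gems["ere"]
        subs = reporter_subnetworks(model, self._scores(model, set()), seed=0)
        assert subs == []

    def test_max_size_one_returns_top_single_reactions(self, toy_gems):
        model = toy_gems["ere"]
        subs = reporter_subnetworks(model, self._scores(model, {"eg07"}),
                                    max_size=1, seed=0)
        assert all(s.size == 1 for s in subs)
        assert subs[0].reactions == ["HYD"]

    def test_score_never_below_best_single_member(self, toy_gems):
        model = toy_gems["ere"]
        scores = {g: z for g, z in zip(sorted(model.genes),
                                       np.linspace(0.5, 6.0, len(model.genes)))}
        subs = reporter_subnetworks(model, scores, max_size=5, seed=0)
        for sub in subs:
            rxn_scores = []
            for rid in sub.reactions:
                genes = sorted(model.reaction(rid).genes())
                zs = [scores[g] for g in genes if g in scores]
                rxn_scores.append(np.mean(zs) if zs else 0.0)
            assert sub.score >= max(rxn_scores) - 1e-9

    def test_subnetworks_are_connected(self, toy_gems):
        model = toy_gems["ere"]
        subs = reporter_subnetworks(
            model, self._scores(model, {"eg05", "eg06", "eg08"}), max_size=6, seed=0)
        assert all(s.connected for s in subs)

    def test_unknown_cofactor_id_warns_and_is_ignored(self, toy_gems):
        model = toy_gems["ere"]
        with pytest.warns(UserWarning, match="not in model"):
            reporter_subnetworks(model, self._scores(model, {"eg07"}),
                                 remove_cofactors=["unobtainium"], seed=0)

    def test_non_finite_gene_score_rejected(self, toy_gems):
        with pytest.raises(ValidationError):
            reporter_subnetworks(toy_gems["ere"], {"eg07": float("inf")}, seed=0)
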