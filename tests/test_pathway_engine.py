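"""Capability detection, pathway construction and knockout simulation."""

import itertools

import pytest

from pksmith.cluster_model import ClusterModel, GeneRecord
from pksmith.errors import ValidationError
from pksmith.ms_adducts import formula_mass
from pksmith.pathway_engine import (
    ReactionTable,
    TailoringStep,
    build_pathway,
    detect_capabilities,
    load_reaction_table,
    simulate,
)


@pytest.fixture(scope="module")
def mad_pathway(mad_bundle, mad_chains):
    caps = detect_capabilities(mad_bundle.cluster)
    return build_pathway(caps, mad_chains[1])


class TestCapabilities:
    def test_mad_fixture_has_all_flags(self, mad_bundle):
        caps = detect_capabilities(mad_bundle.cluster)
        assert caps.has_glycerate_operon
        assert caps.has_methoxymalonate_subcluster
        assert caps.has_epoxidase_hydrolase_pair
        assert caps.p450_count == 2
        assert caps.pyrE3_like_cyclase and caps.vstJ_like_cyclase
        assert len(caps.evidence["has_glycerate_operon"]) >= 5

    def test_removing_o_methyltransferase_drops_subcluster(self, mad_bundle):
        genes = [g for g in mad_bundle.cluster.genes if g.gene_id != "mad15"]
        cluster = ClusterModel("mad-minus-15", genes, mad_bundle.cluster.pks_modules)
        caps = detect_capabilities(cluster)
        assert not caps.has_methoxymalonate_subcluster
        assert caps.has_glycerate_operon  # untouched

    def test_empty_cluster_all_false(self):
        caps = detect_capabilities(ClusterModel("empty", [], []))
        assert not any(
            [
                caps.has_glycerate_operon,
                caps.has_methoxymalonate_subcluster,
                caps.has_epoxidase_hydrolase_pair,
                caps.pyrE3_like_cyclase,
                caps.vstJ_like_cyclase,
            ]
        )
        assert caps.p450_count == 0


class TestBuildPathway:
    def test_full_capability_pathway_is_nine_steps(self, mad_pathway):
        assert [s.step_id for s in mad_pathway] == [
            "IX", "XII", "XIII", "X", "XI", "XIV", "XV", "XVII", "XVIII",
        ]

    def test_missing_cyclase_omits_thp_step(self, mad_bundle, mad_chains):
        caps = detect_capabilities(mad_bundle.cluster)
        caps.vstJ_like_cyclase = False
        steps = [s.step_id for s in build_pathway(caps, mad_chains[1])]
        assert "XVII" not in steps and "XV" in steps

    def test_missing_glycerate_operon_omits_tetronate_steps(self, mad_bundle, mad_chains):
        caps = detect_capabilities(mad_bundle.cluster)
        caps.has_glycerate_operon = False
        steps = [s.step_id for s in build_pathway(caps, mad_chains[1])]
        assert {"IX", "XII", "XIII"}.isdisjoint(steps)

    def test_cyclic_prerequisites_rejected(self):
        steps = [
            TailoringStep("A", "a", [], "", {}, ["B"]),
            TailoringStep("B", "b", [], "", {}, ["A"]),
        ]
        table = ReactionTable(steps=steps, final_product_label="x")
        from pksmith.pathway_engine import _check_acyclic

        with pytest.raises(ValidationError, match="cyclic"):
            _check_acyclic(table.steps)

    def test_c38_dependency_is_configurable(self, mad_bundle, mad_chains):
        caps = detect_capabilities(mad_bundle.cluster)
        pathway = build_pathway(caps, mad_chains[1], c38_hydroxylation_after="XVII")
        xviii = next(s for s in pathway if s.step_id == "XVIII")
        assert xviii.prerequisites == ["XVII"]
        state = simulate(pathway, mad_chains[1], {"mad31"}, cluster=mad_bundle.cluster)
        assert state.blocked_ids == {"XVII", "XVIII"}
        assert state.formula.hill() == "C42H64O11"


class TestSimulate:
    def test_wild_type_endpoint(self, mad_pathway, mad_bundle, mad_chains):
        state = simulate(mad_pathway, mad_chains[1], set(), cluster=mad_bundle.cluster)
        assert state.formula.hill() == "C42H64O12"
        assert state.product_label == "tetromadurin (1)"
        assert state.blocked_steps == []

    def test_pyrE3_cyclase_knockout_gives_t17(self, mad_pathway, mad_bundle, mad_chains):
        state = simulate(mad_pathway, mad_chains[1], {"mad10"}, cluster=mad_bundle.cluster)
        assert state.formula.hill() == "C42H64O11"
        assert state.blocked_ids == {"XV", "XVII", "XVIII"}
        assert state.product_label.startswith("T-17 candidate")

    def test_mass_difference_of_16(self, mad_pathway, mad_bundle, mad_chains):
        wt = simulate(mad_pathway, mad_chains[1], set(), cluster=mad_bundle.cluster)
        ko = simulate(mad_pathway, mad_chains[1], {"mad10"}, cluster=mad_bundle.cluster)
        assert formula_mass(wt.formula, "nominal") - formula_mass(ko.formula, "nominal") == 16

    def test_vstJ_cyclase_knockout(self, mad_pathway, mad_bundle, mad_chains):
        state = simulate(mad_pathway, mad_chains[1], {"mad31"}, cluster=mad_bundle.cluster)
        assert state.blocked_ids == {"XVII"}
        assert "not experimentally observed" in state.product_label

    def test_second_p450_knockout_gives_structure_16_like(self, mad_pathway, mad_bundle, mad_chains):
        state = simulate(mad_pathway, mad_chains[1], {"mad30"}, cluster=mad_bundle.cluster)
        assert state.formula.hill() == "C42H64O11"
        assert state.blocked_ids == {"XVIII"}
        assert "16" in state.product_label

    def test_methoxymalonate_supply_knockout_aborts(self, mad_pathway, mad_bundle, mad_chains):
        state = simulate(mad_pathway, mad_chains[1], {"mad13"}, cluster=mad_bundle.cluster)
        assert state.formula is None
        assert "extender unavailable" in state.product_label

    def test_unknown_knockout_gene_rejected(self, mad_pathway, mad_bundle, mad_chains):
        with pytest.raises(ValidationError, match="unknown gene"):
            simulate(mad_pathway, mad_chains[1], {"madZZ"}, cluster=mad_bundle.cluster)

    def test_unrelated_knockout_changes_nothing(self, mad_pathway, mad_bundle, mad_chains):
        wt = simulate(mad_pathway, mad_chains[1], set(), cluster=mad_bundle.cluster)
        ko = simulate(mad_pathway, mad_chains[1], {"mad20"}, cluster=mad_bundle.cluster)
        assert ko.formula == wt.formula and ko.blocked_steps == []

    def test_blocking_is_monotone_in_knockouts(self, mad_pathway, mad_bundle, mad_chains):
        genes = ["mad10", "mad31", "mad30", "mad29", "mad16", "madC"]
        for a, b in itertools.combinations(genes, 2):
            single = simulate(mad_pathway, mad_chains[1], {a}, cluster=mad_bundle.cluster)
            double = simulate(mad_pathway, mad_chains[1], {a, b}, cluster=mad_bundle.cluster)
            assert single.blocked_ids <= double.blocked_ids

    def test_formula_is_topological_order_independent(self, mad_pathway, mad_bundle, mad_chains):
        """Applying the same unblocked steps in any valid order gives one formula."""
        reference = simulate(mad_pathway, mad_chains[1], {"mad31"}, cluster=mad_bundle.cluster)
        # a different valid topological order of the same steps
        reordered = [mad_pathway[i] for i in (3, 4, 0, 1, 2, 5, 6, 7, 8)]
        ids = [s.step_id for s in reordered]
        assert ids != [s.step_id for s in mad_pathway]
        again = simulate(reordered, mad_chains[1], {"mad31"}, cluster=mad_bundle.cluster)
        assert again.formula == reference.formula
        assert again.blocked_ids == reference.blocked_ids


class TestReactionTable:
    def test_packaged_table_loads_and_is_acyclic(self):
        table = load_reaction_table()
        assert len(table.steps) == 9
        assert table.extender_supply["methoxymalonate"] == [
            "mad11", "mad12", "mad13", "mad14", "mad15",
        ]
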