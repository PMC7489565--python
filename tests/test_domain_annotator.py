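"""Motif-based domain classification: anchor alignment and per-kind rules."""

import random

import pytest

from pksmith.cluster_model import DomainSpec
from pksmith.domain_annotator import (
    annotate_cluster,
    anchor_align,
    call_at,
    call_dh,
    call_er,
    call_kr,
    call_ks,
)
from pksmith.errors import UnalignableDomainError, ValidationError
from pksmith.scaffolds import DEFAULT_SCAFFOLDS
from pksmith.synthetic_data import make_domain


def domain_seq(kind, state, seed=11, rate=0.1):
    return make_domain(DomainSpec(kind, state), random.Random(seed), mutation_rate=rate)


class TestAnchorAlign:
    def test_scaffold_aligns_to_itself(self):
        for kind, sc in DEFAULT_SCAFFOLDS.items():
            amap = anchor_align(sc.sequence, sc)
            assert amap.identity == 1.0
            for name in sc.anchors:
                assert amap.anchors[name] == sc.residues(name)

    def test_planted_q_at_cys_anchor_reported(self):
        seq = domain_seq("KS", {"ks_residue": "Q"})
        amap = anchor_align(seq, DEFAULT_SCAFFOLDS["KS"])
        assert amap.anchors["catalytic_cys"] == "Q"

    def test_shuffled_sequence_unalignable(self):
        sc = DEFAULT_SCAFFOLDS["KS"]
        shuffled = "".join(random.Random(42).sample(sc.sequence, len(sc.sequence)))
        with pytest.raises(UnalignableDomainError, match="identity"):
            anchor_align(shuffled, sc)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            anchor_align("MKL", DEFAULT_SCAFFOLDS["KS"])

    def test_determinism(self):
        seq = domain_seq("AT", {"at_motif": "YASH"})
        a = anchor_align(seq, DEFAULT_SCAFFOLDS["AT"])
        b = anchor_align(seq, DEFAULT_SCAFFOLDS["AT"])
        assert a.anchors == b.anchors and a.score == b.score


class TestKS:
    @pytest.mark.parametrize(
        "residue,subtype,active",
        [("C", "extension", True), ("Q", "KSQ", True), ("A", "extension", False)],
    )
    def test_catalytic_residue_rules(self, residue, subtype, active):
        call = call_ks(domain_seq("KS", {"ks_residue": residue}))
        assert call.subtype == subtype and call.active is active

    def test_ksq_outside_loading_module_flagged_not_fatal(self):
        call = call_ks(domain_seq("KS", {"ks_residue": "Q"}), module_index="3")
        assert call.subtype == "KSQ" and call.active
        assert any("expected only in the loading module" in n for n in call.notes)


class TestAT:
    @pytest.mark.parametrize(
        "motif,subtype",
        [
            ("HASH", "relaxed_hybrid"),
            ("HAFH", "acetate"),
            ("TAFH", "acetate"),
            ("VAFH", "acetate"),
            ("YAFH", "acetate"),
            ("YASH", "propionate"),
            ("VASH", "propionate"),
            ("WASH", "propionate"),
            ("QQQQ", "unknown"),
        ],
    )
    def test_selectivity_motifs(self, motif, subtype):
        call = call_at(domain_seq("AT", {"at_motif": motif}))
        assert call.subtype == subtype

    def test_evidence_records_extracted_motif(self):
        call = call_at(domain_seq("AT", {"at_motif": "WASH"}))
        assert call.motif_evidence["anchors"]["selectivity_motif"] == "WASH"


class TestKR:
    def test_b1_gives_d_hydroxyl(self):
        call = call_kr(domain_seq("KR", {}))
        assert call.subtype == "B1" and call.stereo_outcome == "D" and call.active

    def test_proline_two_after_tyrosine_gives_b2(self):
        call = call_kr(domain_seq("KR", {"pro_at_tyr_plus2": True}))
        assert call.subtype == "B2" and call.stereo_outcome == "D"

    def test_missing_tyrosine_inactivates(self):
        call = call_kr(domain_seq("KR", {"catalytic_tyr": False}))
        assert call.subtype == "inactive" and not call.active
        assert call.stereo_outcome == "none"

    def test_nadph_deletion_flagged_and_inactivates(self):
        call = call_kr(domain_seq("KR", {"catalytic_tyr": False, "nadph_deletion": True}))
        assert not call.active
        assert call.motif_evidence["nadph_site_deletion"] is True
        assert call.motif_evidence["nadph_gap_fraction"] > 0.5

    def test_no_ldd_gives_a_type_l_hydroxyl(self):
        call = call_kr(domain_seq("KR", {"ldd": False}))
        assert call.subtype == "A" and call.stereo_outcome == "L"


class TestDH:
    def test_intact_anchors_active(self):
        assert call_dh(domain_seq("DH", {})).active

    def test_missing_ygp_tyrosine_inactivates(self):
        call = call_dh(domain_seq("DH", {"ygp_tyr": False}))
        assert not call.active
        assert any("YGP tyrosine" in n for n in call.notes)

    def test_asp_substitution_inactivates(self):
        call = call_dh(domain_seq("DH", {"catalytic_asp": False}))
        assert not call.active
        assert any("aspartate" in n for n in call.notes)


class TestER:
    def test_key_tyrosine_controls_configuration(self):
        assert call_er(domain_seq("ER", {"key_tyr": False})).subtype == "D_configuring"
        assert call_er(domain_seq("ER", {"key_tyr": True})).subtype == "L_configuring"
        assert call_er(domain_seq("ER", {"key_tyr": False})).stereo_outcome == "D"


class TestClusterAnnotation:
    def test_mad_fixture_call_pattern(self, mad_annotation):
        """The canonical fixture: 1 KS^Q, 2 inactive KRs (12, 14), 1 inactive DH (5)."""
        ks = [c for c in mad_annotation.calls if c.kind == "KS"]
        assert sum(c.subtype == "KSQ" for c in ks) == 1
        assert mad_annotation.call("LM", "KS").subtype == "KSQ"
        inactive_kr = [c.module_index for c in mad_annotation.calls if c.kind == "KR" and not c.active]
        assert sorted(inactive_kr) == ["12", "14"]
        inactive_dh = [c.module_index for c in mad_annotation.calls if c.kind == "DH" and not c.active]
        assert inactive_dh == ["5"]
        assert not mad_annotation.errors

    def test_mad_extender_tally(self, mad_annotation):
        """6 acetate / 8 propionate (after hybrid resolution) / 1 methoxymalonate."""
        tally = mad_annotation.extender_tally()
        assert tally == {"acetate": 6, "propionate": 8, "methoxymalonate": 1}

    def test_methoxymalonate_override_requires_target_and_subcluster(self, mad_bundle, mad_target):
        with_target = annotate_cluster(mad_bundle.cluster, mad_target)
        at13 = with_target.call("13", "AT")
        assert at13.subtype == "methoxymalonate_override"
        assert at13.motif_evidence["sequence_motif_subtype"] == "propionate"
        blind = annotate_cluster(mad_bundle.cluster)
        assert blind.call("13", "AT").subtype == "propionate"
        assert blind.call("LM", "AT").subtype == "relaxed_hybrid"

    def test_identical_inputs_identical_tables(self, mad_bundle, mad_target, tmp_path):
        from pksmith.cluster_model import write_annotation_table

        paths = []
        for name in ("x.tsv", "y.tsv"):
            res = annotate_cluster(mad_bundle.cluster, mad_target)
            p = tmp_path / name
            write_annotation_table(mad_bundle.cluster, res.calls, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_all_intact_cluster_has_no_inactive_calls(self):
        from pksmith.synthetic_data import make_cluster, random_architecture
        from pksmith.cluster_model import ArchitectureSpec, DomainSpec, ModuleSpec

        spec = ArchitectureSpec(
            cluster_id="intact",
            modules=[
                ModuleSpec("LM", "g1", [DomainSpec("KS", {"ks_residue": "Q"}), DomainSpec("AT", {"at_motif": "HAFH"}), DomainSpec("ACP")]),
                ModuleSpec("1", "g1", [DomainSpec("KS"), DomainSpec("AT", {"at_motif": "YASH"}), DomainSpec("DH"), DomainSpec("KR"), DomainSpec("ACP")]),
            ],
        )
        bundle = make_cluster(spec, seed=5)
        res = annotate_cluster(bundle.cluster)
        assert all(c.active for c in res.calls)

    def test_single_residue_sensitivity(self, mad_spec):
        """Mutating only the planted KS anchor flips exactly that call."""
        import copy

        from pksmith.synthetic_data import make_cluster

        spec2 = copy.deepcopy(mad_spec)
        ks1 = next(
            d for m in spec2.modules if m.module_index == "1" for d in m.domains if d.kind == "KS"
        )
        ks1.state["ks_residue"] = "A"
        base = annotate_cluster(make_cluster(mad_spec, seed=9).cluster)
        mutated = annotate_cluster(make_cluster(spec2, seed=9).cluster)
        changed = [
            (a.module_index, a.kind)
            for a, b in zip(base.calls, mutated.calls)
            if (a.subtype, a.active, a.stereo_outcome) != (b.subtype, b.active, b.stereo_outcome)
        ]
        assert changed == [("1", "KS")]
        assert not mutated.call("1", "KS").active

    def test_unalignable_domains_collected_not_fatal(self, mad_bundle):
        import copy

        cluster = copy.deepcopy(mad_bundle.cluster)
        dom = cluster.pks_modules[1].domains[0]
        dom.sequence = "".join(random.Random(3).sample(dom.sequence, len(dom.sequence)))
        res = annotate_cluster(cluster)
        assert len(res.errors) == 1
        assert res.errors[0]["module"] == "1" and res.errors[0]["kind"] == "KS"
        assert len(res.calls) == 59

    def test_empty_cluster_rejected(self):
        from pksmith.cluster_model import ClusterModel

        with pytest.raises(ValidationError, match="no PKS modules"):
            annotate_cluster(ClusterModel(cluster_id="x", genes=[], pks_modules=[]))
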