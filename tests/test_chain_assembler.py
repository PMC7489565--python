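"""Chain assembly, retrobiosynthetic comparison, formula and SMILES output."""

import pytest

from pksmith.chain_assembler import (
    LinearChain,
    MonomerState,
    assemble_from_calls,
    chain_formula,
    chain_from_target,
    chain_to_smiles,
    compare_chains,
    smiles_formula,
)
from pksmith.domain_annotator import EXTENDERS, DomainCall
from pksmith.errors import ValidationError
from pksmith.synthetic_data import random_chain


def _call(module, kind, subtype, active=True, stereo="none"):
    return DomainCall("g", module, kind, subtype, active, {}, stereo)


def single_module_calls(at="acetate", kr=None, dh=None, er=None):
    calls = [
        _call("LM", "KS", "KSQ"),
        _call("LM", "AT", "propionate"),
        _call("1", "KS", "extension"),
        _call("1", "AT", at),
    ]
    if kr:
        subtype, active, stereo = kr
        calls.append(_call("1", "KR", subtype, active, stereo))
    if dh:
        calls.append(_call("1", "DH", "active" if dh == "active" else "inactive", dh == "active"))
    if er:
        calls.append(_call("1", "ER", f"{er}_configuring", True, er))
    return calls


class TestReductionLadder:
    @pytest.mark.parametrize(
        "kr,dh,er,expected_beta",
        [
            (None, None, None, "ketone"),
            (("B1", True, "D"), None, None, "hydroxyl"),
            (("B1", True, "D"), "inactive", None, "hydroxyl"),
            (("B1", True, "D"), "active", None, "enoyl_double_bond"),
            (("B1", True, "D"), "active", "D", "methylene"),
            (("inactive", False, "none"), "active", None, "ketone"),
        ],
    )
    def test_beta_state(self, kr, dh, er, expected_beta):
        chain = assemble_from_calls(single_module_calls(kr=kr, dh=dh, er=er), ["LM", "1"])
        assert chain.extensions[0].beta_state == expected_beta

    def test_inactive_kr_with_dh_notes_trans_acting_possibility(self):
        chain = assemble_from_calls(
            single_module_calls(kr=("inactive", False, "none"), dh="active"), ["LM", "1"]
        )
        assert any("trans-acting KR" in n for n in chain.extensions[0].notes)

    def test_er_sets_alpha_stereo_on_propionate(self):
        chain = assemble_from_calls(
            single_module_calls(at="propionate", kr=("B1", True, "D"), dh="active", er="D"),
            ["LM", "1"],
        )
        ext = chain.extensions[0]
        assert ext.alpha_substituent == "methyl" and ext.alpha_stereo == "D"

    def test_b1_kr_sets_alpha_stereo_without_er(self):
        chain = assemble_from_calls(
            single_module_calls(at="propionate", kr=("B1", True, "D")), ["LM", "1"]
        )
        assert chain.extensions[0].alpha_stereo == "D"

    def test_unknown_at_subtype_is_hard_error(self):
        with pytest.raises(ValidationError, match="unusable"):
            assemble_from_calls(single_module_calls(at="unknown"), ["LM", "1"])

    def test_hybrid_loading_at_resolves_to_propionate_with_note(self):
        calls = single_module_calls()
        calls[1] = _call("LM", "AT", "relaxed_hybrid")
        chain = assemble_from_calls(calls, ["LM", "1"])
        assert chain.starter.extender.name == "propionate"
        assert any("relaxed-hybrid" in n for n in chain.starter.notes)


class TestMadChains:
    def test_chain13_states_follow_module_tally(self, mad_chains):
        chain13, _ = mad_chains
        states = {m.position: m.beta_state for m in chain13.extensions}
        assert all(states[p] == "methylene" for p in ("2", "4", "8", "11"))
        assert all(states[p] == "hydroxyl" for p in ("5", "7"))
        assert all(states[p] == "ketone" for p in ("12", "14"))
        assert all(states[p] == "enoyl_double_bond" for p in ("1", "3", "6", "9", "10", "13"))
        stereo = {m.position: m.beta_stereo for m in chain13.extensions}
        assert stereo["5"] == stereo["7"] == "D"

    def test_backbone_and_total_carbons(self, mad_chains):
        chain13, chain14 = mad_chains
        assert chain13.backbone_carbons == 31 == chain14.backbone_carbons
        # chain carbons + the glycerate unit = the C42 of the final metabolite
        assert chain14.total_carbons + EXTENDERS["glycerate"].total_carbons == 42

    def test_carbon_numbering_contiguous_and_convention(self, mad_chains):
        _, chain14 = mad_chains
        numbering = chain14.carbon_numbering()
        assert numbering["carbonyl_14"] == 1  # carboxy/tetronate end
        assert numbering["beta_12"] == 7  # the contested hydroxyl carbon
        assert numbering["beta_5"] == 21
        assert max(numbering.values()) == 31

    def test_target_decomposition_tally(self, mad_chains):
        _, chain14 = mad_chains
        names = [chain14.starter.extender.name] + [m.extender.name for m in chain14.extensions]
        assert names.count("propionate") == 8
        assert names.count("acetate") == 6
        assert names.count("methoxymalonate") == 1

    def test_chain13_vs_chain14_single_position_discrepancy(self, mad_chains):
        chain13, chain14 = mad_chains
        diff = compare_chains(chain13, chain14)
        assert diff.verdict == "near_collinear"
        assert diff.positions() == ["12"]
        beta = next(d for d in diff.discrepancies if d.field == "beta_state")
        assert beta.value_a == "ketone" and beta.value_b == "hydroxyl"
        assert "trans-acting KR" in beta.note


class TestCompareChains:
    def test_chain_vs_itself_collinear(self, mad_chains):
        _, chain14 = mad_chains
        diff = compare_chains(chain14, chain14)
        assert diff.verdict == "collinear" and diff.count == 0

    def test_different_lengths_incompatible(self, mad_chains):
        chain13, _ = mad_chains
        short = LinearChain(starter=chain13.starter, extensions=chain13.extensions[:5])
        assert compare_chains(chain13, short).verdict == "incompatible"

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_up_to_value_swap(self, seed):
        a, b = random_chain(seed, 6), random_chain(seed + 1000, 6)
        ab, ba = compare_chains(a, b), compare_chains(b, a)
        assert ab.verdict == ba.verdict and ab.count == ba.count
        assert [(d.position, d.field, d.value_a, d.value_b) for d in ab.discrepancies] == [
            (d.position, d.field, d.value_b, d.value_a) for d in ba.discrepancies
        ]


class TestTargetParsing:
    def test_starter_only_chain(self):
        chain = chain_from_target({"starter": {"extender": "propionate"}, "extensions": []})
        assert chain.backbone_carbons == 3 and chain.extensions == []

    def test_hydroxyl_without_stereo_rejected(self):
        with pytest.raises(ValidationError, match="beta_stereo"):
            chain_from_target(
                {
                    "starter": {"extender": "propionate"},
                    "extensions": [
                        {"position": "1", "extender": "acetate", "beta_state": "hydroxyl",
                         "beta_stereo": "none"}
                    ],
                }
            )

    def test_json_round_trip(self, mad_chains, tmp_path):
        _, chain14 = mad_chains
        p = tmp_path / "chain.json"
        chain14.to_json(p)
        again = LinearChain.from_json(p)
        assert again.to_dict() == chain14.to_dict()


class TestFormulaAndSmiles:
    def test_starter_propionate_is_propionic_acid(self):
        chain = LinearChain(starter=MonomerState("LM", EXTENDERS["propionate"]))
        assert chain_formula(chain).hill() == "C3H6O2"
        assert chain_to_smiles(chain) == "CCC(=O)O"

    def test_single_ketone_extension_is_oxopentanoic_acid(self):
        chain = LinearChain(
            starter=MonomerState("LM", EXTENDERS["propionate"]),
            extensions=[
                MonomerState("1", EXTENDERS["acetate"], beta_state="ketone")
            ],
        )
        assert chain_formula(chain).hill() == "C5H8O3"
        assert smiles_formula(chain_to_smiles(chain)).hill() == "C5H8O3"

    def test_packaged_chain14_formula_matches_smiles(self, mad_chains):
        _, chain14 = mad_chains
        f = chain_formula(chain14)
        assert f == smiles_formula(chain_to_smiles(chain14))

    @pytest.mark.parametrize("seed", range(40))
    def test_formula_smiles_conservation_random_chains(self, seed):
        chain = random_chain(seed)
        assert chain_formula(chain) == smiles_formula(chain_to_smiles(chain))
        assert chain.backbone_carbons == (
            2 * len(chain.extensions)
            + (3 if chain.starter.extender.name == "propionate" else 2)
        )
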