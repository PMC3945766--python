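import pytest
from rdkit import Chem

from mmptk.fragmentation import enumerate_single_cuts, reattach
from mmptk.recap import (
    RuleConfigError,
    default_rules,
    enumerate_retro_cuts,
    identify_retro_bonds,
    load_rules,
)
from mmptk.structures import heavy_atoms
from tests.conftest import std

CANON = Chem.CanonSmiles


@pytest.fixture(scope="module")
def rules():
    return default_rules()


class TestRuleLoading:
    def test_default_rules_ship_the_classic_bond_classes(self, rules):
        ids = {r.rule_id for r in rules}
        assert {"amide", "ester", "amine", "urea", "ether", "olefin",
                "quaternary_nitrogen", "aromatic_nitrogen_aliphatic_carbon",
                "lactam_nitrogen_aliphatic_carbon", "aromatic_carbon_aromatic_carbon",
                "sulfonamide"} <= ids

    def test_olefin_cleavage_disabled_by_default(self, rules):
        olefin = next(r for r in rules if r.rule_id == "olefin")
        assert not olefin.enabled and olefin.bond_order == 2

    def test_malformed_smarts_rejected_at_load(self, tmp_path):
        bad = tmp_path / "rules.tsv"
        bad.write_text("broken\t[C:1](((\ttrue\n")
        with pytest.raises(RuleConfigError):
            load_rules(bad)

    def test_missing_atom_maps_rejected(self, tmp_path):
        bad = tmp_path / "rules.tsv"
        bad.write_text("unmapped\tC=O\ttrue\n")
        with pytest.raises(RuleConfigError):
            load_rules(bad)


class TestIdentifyRetroBonds:
    def test_acetanilide_amide_bond(self, rules):
        mol = std("CC(=O)Nc1ccccc1")
        tagged = identify_retro_bonds(mol, rules)
        assert len(tagged) == 1
        _, rule_ids, _ = tagged[0]
        assert "amide" in rule_ids

    def test_methyl_benzoate_ester_bond(self, rules):
        mol = std("COC(=O)c1ccccc1")
        tagged = identify_retro_bonds(mol, rules)
        assert len(tagged) == 1
        assert "ester" in tagged[0][1]

    def test_ring_bonds_excluded(self, rules):
        assert identify_retro_bonds(std("C1CCCCC1"), rules) == []
        # lactam: the ring amide bond itself is not cleavable
        assert identify_retro_bonds(std("O=C1CCCN1"), rules) == []

    def test_sulfonamide_bond(self, rules):
        tagged = identify_retro_bonds(std("CS(=O)(=O)NC"), rules)
        assert any("sulfonamide" in ids for _, ids, _ in tagged)

    def test_biaryl_bond(self, rules):
        tagged = identify_retro_bonds(std("c1ccc(-c2ccccc2)cc1"), rules)
        assert len(tagged) == 1
        assert "aromatic_carbon_aromatic_carbon" in tagged[0][1]


class TestEnumerateRetroCuts:
    def test_acetanilide_two_orientations(self, rules):
        cuts = enumerate_retro_cuts(std("CC(=O)Nc1ccccc1"), rules)
        assert len(cuts) == 2
        assert {c.core_smiles for c in cuts} == {CANON("[*]C(C)=O"), CANON("[*]Nc1ccccc1")}
        assert all("amide" in c.rule_ids for c in cuts)

    def test_no_rule_matches(self, rules):
        assert enumerate_retro_cuts(std("CC"), rules) == []

    def test_naphthalenyl_amides_share_retro_core(self, rules):
        # acetamide vs propionamide on 2-aminonaphthalene: shared 11-heavy core,
        # exchanged fragments of 3 and 4 heavy atoms -> a legal RECAP-MMP downstream
        ace = enumerate_retro_cuts(std("CC(=O)Nc1ccc2ccccc2c1"), rules)
        pro = enumerate_retro_cuts(std("CCC(=O)Nc1ccc2ccccc2c1"), rules)
        core = CANON("[*]Nc1ccc2ccccc2c1")
        assert heavy_atoms(core) == 11
        frag_a = next(c.fragment_smiles for c in ace if c.core_smiles == core)
        frag_b = next(c.fragment_smiles for c in pro if c.core_smiles == core)
        assert (heavy_atoms(frag_a), heavy_atoms(frag_b)) == (3, 4)

    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)Nc1ccccc1", "COC(=O)c1ccccc1", "CCOC", "CS(=O)(=O)NC",
         "c1ccc(-c2ccccc2)cc1", "CC(=O)N(C)C(C)=O", "O=C1CCCN1CC"],
    )
    def test_retro_cuts_subset_of_standard_cuts_and_reassemble(self, smiles, rules):
        mol = std(smiles)
        standard = {(c.core_smiles, c.fragment_smiles) for c in enumerate_single_cuts(mol)}
        retro = enumerate_retro_cuts(mol, rules)
        assert retro, f"expected retro bonds in {smiles}"
        for cut in retro:
            assert (cut.core_smiles, cut.fragment_smiles) in standard
            assert cut.core_heavy + cut.fragment_heavy == mol.heavy_atom_count
            assert reattach(cut.core_smiles, cut.fragment_smiles) == mol.canonical_smiles
            assert cut.rule_ids

    def test_rule_audit_smarts_rematches_reassembled_parent(self, rules):
        # every emitted cut carries a rule whose SMARTS matches the parent at an acyclic bond
        by_id = {r.rule_id: r for r in rules}
        for smiles in ["CC(=O)Nc1ccccc1", "COC(=O)c1ccccc1", "CN(C)C(=O)N(C)C"]:
            mol = std(smiles)
            for cut in enumerate_retro_cuts(mol, rules):
                parent = Chem.MolFromSmiles(reattach(cut.core_smiles, cut.fragment_smiles))
                for rule_id in cut.rule_ids:
                    assert parent.HasSubstructMatch(by_id[rule_id].query())

    def test_olefin_cut_when_enabled(self, rules):
        enabled = [r if r.rule_id != "olefin" else
                   type(r)(rule_id=r.rule_id, smarts=r.smarts, enabled=True, bond_order=2)
                   for r in rules]
        mol = std("CC=Cc1ccccc1")
        cuts = enumerate_retro_cuts(mol, enabled)
        olefin_cuts = [c for c in cuts if "olefin" in c.rule_ids]
        assert olefin_cuts
        for c in olefin_cuts:
            assert reattach(c.core_smiles, c.fragment_smiles, bond_order=2) == mol.canonical_smiles
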