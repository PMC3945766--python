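import pytest
from rdkit import Chem

from mmptk.fragmentation import all_cuts, build_index
from mmptk.mmp import (
    MMP,
    apply_size_rules,
    assemble_mmps,
    brute_force_pairs,
    detect_cliffs,
    select_canonical,
)
from tests.conftest import make_target_set, std

CANON = Chem.CanonSmiles


class TestSizeRules:
    @pytest.mark.parametrize(
        "core, fa, fb, expected",
        [
            (26, 13, 5, True),   # every bound at its limit simultaneously
            (20, 13, 4, False),  # fragment size difference 9 > 8
            (10, 6, 5, False),   # core smaller than twice the larger fragment
            (26, 14, 5, False),  # fragment above the 13-atom cap
            (6, 2, 2, True),
            (6, 0, 3, True),     # hydrogen fragment passes the 2x rule trivially
            (6, 0, 9, False),    # but the difference cap limits H -> fragment additions to 8
        ],
    )
    def test_boundaries(self, core, fa, fb, expected):
        assert apply_size_rules(core, fa, fb) is expected

    def test_symmetric_in_fragments(self):
        assert apply_size_rules(20, 3, 7) == apply_size_rules(20, 7, 3)


def _toluene_ethylbenzene():
    mols = {"tol": std("Cc1ccccc1", "tol"), "etb": std("CCc1ccccc1", "etb")}
    ts = make_target_set({"tol": 5.0, "etb": 6.0})
    cuts = {cid: all_cuts(m) for cid, m in mols.items()}
    return ts, cuts


class TestAssembleMMPs:
    def test_toluene_ethylbenzene_candidates(self):
        ts, cuts = _toluene_ethylbenzene()
        index = build_index(ts, cuts)
        exhaustive = assemble_mmps(index, ts, dedup=False)
        cores = {m.core_smiles for m in exhaustive}
        # methyl->ethyl under the phenyl core, H->methyl under the benzyl core
        assert {CANON("[*]c1ccccc1"), CANON("[*]Cc1ccccc1")} <= cores

    def test_pair_level_dedup_keeps_smallest_transformation(self):
        ts, cuts = _toluene_ethylbenzene()
        index = build_index(ts, cuts)
        [mmp] = assemble_mmps(index, ts)
        # H->methyl (max fragment 1) beats methyl->ethyl (max fragment 2)
        assert mmp.core_smiles == CANON("[*]Cc1ccccc1")
        assert (mmp.frag_a_heavy, mmp.frag_b_heavy) in {(0, 1), (1, 0)}

    def test_singleton_core_key_yields_no_mmp(self):
        ts = make_target_set({"a": 5.0})
        index = build_index(ts, {"a": all_cuts(std("Cc1ccccc1", "a"))})
        assert assemble_mmps(index, ts) == []

    def test_same_compound_symmetric_cuts_yield_no_mmp(self):
        # p-xylene cuts both methyls onto the same core; same compound never pairs with itself
        ts = make_target_set({"a": 5.0})
        index = build_index(ts, {"a": all_cuts(std("Cc1ccc(C)cc1", "a"))})
        assert assemble_mmps(index, ts) == []

    def test_symmetry_under_input_order(self):
        ts, cuts = _toluene_ethylbenzene()
        index = build_index(ts, cuts)
        forward = assemble_mmps(index, ts)
        ts_r = make_target_set({"etb": 6.0, "tol": 5.0})
        index_r = build_index(ts_r, cuts)
        assert assemble_mmps(index_r, ts_r) == forward

    def test_index_pairs_match_brute_force(self):
        ts, cuts = _toluene_ethylbenzene()
        index = build_index(ts, cuts)
        got = {
            (m.cpd_a, m.cpd_b, m.core_smiles, m.frag_a, m.frag_b)
            for m in assemble_mmps(index, ts, dedup=False)
        }
        assert got == brute_force_pairs(cuts, ts)


class TestSelectCanonical:
    def _mmp(self, core_heavy, fa, fb, core="[*]C"):
        return MMP(
            cpd_a="a", cpd_b="b", core_smiles=core, frag_a="[*]X", frag_b="[*]Y",
            core_heavy=core_heavy, frag_a_heavy=fa, frag_b_heavy=fb,
            target_id="T1", measurement_kind="Ki",
        )

    def test_smaller_max_fragment_wins(self):
        small = self._mmp(7, 0, 1)
        large = self._mmp(6, 1, 2)
        assert select_canonical([large, small]) is small

    def test_single_candidate_returned(self):
        m = self._mmp(6, 1, 2)
        assert select_canonical([m]) is m

    def test_tie_broken_by_core_smiles(self):
        a = self._mmp(6, 1, 2, core="[*]A")
        b = self._mmp(6, 1, 2, core="[*]B")
        assert select_canonical([b, a]) is a

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_canonical([])


class TestDetectCliffs:
    def _mmp(self, a="a", b="b"):
        return MMP(cpd_a=a, cpd_b=b, core_smiles="[*]C", frag_a="[*]N", frag_b="[*]O",
                   core_heavy=6, frag_a_heavy=1, frag_b_heavy=1,
                   target_id="T1", measurement_kind="Ki")

    def test_two_order_cliff(self):
        ts = make_target_set({"a": 5.0, "b": 7.2})
        [cliff] = detect_cliffs([self._mmp()], ts, 2.0)
        assert cliff.delta == pytest.approx(2.2)
        assert (cliff.cpd_low, cliff.cpd_high) == ("a", "b")

    def test_threshold_dependence(self):
        ts = make_target_set({"a": 5.0, "b": 6.5})
        assert detect_cliffs([self._mmp()], ts, 2.0) == []
        assert len(detect_cliffs([self._mmp()], ts, 1.0)) == 1

    def test_equal_potencies_never_a_cliff(self):
        ts = make_target_set({"a": 5.0, "b": 5.0})
        assert detect_cliffs([self._mmp()], ts, 0.5) == []

    def test_missing_potency_is_a_contract_violation(self):
        ts = make_target_set({"a": 5.0})
        with pytest.raises(KeyError):
            detect_cliffs([self._mmp()], ts, 2.0)

    def test_threshold_nesting(self):
        ts = make_target_set({"a": 5.0, "b": 7.2, "c": 6.1})
        mmps = [self._mmp(), self._mmp("a", "c"), self._mmp("b", "c")]
        at2 = {(c.cpd_low, c.cpd_high) for c in detect_cliffs(mmps, ts, 2.0)}
        at1 = {(c.cpd_low, c.cpd_high) for c in detect_cliffs(mmps, ts, 1.0)}
        assert at2 <= at1
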