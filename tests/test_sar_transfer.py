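import numpy as np
import pytest
from rdkit import Chem

from mmptk.fragmentation import all_cuts
from mmptk.sar_transfer import (
    MatchingSeries,
    classify_progression,
    extract_series,
    find_matching,
)
from tests.conftest import make_target_set, std

CANON = Chem.CanonSmiles


def matching(pa, pb, subs=None):
    subs = subs or [f"[*]S{i}" for i in range(len(pa))]
    return MatchingSeries(
        target_id="T1",
        measurement_kind="Ki",
        core_a="[*]A",
        core_b="[*]B",
        pairs=tuple(zip(subs, pa, pb)),
        span_a=max(pa) - min(pa),
        span_b=max(pb) - min(pb),
    )


class TestExtractSeries:
    def test_para_substituted_benzamides_form_one_series(self):
        smiles = {
            "c1": "NC(=O)c1ccc(C)cc1",
            "c2": "NC(=O)c1ccc(CC)cc1",
            "c3": "NC(=O)c1ccc(Cl)cc1",
            "c4": "NC(=O)c1ccc(OC)cc1",
        }
        ts = make_target_set({c: 5.0 + i for i, c in enumerate(smiles)})
        cuts = {c: all_cuts(std(s, c)) for c, s in smiles.items()}
        series = extract_series(ts, cuts)
        core = CANON("[*]c1ccc(C(N)=O)cc1")
        s = next(x for x in series if x.core_smiles == core)
        assert len(s) == 4

    def test_singleton_target_set_gives_singleton_series(self):
        ts = make_target_set({"a": 5.0})
        series = extract_series(ts, {"a": all_cuts(std("Cc1ccccc1", "a"))})
        assert series and all(len(s) == 1 for s in series)

    def test_symmetric_cut_sites_collapse(self):
        # p-xylene has two equivalent methyls; one membership under the tolyl core
        ts = make_target_set({"a": 5.0})
        series = extract_series(ts, {"a": all_cuts(std("Cc1ccc(C)cc1", "a"))})
        tolyl = next(s for s in series if s.core_smiles == CANON("[*]c1ccc(C)cc1"))
        assert len(tolyl) == 1

    def test_size_rules_respected(self):
        ts = make_target_set({"a": 5.0})
        series = extract_series(ts, {"a": all_cuts(std("Cc1ccccc1", "a"))})
        # methyl core (1 heavy) with phenyl substituent (6 heavy) violates core >= 2x frag
        assert all(s.core_smiles != CANON("[*]C") for s in series)


class TestFindMatching:
    def _series_pair(self, shared=3, span=2.2):
        smiles_a = {"a0": "Cc1ccccc1", "a1": "CCc1ccccc1", "a2": "Clc1ccccc1"}
        smiles_b = {"b0": "Cc1ccc2ccccc2c1", "b1": "CCc1ccc2ccccc2c1", "b2": "Clc1ccc2ccccc2c1"}
        pots = {"a0": 5.0, "a1": 6.1, "a2": 5.0 + span, "b0": 5.5, "b1": 6.6, "b2": 5.5 + span}
        ts = make_target_set(pots)
        cuts = {c: all_cuts(std(s, c)) for c, s in {**smiles_a, **smiles_b}.items()}
        return extract_series(ts, cuts)

    def test_three_shared_substituents_with_span(self):
        out = find_matching(self._series_pair())
        assert len(out) == 1
        m = out[0]
        assert len(m.pairs) == 3
        assert {m.core_a, m.core_b} == {CANON("[*]c1ccccc1"), CANON("[*]c1ccc2ccccc2c1")}

    def test_intersection_below_min_pairs_rejected(self):
        series = self._series_pair()
        assert find_matching(series, min_pairs=4) == []

    def test_insufficient_span_rejected(self):
        out = find_matching(self._series_pair(span=1.5))
        assert out == []


class TestClassifyProgression:
    def test_identical_ranking_is_regular(self):
        t = classify_progression(matching([5, 6, 7], [6, 7, 8]))
        assert t.progression == "regular" and t.rank_correlation == 1.0

    def test_spearman_point_eight_is_approximate(self):
        # n=4, one adjacent swap: sum d^2 = 2, rho = 1 - 12/60 = 0.8
        t = classify_progression(matching([5, 6, 7, 8], [5, 7, 6, 8]))
        assert t.progression == "approximate"
        assert t.rank_correlation == pytest.approx(0.8)

    def test_spearman_point_five_is_no_transfer(self):
        # n=3, one swap: sum d^2 = 2, rho = 1 - 12/24 = 0.5
        assert classify_progression(matching([5, 6, 7], [5, 7, 6])) is None

    def test_custom_threshold(self):
        m = matching([5, 6, 7], [5, 7, 6])
        assert classify_progression(m, approx_threshold=0.5).progression == "approximate"

    def test_ties_disqualify_regular(self):
        t = classify_progression(matching([5, 6, 7], [6, 6, 8]))
        assert t is None or t.progression != "regular"

    def test_symmetric_for_regular_class(self):
        pa, pb = [5.0, 6.2, 7.1], [6.0, 6.9, 8.3]
        fwd = classify_progression(matching(pa, pb))
        rev = classify_progression(matching(pb, pa))
        assert fwd.progression == rev.progression == "regular"

    def test_derangement_destroys_regular(self):
        rng = np.random.default_rng(7)
        pa = [5.0, 5.8, 6.7, 7.5, 8.2]
        pb = list(np.array(pa) + 0.4)
        assert classify_progression(matching(pa, pb)).progression == "regular"
        # derange the partner potencies: no index keeps its value
        perm = [2, 0, 4, 1, 3]
        deranged = [pb[i] for i in perm]
        out = classify_progression(matching(pa, deranged))
        assert out is None or out.progression != "regular"


def test_nesting_regular_within_transfer_within_matching():
    rng = np.random.default_rng(11)
    n_matching = n_transfer = n_regular = 0
    for _ in range(25):
        n = int(rng.integers(3, 7))
        pa = sorted(rng.uniform(5, 9, size=n))
        pb = rng.permutation(pa) + rng.normal(0, 0.2, size=n)
        m = matching(list(pa), list(pb))
        n_matching += 1
        t = classify_progression(m)
        if t:
            n_transfer += 1
            if t.progression == "regular":
                n_regular += 1
    assert n_regular <= n_transfer <= n_matching
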