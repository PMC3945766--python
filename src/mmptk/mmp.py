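"""MMP assembly, transformation size rules, and activity-cliff detection.

Two compounds in a target set form a matched molecular pair (MMP) when
they share a fragmentation core and differ only in the exchanged
fragment.  Transformation size restrictions keep the exchange a
chemically meaningful substitution: the shared core must be at least
twice the size of each exchanged fragment, the fragments may differ by
at most eight heavy atoms, and neither fragment may exceed 13 heavy
atoms.  The largest permitted transformations therefore include e.g.
the addition of a substituted ring, or swapping a five- or
six-membered ring for a substituted fused two-ring system.

An MMP whose partners' potencies differ by at least two orders of
magnitude is an MMP-cliff; a one-order threshold gives the relaxed
cliff set.  Cliff sets are nested: raising the threshold never adds a
cliff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from mmptk.curation import TargetSet
from mmptk.fragmentation import Cut, FragmentIndex

#: Absolute tolerance on potency-difference comparisons; absorbs the
#: round-trip through nM values (pPotency -> nM -> pPotency).
POTENCY_TOL = 1e-9


@dataclass(frozen=True)
class Transformation:
    """The exchanged substructure pair, direction-normalized."""

    frag_left: str
    frag_right: str

    @property
    def notation(self) -> str:
        return f"{self.frag_left}>>{self.frag_right}"


@dataclass(frozen=True)
class MMP:
    """A matched molecular pair within one target set.

    ``cpd_a < cpd_b`` under string ordering; ``frag_a`` belongs to
    ``cpd_a``.  The stored transformation is direction-normalized
    (left fragment lexicographically <= right); cliff reporting
    re-derives the potency-ordered orientation.
    """

    cpd_a: str
    cpd_b: str
    core_smiles: str
    frag_a: str
    frag_b: str
    core_heavy: int
    frag_a_heavy: int
    frag_b_heavy: int
    target_id: str
    measurement_kind: str

    @property
    def transformation(self) -> Transformation:
        left, right = sorted((self.frag_a, self.frag_b))
        return Transformation(frag_left=left, frag_right=right)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cpd_a, self.cpd_b)


@dataclass(frozen=True)
class MMPCliff:
    """An MMP with a potency difference at or above the cliff threshold."""

    mmp: MMP
    cpd_low: str
    cpd_high: str
    pPot_low: float
    pPot_high: float

    @property
    def delta(self) -> float:
        return self.pPot_high - self.pPot_low


def apply_size_rules(
    core_heavy: int,
    frag_a_heavy: int,
    frag_b_heavy: int,
    core_multiple: int = 2,
    max_diff: int = 8,
    max_frag: int = 13,
) -> bool:
    """Transformation size restrictions on a candidate pair.

    True iff the core is at least ``core_multiple`` times the size of
    each exchanged fragment, the fragment sizes differ by at most
    ``max_diff`` heavy atoms, and neither fragment exceeds ``max_frag``
    heavy atoms.  All bounds are inclusive.
    """
    return (
        core_heavy >= core_multiple * frag_a_heavy
        and core_heavy >= core_multiple * frag_b_heavy
        and abs(frag_a_heavy - frag_b_heavy) <= max_diff
        and max(frag_a_heavy, frag_b_heavy) <= max_frag
    )


def _candidate(
    core: str,
    cid_i: str,
    frag_i: str,
    cid_j: str,
    frag_j: str,
    heavy: Mapping[str, int],
    core_heavy: int,
    target_set: TargetSet,
) -> MMP:
    if cid_i > cid_j:
        cid_i, cid_j = cid_j, cid_i
        frag_i, frag_j = frag_j, frag_i
    return MMP(
        cpd_a=cid_i,
        cpd_b=cid_j,
        core_smiles=core,
        frag_a=frag_i,
        frag_b=frag_j,
        core_heavy=core_heavy,
        frag_a_heavy=heavy[frag_i],
        frag_b_heavy=heavy[frag_j],
        target_id=target_set.target_id,
        measurement_kind=target_set.measurement_kind,
    )


def select_canonical(pair_candidates: Sequence[MMP]) -> MMP:
    """Pick one canonical MMP among candidates relating the same pair.

    The winner minimizes (largest fragment, total fragment size,
    core SMILES lexicographic) — i.e. the decomposition with the
    largest shared context and the smallest single-site change.
    """
    if not pair_candidates:
        raise ValueError("empty candidate list")
    return min(
        pair_candidates,
        key=lambda m: (
            max(m.frag_a_heavy, m.frag_b_heavy),
            m.frag_a_heavy + m.frag_b_heavy,
            m.core_smiles,
        ),
    )


def assemble_mmps(
    index: FragmentIndex,
    target_set: TargetSet,
    core_multiple: int = 2,
    max_diff: int = 8,
    max_frag: int = 13,
    dedup: bool = True,
) -> list[MMP]:
    """Assemble size-restricted MMPs from a fragment index.

    Every unordered pair of index entries under one core with distinct
    compounds and distinct fragments that passes the size rules is a
    candidate.  With ``dedup`` (the default), one canonical MMP is kept
    per compound pair via :func:`select_canonical`; set it False for
    the exhaustive per-(pair, transformation) list.
    """
    from mmptk.structures import heavy_atoms

    heavy_cache: dict[str, int] = {}

    def _heavy(smi: str) -> int:
        if smi not in heavy_cache:
            heavy_cache[smi] = heavy_atoms(smi)
        return heavy_cache[smi]

    by_pair: dict[tuple[str, str], list[MMP]] = {}
    all_candidates: list[MMP] = []
    for core, entries in index.entries.items():
        if len(entries) < 2:
            continue
        core_heavy = _heavy(core)
        for (cid_i, frag_i), (cid_j, frag_j) in itertools.combinations(entries, 2):
            if cid_i == cid_j or frag_i == frag_j:
                continue
            fa, fb = _heavy(frag_i), _heavy(frag_j)
            if not apply_size_rules(core_heavy, fa, fb, core_multiple, max_diff, max_frag):
                continue
            cand = _candidate(core, cid_i, frag_i, cid_j, frag_j, heavy_cache, core_heavy, target_set)
            if dedup:
                by_pair.setdefault(cand.pair, []).append(cand)
            else:
                all_candidates.append(cand)
    if dedup:
        result = [select_canonical(cands) for _, cands in sorted(by_pair.items())]
    else:
        result = sorted(
            set(all_candidates),
            key=lambda m: (m.cpd_a, m.cpd_b, m.core_smiles, m.frag_a, m.frag_b),
        )
    return result


def detect_cliffs(
    mmps: Iterable[MMP],
    target_set: TargetSet,
    threshold_oom: float = 2.0,
) -> list[MMPCliff]:
    """MMPs whose potency difference reaches the cliff threshold (in OoM).

    Orientation is recorded from the less to the more potent compound.
    A missing potency means the curation contract was violated and
    raises ``KeyError``.
    """
    cliffs: list[MMPCliff] = []
    for mmp in mmps:
        pa = target_set.members[mmp.cpd_a]
        pb = target_set.members[mmp.cpd_b]
        if abs(pa - pb) >= threshold_oom - POTENCY_TOL:
            low, high = (mmp.cpd_a, mmp.cpd_b) if pa <= pb else (mmp.cpd_b, mmp.cpd_a)
            cliffs.append(
                MMPCliff(
                    mmp=mmp,
                    cpd_low=low,
                    cpd_high=high,
                    pPot_low=min(pa, pb),
                    pPot_high=max(pa, pb),
                )
            )
    return cliffs


def brute_force_pairs(
    cuts_by_compound: Mapping[str, Sequence[Cut]],
    target_set: TargetSet,
    core_multiple: int = 2,
    max_diff: int = 8,
    max_frag: int = 13,
) -> set[tuple[str, str, str, str, str]]:
    """All-pairs cut-intersection MMP enumeration (audit path).

    Compares every pair of compounds' cut lists directly, bypassing the
    fragment index, and returns the set of (cpd_a, cpd_b, core, frag_a,
    frag_b) tuples passing the size rules.  Quadratic in target-set
    size; used to verify index completeness on small sets, not for
    production runs.
    """
    out: set[tuple[str, str, str, str, str]] = set()
    cids = sorted(target_set.members)
    for i, ci in enumerate(cids):
        cuts_i = cuts_by_compound.get(ci, ())
        by_core_i: dict[str, set[str]] = {}
        for c in cuts_i:
            by_core_i.setdefault(c.core_smiles, set()).add(c.fragment_smiles)
        for cj in cids[i + 1 :]:
            for c in cuts_by_compound.get(cj, ()):
                frags_i = by_core_i.get(c.core_smiles)
                if not frags_i:
                    continue
                for fi in frags_i:
                    if fi == c.fragment_smiles:
                        continue
                    from mmptk.structures import heavy_atoms

                    fa, fb = heavy_atoms(fi), heavy_atoms(c.fragment_smiles)
                    if apply_size_rules(c.core_heavy, fa, fb, core_multiple, max_diff, max_frag):
                        out.add((ci, cj, c.core_smiles, fi, c.fragment_smiles))
    return out
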