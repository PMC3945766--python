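"""Target-based SAR transfer series.

Two analog series against the same target, built on different core
structures but containing pairwise corresponding substituents, may show
the same potency progression — in which case the SAR of one series
transfers to the other.  A qualifying ("matching") series pair has at
least three corresponding substituent pairs and spans at least two
orders of magnitude in potency on each side.  Progression is classified
from the rank agreement of the paired potencies: "regular" when the
rank orders correspond strictly (no ties), "approximate" when the
Spearman rank correlation reaches a configurable threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy import stats

from mmptk.curation import TargetSet
from mmptk.fragmentation import Cut
from mmptk.mmp import POTENCY_TOL

logger = logging.getLogger(__name__)


@dataclass
class Series:
    """An analog series: one core, substituent -> (compound, potency)."""

    target_id: str
    measurement_kind: str
    core_smiles: str
    members: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MatchingSeries:
    """Two series with distinct cores and corresponding substituents.

    ``pairs`` lists (substituent, pPotency in a, pPotency in b) for the
    shared substituents, sorted by substituent SMILES; spans are the
    potency ranges over the matched pairs only.
    """

    target_id: str
    measurement_kind: str
    core_a: str
    core_b: str
    pairs: tuple[tuple[str, float, float], ...]
    span_a: float
    span_b: float


@dataclass(frozen=True)
class SARTransferSeries:
    """A matching series with (at least approximate) potency progression."""

    matching: MatchingSeries
    progression: str  # "regular" | "approximate"
    rank_correlation: float


def extract_series(
    target_set: TargetSet,
    cuts_by_compound: Mapping[str, Sequence[Cut]],
    core_multiple: int = 2,
    max_frag: int = 13,
) -> list[Series]:
    """Group a target set's cuts into analog series keyed by core.

    Only decompositions passing the per-cut size rules (core at least
    ``core_multiple`` times the substituent, substituent at most
    ``max_frag`` heavy atoms) contribute, matching the size-restricted
    MMP basis of the analysis.  A compound contributes to every core it
    exhibits; symmetric cut sites collapse because members are keyed by
    canonical substituent.
    """
    by_core: dict[str, dict[str, tuple[str, float]]] = {}
    for cid in sorted(target_set.members):
        ppot = target_set.members[cid]
        for cut in cuts_by_compound.get(cid, ()):
            if cut.core_heavy < core_multiple * cut.fragment_heavy:
                continue
            if cut.fragment_heavy > max_frag:
                continue
            members = by_core.setdefault(cut.core_smiles, {})
            # one member per substituent; first (smallest cid) wins deterministically
            members.setdefault(cut.fragment_smiles, (cid, ppot))
    return [
        Series(
            target_id=target_set.target_id,
            measurement_kind=target_set.measurement_kind,
            core_smiles=core,
            members=by_core[core],
        )
        for core in sorted(by_core)
    ]


def find_matching(
    series_list: Sequence[Series],
    min_pairs: int = 3,
    min_span: float = 2.0,
) -> list[MatchingSeries]:
    """Pair up series with enough corresponding substituents and potency span.

    Every unordered pair of series with distinct cores whose
    substituent intersection has at least ``min_pairs`` members and
    whose matched-pair potency ranges both reach ``min_span`` (in
    orders of magnitude) qualifies.  Output is sorted by (core_a,
    core_b) with core_a < core_b.
    """
    out: list[MatchingSeries] = []
    for sa, sb in itertools.combinations(sorted(series_list, key=lambda s: s.core_smiles), 2):
        if sa.core_smiles == sb.core_smiles:
            continue
        shared = sorted(set(sa.members) & set(sb.members))
        if len(shared) < min_pairs:
            continue
        pa = [sa.members[f][1] for f in shared]
        pb = [sb.members[f][1] for f in shared]
        span_a = max(pa) - min(pa)
        span_b = max(pb) - min(pb)
        if span_a < min_span - POTENCY_TOL or span_b < min_span - POTENCY_TOL:
            continue
        overlap = {sa.members[f][0] for f in shared} & {sb.members[f][0] for f in shared}
        if overlap:
            logger.info(
                "compounds %s appear in both series %s / %s",
                sorted(overlap), sa.core_smiles, sb.core_smiles,
            )
        out.append(
            MatchingSeries(
                target_id=sa.target_id,
                measurement_kind=sa.measurement_kind,
                core_a=sa.core_smiles,
                core_b=sb.core_smiles,
                pairs=tuple((f, sa.members[f][1], sb.members[f][1]) for f in shared),
                span_a=span_a,
                span_b=span_b,
            )
        )
    return out


def _ranks(values: Sequence[float], substituents: Sequence[str]) -> tuple[list[int], bool]:
    """Ordinal ranks with deterministic tie-breaking by substituent SMILES.

    Returns (ranks, has_ties) where ties are potencies equal within
    POTENCY_TOL.
    """
    order = sorted(range(len(values)), key=lambda i: (values[i], substituents[i]))
    ranks = [0] * len(values)
    for rank, idx in enumerate(order):
        ranks[idx] = rank
    has_ties = any(
        abs(values[order[k]] - values[order[k + 1]]) < POTENCY_TOL
        for k in range(len(order) - 1)
    )
    return ranks, has_ties


def classify_progression(
    m: MatchingSeries,
    approx_threshold: float = 0.7,
) -> Optional[SARTransferSeries]:
    """Classify a matching series by potency-progression quality.

    Regular: the two series rank their shared substituents identically
    with no ties (Spearman correlation exactly 1).  Approximate: the
    Spearman rank correlation reaches ``approx_threshold`` without
    being regular.  Otherwise None — the matching series shows no SAR
    transfer.
    """
    subs = [p[0] for p in m.pairs]
    pa = [p[1] for p in m.pairs]
    pb = [p[2] for p in m.pairs]
    ranks_a, ties_a = _ranks(pa, subs)
    ranks_b, ties_b = _ranks(pb, subs)
    rho = float(stats.spearmanr(pa, pb).statistic)
    if ranks_a == ranks_b and not ties_a and not ties_b:
        return SARTransferSeries(matching=m, progression="regular", rank_correlation=1.0)
    if rho >= approx_threshold:
        return SARTransferSeries(matching=m, progression="approximate", rank_correlation=rho)
    return None
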