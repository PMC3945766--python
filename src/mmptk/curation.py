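"""High-confidence activity data curation.

Activity records are filtered to exact measurements (relation "="),
direct target interactions (relationship type "D") at the highest
target confidence level (score 9), for Ki or IC50 measurements with a
positive value in nM.  Replicate measurements of one compound against
one target are aggregated by geometric mean, provided all replicates
fall within one order of magnitude; otherwise the compound is
discarded.  Potencies are stored on the negative decadic log scale:
pPotency = 9 - log10(value in nM), i.e. pKi / pIC50.

Ki and IC50 data are never mixed: each (target, measurement kind) gets
its own target set.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from mmptk.structures import Molecule

logger = logging.getLogger(__name__)

MEASUREMENT_KINDS = ("Ki", "IC50")

#: Inclusive bound for the replicate window: max/min <= 10 passes.
#: The small relative slack absorbs round-trips through nM values.
_ONE_OOM_RATIO = 10.0 * (1.0 + 1e-12)


class _Discard:
    """Sentinel returned by :func:`aggregate_potency` for inconsistent replicates."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "DISCARD"


DISCARD = _Discard()


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement of a compound against a target."""

    compound_id: str
    target_id: str
    measurement_kind: str  # "Ki" or "IC50"
    relation: str  # qualifier: "=", ">", "<", "~", ...
    value_nM: Optional[float]
    confidence_score: int
    relationship_type: str  # single-character code; "D" = direct interaction
    activity_comment: str = ""  # e.g. "inactive", "inconclusive"


@dataclass
class TargetSet:
    """All curated compounds of one measurement kind against one target.

    ``members`` maps compound_id -> pPotency.  A compound appears at
    most once; structural duplicates were merged during curation.
    """

    target_id: str
    measurement_kind: str
    members: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


_INACTIVE_FLAGS = frozenset({"inactive", "inconclusive", "not active"})


def p_potency(value_nM: float) -> float:
    """pPotency (pKi/pIC50) of a potency in nM: 9 - log10(nM)."""
    if value_nM <= 0:
        raise ValueError(f"non-positive potency value: {value_nM}")
    return 9.0 - math.log10(value_nM)


def filter_records(
    records: Iterable[ActivityRecord],
    drop_counts: Optional[Counter] = None,
) -> list[ActivityRecord]:
    """Keep only high-confidence, exactly measured activity records.

    A record is retained iff relation is "=", confidence score is 9,
    relationship type is "D", the measurement kind is Ki or IC50, the
    value is present and positive, and no inactive/inconclusive flag is
    set.  Drop reasons are counted (pass ``drop_counts`` to collect
    them) and logged; filtering never raises.
    """
    counts = drop_counts if drop_counts is not None else Counter()
    kept: list[ActivityRecord] = []
    for rec in records:
        if rec.measurement_kind not in MEASUREMENT_KINDS:
            counts["measurement_kind"] += 1
        elif rec.value_nM is None or (rec.activity_comment or "").strip().lower() in _INACTIVE_FLAGS:
            counts["inactive_or_inconclusive"] += 1
        elif rec.relation != "=":
            counts["approximate_relation"] += 1
        elif rec.confidence_score != 9:
            counts["confidence_score"] += 1
        elif rec.relationship_type != "D":
            counts["relationship_type"] += 1
        elif rec.value_nM <= 0:
            counts["non_positive_value"] += 1
        else:
            kept.append(rec)
    n_dropped = sum(counts.values())
    if n_dropped:
        logger.info("filtered %d records: %s", n_dropped, dict(counts))
    return kept


def aggregate_potency(values_nM: Sequence[float]):
    """Aggregate replicate potencies to one pPotency, or DISCARD.

    Returns ``9 - log10(geometric mean)`` when all replicate values
    fall within one order of magnitude (max/min <= 10, inclusive);
    otherwise returns the :data:`DISCARD` sentinel and the compound is
    dropped from the target set.
    """
    if not values_nM:
        raise ValueError("empty replicate list")
    if any(v <= 0 for v in values_nM):
        raise ValueError("non-positive potency value (should be filtered upstream)")
    if max(values_nM) / min(values_nM) > _ONE_OOM_RATIO:
        return DISCARD
    gmean_log10 = sum(math.log10(v) for v in values_nM) / len(values_nM)
    return 9.0 - gmean_log10


def build_target_sets(
    records: Iterable[ActivityRecord],
    molecules: Mapping[str, Molecule],
    drop_counts: Optional[Counter] = None,
) -> list[TargetSet]:
    """Organize filtered records into per-(target, kind) target sets.

    Structural duplicates (identical canonical SMILES against the same
    target) are merged under the lexicographically smallest compound_id
    before replicate aggregation, so one structure never enters a
    target set twice.  Compounds whose replicates span more than one
    order of magnitude are discarded.  Records whose compound_id has no
    standardized structure are logged and skipped.
    """
    counts = drop_counts if drop_counts is not None else Counter()
    # (target, kind) -> canonical smiles -> {compound_ids, values}
    groups: dict[tuple[str, str], dict[str, dict]] = defaultdict(dict)
    for rec in records:
        mol = molecules.get(rec.compound_id)
        if mol is None:
            counts["missing_structure"] += 1
            logger.warning("no structure for compound %s; skipping", rec.compound_id)
            continue
        bucket = groups[(rec.target_id, rec.measurement_kind)]
        entry = bucket.setdefault(mol.canonical_smiles, {"cids": set(), "values": []})
        entry["cids"].add(rec.compound_id)
        entry["values"].append(rec.value_nM)

    target_sets: list[TargetSet] = []
    for (target_id, kind) in sorted(groups):
        members: dict[str, float] = {}
        for smiles in sorted(groups[(target_id, kind)]):
            entry = groups[(target_id, kind)][smiles]
            ppot = aggregate_potency(entry["values"])
            if ppot is DISCARD:
                counts["replicate_range"] += 1
                continue
            members[min(entry["cids"])] = ppot
        if members:
            target_sets.append(TargetSet(target_id=target_id, measurement_kind=kind, members=members))
    return target_sets
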