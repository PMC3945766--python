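import pandas as pd
import pytest

from mmptk.curation import ActivityRecord, TargetSet, build_target_sets, filter_records
from mmptk.structures import standardize


def std(smiles: str, cid: str = "X"):
    return standardize(smiles, compound_id=cid)


def make_target_set(potencies: dict[str, float], target_id="T1", kind="Ki") -> TargetSet:
    return TargetSet(target_id=target_id, measurement_kind=kind, members=dict(potencies))


def record(cid, value_nM, target="T1", kind="Ki", relation="=", conf=9, rel_type="D", comment=""):
    return ActivityRecord(
        compound_id=cid,
        target_id=target,
        measurement_kind=kind,
        relation=relation,
        value_nM=value_nM,
        confidence_score=conf,
        relationship_type=rel_type,
        activity_comment=comment,
    )


def curate_plan_tables(plan):
    """Run fixture tables through curation, returning (molecules, target_set)."""
    from mmptk.fixtures import generate

    compounds, activities, manifest = generate(plan)
    molecules = {r.compound_id: std(r.smiles, r.compound_id) for r in compounds.itertuples()}
    records = [
        record(r.compound_id, r.value_nM, target=r.target_id, kind=r.measurement_kind,
               relation=r.relation, conf=r.confidence_score, rel_type=r.relationship_type,
               comment=getattr(r, "activity_comment", "") or "")
        for r in activities.itertuples()
    ]
    sets = build_target_sets(filter_records(records), molecules)
    assert len(sets) == 1
    return molecules, sets[0], manifest


@pytest.fixture()
def write_plan_files(tmp_path):
    """Write a plan's tables to disk; returns (compounds_path, activities_path, manifest)."""

    def _write(plan, subdir="data"):
        from mmptk.fixtures import generate

        d = tmp_path / subdir
        d.mkdir(parents=True, exist_ok=True)
        compounds, activities, manifest = generate(plan)
        cpath, apath = d / "compounds.tsv", d / "activities.tsv"
        compounds.to_csv(cpath, sep="\t", index=False, lineterminator="\n")
        activities.to_csv(apath, sep="\t", index=False, lineterminator="\n")
        return cpath, apath, manifest

    return _write
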