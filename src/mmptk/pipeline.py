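"""End-to-end run orchestration, I/O, and the statistics report.

A run reads a compound table and an activity table, curates them into
per-(target, measurement kind) target sets, generates size-restricted
MMPs and (optionally) RECAP-MMPs, detects cliffs at each configured
potency-difference threshold, identifies SAR transfer series, and
writes per-target TSV outputs plus a JSON report whose counters mirror
the structure of the summary statistics tables: data set sizes, MMP
and cliff counts with compound coverage, RECAP-MMP counts, and
matching / transfer / regular series counts.  Ki and IC50 data are
processed and written separately throughout.

Outputs are deterministic: two runs with identical inputs, config and
seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from mmptk import curation, fragmentation, mmp as mmp_mod, recap as recap_mod, sar_transfer
from mmptk.curation import ActivityRecord, TargetSet
from mmptk.structures import Molecule, StandardizationError, standardize

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "measurement_kind": "measurement_kind",
    "relation": "relation",
    "value_nM": "value_nM",
    "confidence_score": "confidence_score",
    "relationship_type": "relationship_type",
    "activity_comment": "activity_comment",
}


@dataclass
class RunConfig:
    """Run parameterization.  The defaults are the reference settings:

    core at least 2x each exchanged fragment, fragment size difference
    at most 8 heavy atoms, fragments at most 13 heavy atoms; cliff
    thresholds of 1 and 2 orders of magnitude; SAR transfer requires at
    least 3 corresponding pairs spanning at least 2 orders of magnitude,
    with approximate progression at Spearman rho >= 0.7.
    """

    measurement_kind: Optional[str] = None  # None = all kinds present
    cliff_thresholds: tuple[float, ...] = (1.0, 2.0)
    core_multiple: int = 2
    max_diff: int = 8
    max_frag: int = 13
    scheme: str = "both"  # "standard" | "recap" | "both"
    min_pairs: int = 3
    min_span: float = 2.0
    approx_threshold: float = 0.7
    hydrogen_expansion: bool = True
    dedup_pairs: bool = True
    rules_path: Optional[str] = None
    seed: int = 0
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key = value config file (unknown keys rejected)."""
        cfg = cls()
        valid = set(asdict(cfg))
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid or key == "column_map":
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(cfg, key)
                if key == "cliff_thresholds":
                    setattr(cfg, key, tuple(float(v) for v in value.split(",")))
                elif isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("true", "1", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, None if value.lower() == "none" else value)
        return cfg


def read_compound_table(path, column_map: Optional[dict] = None) -> dict[str, Molecule]:
    """Read a delimited compound table into standardized molecules.

    Files ending in .smi are parsed as SMILES-whitespace-identifier
    lines; everything else as TSV/CSV with named columns.  Unparsable
    structures are logged and skipped.
    """
    path = Path(path)
    cmap = column_map or DEFAULT_COLUMN_MAP
    if path.suffix == ".smi":
        from mmptk.structures import read_smiles_file

        return {m.compound_id: m for m in read_smiles_file(path)}
    df = pd.read_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",", dtype=str)
    for col in (cmap["compound_id"], cmap["smiles"]):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    molecules: dict[str, Molecule] = {}
    for _, row in df.iterrows():
        cid = str(row[cmap["compound_id"]])
        try:
            molecules[cid] = standardize(str(row[cmap["smiles"]]), compound_id=cid)
        except StandardizationError as exc:
            logger.warning("skipping compound %s: %s", cid, exc)
    return molecules


def read_activity_table(path, column_map: Optional[dict] = None) -> list[ActivityRecord]:
    """Read a delimited activity table into activity records."""
    path = Path(path)
    cmap = column_map or DEFAULT_COLUMN_MAP
    df = pd.read_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",")
    required = ["compound_id", "target_id", "measurement_kind", "relation",
                "value_nM", "confidence_score", "relationship_type"]
    for key in required:
        if cmap[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cmap[key]!r}")
    has_comment = cmap["activity_comment"] in df.columns
    records = []
    for _, row in df.iterrows():
        value = row[cmap["value_nM"]]
        records.append(
            ActivityRecord(
                compound_id=str(row[cmap["compound_id"]]),
                target_id=str(row[cmap["target_id"]]),
                measurement_kind=str(row[cmap["measurement_kind"]]),
                relation=str(row[cmap["relation"]]),
                value_nM=None if pd.isna(value) else float(value),
                confidence_score=int(row[cmap["confidence_score"]]),
                relationship_type=str(row[cmap["relationship_type"]]),
                activity_comment="" if not has_comment or pd.isna(row[cmap["activity_comment"]]) else str(row[cmap["activity_comment"]]),
            )
        )
    return records


def _safe_name(target_id: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in target_id)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_target_set(ts: TargetSet, molecules: dict[str, Molecule], path: Path) -> None:
    rows = [
        {
            "compound_id": cid,
            "canonical_smiles": molecules[cid].canonical_smiles,
            "pPotency": round(ts.members[cid], 6),
        }
        for cid in sorted(ts.members)
    ]
    _write_tsv(pd.DataFrame(rows, columns=["compound_id", "canonical_smiles", "pPotency"]), path)


def _mmp_rows(mmps, ts: TargetSet, molecules, scheme: str) -> pd.DataFrame:
    rows = []
    for m in mmps:
        rows.append(
            {
                "target_id": m.target_id,
                "cpd_a": m.cpd_a,
                "cpd_b": m.cpd_b,
                "smiles_a": molecules[m.cpd_a].canonical_smiles,
                "smiles_b": molecules[m.cpd_b].canonical_smiles,
                "core": m.core_smiles,
                "transformation": m.transformation.notation,
                "pPot_a": round(ts.members[m.cpd_a], 6),
                "pPot_b": round(ts.members[m.cpd_b], 6),
                "delta": round(abs(ts.members[m.cpd_a] - ts.members[m.cpd_b]), 6),
                "scheme": scheme,
            }
        )
    cols = ["target_id", "cpd_a", "cpd_b", "smiles_a", "smiles_b", "core",
            "transformation", "pPot_a", "pPot_b", "delta", "scheme"]
    return pd.DataFrame(rows, columns=cols)


def _series_rows(transfers, matchings) -> pd.DataFrame:
    by_key = {(t.matching.core_a, t.matching.core_b): t for t in transfers}
    rows = []
    for m in matchings:
        t = by_key.get((m.core_a, m.core_b))
        rows.append(
            {
                "target_id": m.target_id,
                "core_a": m.core_a,
                "core_b": m.core_b,
                "n_pairs": len(m.pairs),
                "substituents": ";".join(p[0] for p in m.pairs),
                "pPot_a": ";".join(f"{p[1]:.4f}" for p in m.pairs),
                "pPot_b": ";".join(f"{p[2]:.4f}" for p in m.pairs),
                "span_a": round(m.span_a, 6),
                "span_b": round(m.span_b, 6),
                "progression": t.progression if t else "none",
                "rank_correlation": round(t.rank_correlation, 6) if t else "",
            }
        )
    cols = ["target_id", "core_a", "core_b", "n_pairs", "substituents", "pPot_a",
            "pPot_b", "span_a", "span_b", "progression", "rank_correlation"]
    return pd.DataFrame(rows, columns=cols)


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else 0.0


def run_pipeline(
    config: RunConfig,
    compounds_path,
    activities_path,
    out_dir,
) -> dict:
    """Execute the full pipeline and write a run directory.

    Per (target, measurement kind): the curated target set, MMP and
    cliff tables, RECAP-MMP tables and SAR transfer series tables, all
    as TSV; plus one report.json with the aggregated counters.  Returns
    the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    molecules = read_compound_table(compounds_path, config.column_map)
    records = read_activity_table(activities_path, config.column_map)
    if config.measurement_kind:
        records = [r for r in records if r.measurement_kind == config.measurement_kind]

    drop_counts: Counter = Counter()
    kept = curation.filter_records(records, drop_counts)
    target_sets = curation.build_target_sets(kept, molecules, drop_counts)

    rules = (
        recap_mod.load_rules(config.rules_path)
        if config.rules_path
        else recap_mod.default_rules()
    )

    do_standard = config.scheme in ("standard", "both")
    do_recap = config.scheme in ("recap", "both")

    report: dict = {
        "config": {
            "cliff_thresholds": list(config.cliff_thresholds),
            "core_multiple": config.core_multiple,
            "max_diff": config.max_diff,
            "max_frag": config.max_frag,
            "scheme": config.scheme,
            "min_pairs": config.min_pairs,
            "min_span": config.min_span,
            "approx_threshold": config.approx_threshold,
            "hydrogen_expansion": config.hydrogen_expansion,
            "seed": config.seed,
        },
        "curation": {
            "records_in": len(records),
            "records_kept": len(kept),
            "dropped": dict(sorted(drop_counts.items())),
        },
        "kinds": {},
    }

    kinds = sorted({ts.measurement_kind for ts in target_sets})
    for kind in kinds:
        sets_k = [ts for ts in target_sets if ts.measurement_kind == kind]
        kind_report = {
            "n_targets": len(sets_k),
            "n_compounds": sum(len(ts) for ts in sets_k),
            "n_measurements": sum(
                1 for r in kept if r.measurement_kind == kind
            ),
        }
        n_mmps = n_mmps_exhaustive = 0
        targets_with_mmps: set[str] = set()
        mmp_compounds: set[tuple[str, str]] = set()
        cliff_stats = {
            f"{t:g}": {"n": 0, "targets": set(), "compounds": set()}
            for t in config.cliff_thresholds
        }
        n_recap = 0
        recap_targets: set[str] = set()
        recap_compounds: set[tuple[str, str]] = set()
        n_matching = n_transfer = n_regular = 0
        transfer_targets: set[str] = set()
        regular_targets: set[str] = set()

        for ts in sets_k:
            tdir = out_dir / kind / _safe_name(ts.target_id)
            write_target_set(ts, molecules, tdir / "target_set.tsv")
            cuts = {
                cid: fragmentation.all_cuts(molecules[cid], hydrogen=config.hydrogen_expansion)
                for cid in sorted(ts.members)
            }
            if do_standard:
                index = fragmentation.build_index(ts, cuts)
                mmps = mmp_mod.assemble_mmps(
                    index, ts, config.core_multiple, config.max_diff,
                    config.max_frag, dedup=config.dedup_pairs,
                )
                exhaustive = mmp_mod.assemble_mmps(
                    index, ts, config.core_multiple, config.max_diff,
                    config.max_frag, dedup=False,
                )
                _write_tsv(_mmp_rows(mmps, ts, molecules, "standard"), tdir / "mmps.tsv")
                n_mmps += len(mmps)
                n_mmps_exhaustive += len(exhaustive)
                if mmps:
                    targets_with_mmps.add(ts.target_id)
                for m in mmps:
                    mmp_compounds.add((ts.target_id, m.cpd_a))
                    mmp_compounds.add((ts.target_id, m.cpd_b))
                for t in config.cliff_thresholds:
                    cliffs = mmp_mod.detect_cliffs(mmps, ts, t)
                    key = f"{t:g}"
                    cliff_stats[key]["n"] += len(cliffs)
                    if cliffs:
                        cliff_stats[key]["targets"].add(ts.target_id)
                    for c in cliffs:
                        cliff_stats[key]["compounds"].add((ts.target_id, c.cpd_low))
                        cliff_stats[key]["compounds"].add((ts.target_id, c.cpd_high))
                    _write_tsv(
                        _mmp_rows([c.mmp for c in cliffs], ts, molecules, "standard"),
                        tdir / f"cliffs_{key}oom.tsv",
                    )
                # SAR transfer rides on the standard (hydrogen-expanded) cuts
                series = sar_transfer.extract_series(
                    ts, cuts, config.core_multiple, config.max_frag
                )
                matchings = sar_transfer.find_matching(series, config.min_pairs, config.min_span)
                transfers = [
                    t_
                    for m in matchings
                    if (t_ := sar_transfer.classify_progression(m, config.approx_threshold))
                ]
                _write_tsv(_series_rows(transfers, matchings), tdir / "sar_transfer.tsv")
                n_matching += len(matchings)
                n_transfer += len(transfers)
                n_regular += sum(1 for t_ in transfers if t_.progression == "regular")
                if transfers:
                    transfer_targets.add(ts.target_id)
                if any(t_.progression == "regular" for t_ in transfers):
                    regular_targets.add(ts.target_id)
            if do_recap:
                retro_cuts = {
                    cid: recap_mod.enumerate_retro_cuts(molecules[cid], rules)
                    for cid in sorted(ts.members)
                }
                retro_index = fragmentation.build_index(ts, retro_cuts)
                recap_mmps = mmp_mod.assemble_mmps(
                    retro_index, ts, config.core_multiple, config.max_diff,
                    config.max_frag, dedup=config.dedup_pairs,
                )
                _write_tsv(_mmp_rows(recap_mmps, ts, molecules, "recap"), tdir / "recap_mmps.tsv")
                n_recap += len(recap_mmps)
                if recap_mmps:
                    recap_targets.add(ts.target_id)
                for m in recap_mmps:
                    recap_compounds.add((ts.target_id, m.cpd_a))
                    recap_compounds.add((ts.target_id, m.cpd_b))

        total_cpds = kind_report["n_compounds"]
        if do_standard:
            kind_report["mmps"] = {
                "n_mmps": n_mmps,
                "n_mmps_exhaustive": n_mmps_exhaustive,
                "targets_with_mmps": len(targets_with_mmps),
                "mmp_compounds": len(mmp_compounds),
                "mmp_compounds_pct": _pct(len(mmp_compounds), total_cpds),
            }
            kind_report["cliffs"] = {
                key: {
                    "n_cliffs": st["n"],
                    "pct_of_mmps": _pct(st["n"], n_mmps),
                    "targets_with_cliffs": len(st["targets"]),
                    "cliff_compounds": len(st["compounds"]),
                    "cliff_compounds_pct": _pct(len(st["compounds"]), total_cpds),
                }
                for key, st in cliff_stats.items()
            }
            kind_report["sar_transfer"] = {
                "matching_series": n_matching,
                "transfer_series": n_transfer,
                "targets_with_transfer_series": len(transfer_targets),
                "regular_series": n_regular,
                "targets_with_regular_series": len(regular_targets),
            }
        if do_recap:
            kind_report["recap"] = {
                "n_recap_mmps": n_recap,
                "targets_with_recap_mmps": len(recap_targets),
                "recap_mmp_compounds": len(recap_compounds),
                "recap_mmp_compounds_pct": _pct(len(recap_compounds), total_cpds),
            }
        report["kinds"][kind] = kind_report

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out_dir)
    return report
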