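"""Deterministic synthetic target sets with a combinatorial ground truth.

A fixture plan assembles an analog grid — scaffolds with one open
valence crossed with a list of substituents — and assigns potencies by
an additive model: pKi = base + core effect + substituent effect
(+ optional seeded Gaussian noise).  The same grid structure is what a
medicinal-chemistry series looks like to the pipeline, so every stage
(curation, MMP assembly, cliff detection, RECAP restriction, SAR
transfer) can be verified against counts derived combinatorially from
the plan instead of a database download.

The combinatorial oracle enumerates matched pairs per scaffold subject
to the transformation size rules, cliff pairs from potency deltas,
retro-eligible pairs from junction bond classes, and matching/regular
series from the shared substituent grid.  It is exact for the curated
plans shipped here, whose scaffolds and substituents are chosen so that
no decomposition outside the planted grid can satisfy the size rules
(scaffolds of six or more heavy atoms, substituents of at most four;
see docs/methods.md for the argument).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mmptk.fragmentation import reattach
from mmptk.mmp import POTENCY_TOL, apply_size_rules
from mmptk.structures import HYDROGEN_FRAGMENT, canonical_smiles, heavy_atoms, standardize


class FixtureError(ValueError):
    """Raised when a plan cannot be realized chemically."""


@dataclass(frozen=True)
class FixturePlan:
    """Recipe for one synthetic target set.

    ``cores`` are scaffold SMILES with one attachment atom;
    ``substituents`` are fragment SMILES (the hydrogen pseudo-fragment
    is allowed).  Potency of compound (i, j) is
    ``base_pki + core_effects[i] + substituent_effects[j]`` plus
    Gaussian noise of ``noise_sd`` log units when nonzero.
    ``junction_retro[j]`` declares whether the scaffold-substituent
    junction bond of substituent j is a retrosynthetic bond class
    (amide, sulfonamide, ...), which the oracle uses to count
    RECAP-eligible pairs.  ``pair_stems`` optionally records the
    heavy-atom size of the common rooted stem two substituents share
    (e.g. the C=O of two acyl groups), which enlarges the shared core
    available to that pair.

    Same seed and plan always produce byte-identical tables.
    """

    seed: int
    cores: tuple[str, ...]
    substituents: tuple[str, ...]
    core_effects: tuple[float, ...]
    substituent_effects: tuple[float, ...]
    base_pki: float = 5.5
    noise_sd: float = 0.0
    target_id: str = "TGT-001"
    measurement_kind: str = "Ki"
    junction_retro: Optional[tuple[bool, ...]] = None
    pair_stems: tuple[tuple[int, int, int], ...] = ()  # (j1, j2, stem_heavy)
    planted_bad_records: int = 0
    planted_cliff_pairs: Optional[int] = None  # validated against the oracle when set
    planted_regular_series: Optional[int] = None

    def __post_init__(self):
        if len(self.cores) != len(self.core_effects):
            raise FixtureError("cores and core_effects length mismatch")
        if len(self.substituents) != len(self.substituent_effects):
            raise FixtureError("substituents and substituent_effects length mismatch")
        if self.junction_retro is not None and len(self.junction_retro) != len(self.substituents):
            raise FixtureError("junction_retro and substituents length mismatch")


def compound_id(plan: FixturePlan, i: int, j: int) -> str:
    # namespaced by target so grids from several plans can be concatenated
    return f"{plan.target_id}-{i:02d}-{j:02d}"


def _assemble_grid(plan: FixturePlan) -> dict[tuple[int, int], str]:
    """Reassemble every core x substituent combination; validate uniqueness."""
    smiles: dict[tuple[int, int], str] = {}
    seen: dict[str, tuple[int, int]] = {}
    for i, core in enumerate(plan.cores):
        for j, sub in enumerate(plan.substituents):
            try:
                smi = reattach(core, sub)
            except Exception as exc:
                raise FixtureError(f"invalid combination core={core!r} substituent={sub!r}: {exc}") from exc
            canon = standardize(smi).canonical_smiles
            if canon in seen:
                raise FixtureError(
                    f"duplicate structure {canon!r} from (core {i}, sub {j}) and {seen[canon]}"
                )
            seen[canon] = (i, j)
            smiles[(i, j)] = canon
    return smiles


def _potency_matrix(plan: FixturePlan) -> np.ndarray:
    rng = np.random.default_rng(plan.seed)
    pki = np.array(
        [
            [plan.base_pki + ce + se for se in plan.substituent_effects]
            for ce in plan.core_effects
        ]
    )
    if plan.noise_sd > 0:
        pki = pki + rng.normal(0.0, plan.noise_sd, size=pki.shape)
    return pki


def _stem(plan: FixturePlan, j1: int, j2: int) -> int:
    for a, b, s in plan.pair_stems:
        if {a, b} == {j1, j2}:
            return s
    return 0


def _spearman(xs: Sequence[float], ys: Sequence[float]) -> float:
    from scipy import stats

    return float(stats.spearmanr(xs, ys).statistic)


def _rank_order(values: Sequence[float]) -> tuple[list[int], bool]:
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0] * len(values)
    for r, k in enumerate(order):
        ranks[k] = r
    ties = any(
        abs(values[order[k]] - values[order[k + 1]]) < POTENCY_TOL
        for k in range(len(order) - 1)
    )
    return ranks, ties


def oracle_manifest(
    plan: FixturePlan,
    cliff_thresholds: Sequence[float] = (1.0, 2.0),
    min_pairs: int = 3,
    min_span: float = 2.0,
    approx_threshold: float = 0.7,
) -> dict:
    """Expected pipeline outputs, derived combinatorially from the plan.

    Enumerates matched pairs within each scaffold (using the junction
    decomposition enlarged by any declared pair stem), same-substituent
    pairs across scaffolds (with the substituent as the shared core),
    cliff pairs from the assigned potencies, retro-eligible pairs from
    the declared junction bond classes, and matching / transfer /
    regular series from the shared substituent grid.
    """
    pki = _potency_matrix(plan)
    core_h = [heavy_atoms(c) for c in plan.cores]
    sub_h = [heavy_atoms(s) for s in plan.substituents]
    retro = plan.junction_retro or tuple(False for _ in plan.substituents)
    n_cores, n_subs = len(plan.cores), len(plan.substituents)

    mmp_pairs: list[tuple[str, str]] = []
    recap_pairs: list[tuple[str, str]] = []
    deltas: dict[tuple[str, str], float] = {}
    # within-scaffold pairs: shared core is scaffold (+ common stem)
    for i in range(n_cores):
        for j1, j2 in itertools.combinations(range(n_subs), 2):
            stem = _stem(plan, j1, j2)
            pair = tuple(sorted((compound_id(plan, i, j1), compound_id(plan, i, j2))))
            if apply_size_rules(core_h[i] + stem, sub_h[j1] - stem, sub_h[j2] - stem):
                mmp_pairs.append(pair)
                deltas[pair] = abs(pki[i, j1] - pki[i, j2])
            # RECAP cuts happen at the junction only, so no stem enlargement
            if (
                retro[j1]
                and retro[j2]
                and apply_size_rules(core_h[i], sub_h[j1], sub_h[j2])
            ):
                recap_pairs.append(pair)
    # cross-scaffold pairs sharing a substituent: shared core is the substituent
    for j in range(n_subs):
        if plan.substituents[j] == HYDROGEN_FRAGMENT:
            continue
        for i1, i2 in itertools.combinations(range(n_cores), 2):
            if apply_size_rules(sub_h[j], core_h[i1], core_h[i2]):
                pair = tuple(sorted((compound_id(plan, i1, j), compound_id(plan, i2, j))))
                mmp_pairs.append(pair)
                deltas[pair] = abs(pki[i1, j] - pki[i2, j])

    cliffs = {
        f"{t:g}": sorted(p for p in mmp_pairs if deltas[p] >= t - POTENCY_TOL)
        for t in cliff_thresholds
    }

    # series: substituents legal under each scaffold's junction core
    legal = [
        [j for j in range(n_subs) if core_h[i] >= 2 * sub_h[j] and sub_h[j] <= 13]
        for i in range(n_cores)
    ]
    matching: list[dict] = []
    n_regular = 0
    n_transfer = 0
    for i1, i2 in itertools.combinations(range(n_cores), 2):
        shared = sorted(set(legal[i1]) & set(legal[i2]))
        if len(shared) < min_pairs:
            continue
        pa = [pki[i1, j] for j in shared]
        pb = [pki[i2, j] for j in shared]
        if max(pa) - min(pa) < min_span - POTENCY_TOL:
            continue
        if max(pb) - min(pb) < min_span - POTENCY_TOL:
            continue
        ranks_a, ties_a = _rank_order(pa)
        ranks_b, ties_b = _rank_order(pb)
        regular = ranks_a == ranks_b and not ties_a and not ties_b
        rho = _spearman(pa, pb)
        progression = "regular" if regular else ("approximate" if rho >= approx_threshold else "none")
        if progression == "regular":
            n_regular += 1
        if progression in ("regular", "approximate"):
            n_transfer += 1
        matching.append(
            {
                "core_a": canonical_smiles(plan.cores[i1]),
                "core_b": canonical_smiles(plan.cores[i2]),
                "n_shared": len(shared),
                "progression": progression,
            }
        )

    manifest = {
        "target_id": plan.target_id,
        "measurement_kind": plan.measurement_kind,
        "n_compounds": n_cores * n_subs,
        "compounds": {
            compound_id(plan, i, j): {"pki": float(pki[i, j])}
            for i in range(n_cores)
            for j in range(n_subs)
        },
        "mmp_pairs": sorted(mmp_pairs),
        "n_mmps": len(mmp_pairs),
        "cliff_pairs": cliffs,
        "n_cliffs": {t: len(v) for t, v in cliffs.items()},
        "recap_pairs": sorted(recap_pairs),
        "n_recap_mmps": len(recap_pairs),
        "matching_series": matching,
        "n_matching_series": len(matching),
        "n_transfer_series": n_transfer,
        "n_regular_series": n_regular,
        "n_bad_records": plan.planted_bad_records,
    }
    if plan.planted_cliff_pairs is not None and manifest["n_cliffs"].get("2") != plan.planted_cliff_pairs:
        raise FixtureError(
            f"plan declares {plan.planted_cliff_pairs} cliff pairs but the oracle finds "
            f"{manifest['n_cliffs'].get('2')}"
        )
    if plan.planted_regular_series is not None and n_regular != plan.planted_regular_series:
        raise FixtureError(
            f"plan declares {plan.planted_regular_series} regular series but the oracle finds {n_regular}"
        )
    return manifest


_BAD_RECORD_CYCLE = (
    {"relation": ">", "reason": "approximate_relation"},
    {"relation": "<", "reason": "approximate_relation"},
    {"relation": "~", "reason": "approximate_relation"},
    {"confidence_score": 8, "reason": "confidence_score"},
    {"relationship_type": "H", "reason": "relationship_type"},
    {"activity_comment": "inactive", "reason": "inactive_or_inconclusive"},
)


def generate(plan: FixturePlan) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit (compound table, activity table, ground-truth manifest).

    The compound table has columns compound_id, smiles; the activity
    table follows the curation column map (compound_id, target_id,
    measurement_kind, relation, value_nM, confidence_score,
    relationship_type, activity_comment).  ``planted_bad_records``
    appends records that the curation filters must drop, listed with
    their reasons in the manifest.
    """
    grid = _assemble_grid(plan)
    pki = _potency_matrix(plan)
    manifest = oracle_manifest(plan)
    for (i, j), smi in grid.items():
        manifest["compounds"][compound_id(plan, i, j)]["smiles"] = smi

    compounds = pd.DataFrame(
        [
            {"compound_id": compound_id(plan, i, j), "smiles": grid[(i, j)]}
            for i in range(len(plan.cores))
            for j in range(len(plan.substituents))
        ]
    )
    rows = []
    for i in range(len(plan.cores)):
        for j in range(len(plan.substituents)):
            rows.append(
                {
                    "compound_id": compound_id(plan, i, j),
                    "target_id": plan.target_id,
                    "measurement_kind": plan.measurement_kind,
                    "relation": "=",
                    "value_nM": 10.0 ** (9.0 - pki[i, j]),
                    "confidence_score": 9,
                    "relationship_type": "D",
                    "activity_comment": "",
                }
            )
    bad_manifest = []
    cids = list(compounds["compound_id"])
    for k in range(plan.planted_bad_records):
        tweak = dict(_BAD_RECORD_CYCLE[k % len(_BAD_RECORD_CYCLE)])
        reason = tweak.pop("reason")
        row = {
            "compound_id": cids[k % len(cids)],
            "target_id": plan.target_id,
            "measurement_kind": plan.measurement_kind,
            "relation": "=",
            "value_nM": 100.0,
            "confidence_score": 9,
            "relationship_type": "D",
            "activity_comment": "",
        }
        row.update(tweak)
        rows.append(row)
        bad_manifest.append({"compound_id": row["compound_id"], "reason": reason})
    manifest["bad_records"] = bad_manifest
    activities = pd.DataFrame(rows)
    return compounds, activities, manifest


def default_plan(seed: int = 0, noise_sd: float = 0.0) -> FixturePlan:
    """Benzene/naphthalene analog grid: 10 compounds, 20 MMPs, 1 regular series."""
    return FixturePlan(
        seed=seed,
        cores=("[*]c1ccccc1", "[*]c1ccc2ccccc2c1"),
        core_effects=(0.0, 0.5),
        substituents=(HYDROGEN_FRAGMENT, "[*]C", "[*]CC", "[*]Cl", "[*]OC"),
        substituent_effects=(0.0, 0.6, 1.2, 2.4, 3.2),
        base_pki=5.5,
        noise_sd=noise_sd,
        pair_stems=((1, 2, 1),),  # methyl/ethyl share a one-carbon stem
    )


def amide_plan(seed: int = 0, noise_sd: float = 0.0) -> FixturePlan:
    """Indoline/tetrahydroquinoline N-acyl grid exercising retro (amide) cuts."""
    return FixturePlan(
        seed=seed,
        cores=("[*]N1CCc2ccccc21", "[*]N1CCCc2ccccc21"),
        core_effects=(0.0, 0.4),
        substituents=(HYDROGEN_FRAGMENT, "[*]C(C)=O", "[*]C(=O)CC", "[*]S(C)(=O)=O"),
        substituent_effects=(0.0, 1.1, 2.2, 3.0),
        base_pki=5.8,
        noise_sd=noise_sd,
        target_id="TGT-002",
        junction_retro=(False, True, True, True),
        pair_stems=((1, 2, 2),),  # acetyl/propionyl share the C=O stem
    )


def heteroaryl_plan(seed: int = 0, noise_sd: float = 0.0) -> FixturePlan:
    """Three-scaffold grid (benzene, pyridine, naphthalene), three matching series."""
    return FixturePlan(
        seed=seed,
        cores=("[*]c1ccccc1", "[*]c1ccncc1", "[*]c1ccc2ccccc2c1"),
        core_effects=(0.0, 0.3, 0.7),
        substituents=(HYDROGEN_FRAGMENT, "[*]C", "[*]Cl", "[*]OC"),
        substituent_effects=(0.0, 0.8, 2.1, 2.9),
        base_pki=6.0,
        noise_sd=noise_sd,
        target_id="TGT-003",
        measurement_kind="IC50",
    )


def curated_plans(seed: int = 0) -> list[FixturePlan]:
    """The noise-free plans whose oracle manifests are exact."""
    return [default_plan(seed), amide_plan(seed + 1), heteroaryl_plan(seed + 2)]


_SCAFFOLD_POOL = (
    "[*]c1ccccc1",
    "[*]c1ccc2ccccc2c1",
    "[*]c1ccncc1",
    "[*]c1ccc(F)cc1",
    "[*]C1CCCCC1",
    "[*]N1CCc2ccccc21",
    "[*]Nc1ccccc1",
    "[*]c1ccc(-c2ccccc2)cc1",
)

_SUBSTITUENT_POOL = (
    HYDROGEN_FRAGMENT,
    "[*]C",
    "[*]CC",
    "[*]CCC",
    "[*]C(C)C",
    "[*]Cl",
    "[*]F",
    "[*]Br",
    "[*]OC",
    "[*]OCC",
    "[*]N(C)C",
    "[*]C(F)(F)F",
    "[*]C(C)=O",
    "[*]C#N",
    "[*]O",
    "[*]S(C)(=O)=O",
)


def random_plan(seed: int, target_id: Optional[str] = None, measurement_kind: str = "Ki") -> FixturePlan:
    """A seeded, varied analog grid for stress-testing (<= 40 molecules).

    Draws scaffolds and substituents from curated pools and assigns
    random effects.  Combinations that would collide into the same
    structure are dropped deterministically, so the grid always
    satisfies the generator's uniqueness contract.  No oracle-manifest
    exactness is promised for these plans — they exist to exercise
    fragmentation and pairing on diverse chemistry.
    """
    rng = np.random.default_rng(seed)
    n_cores = int(rng.integers(2, 4))
    n_subs = int(rng.integers(4, 8))
    cores = tuple(str(c) for c in rng.choice(_SCAFFOLD_POOL, size=n_cores, replace=False))
    subs = [str(s) for s in rng.choice(_SUBSTITUENT_POOL, size=n_subs, replace=False)]
    # drop substituents that collide into an existing structure
    kept: list[str] = []
    seen: set[str] = set()
    for sub in subs:
        trial = []
        ok = True
        for core in cores:
            try:
                canon = standardize(reattach(core, sub)).canonical_smiles
            except Exception:
                ok = False
                break
            if canon in seen or canon in trial:
                ok = False
                break
            trial.append(canon)
        if ok:
            kept.append(sub)
            seen.update(trial)
    if len(kept) < 2:
        kept = [HYDROGEN_FRAGMENT, "[*]C"]  # degenerate draw; fall back to a minimal grid
    core_effects = tuple(float(x) for x in np.round(rng.uniform(0.0, 1.0, size=n_cores), 1))
    sub_effects = tuple(float(x) for x in np.round(rng.uniform(0.0, 3.5, size=len(kept)), 1))
    return FixturePlan(
        seed=seed,
        cores=cores,
        core_effects=core_effects,
        substituents=tuple(kept),
        substituent_effects=sub_effects,
        base_pki=float(np.round(rng.uniform(5.0, 6.5), 1)),
        target_id=target_id or f"TGT-R{seed:04d}",
        measurement_kind=measurement_kind,
    )
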