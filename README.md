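# mmptk — matched molecular pair analysis for curated activity data

`mmptk` turns a table of compound structures and bioactivity measurements
into matched molecular pairs (MMPs), activity cliffs, retrosynthetically
meaningful pairs, and SAR-transfer series, with the data curation steps
needed to make those comparisons trustworthy.

## Scientific problem

A matched molecular pair is a pair of compounds that differ only by a
single, well-defined structural change at one site — for example, a
chloro-for-methoxy swap on an otherwise identical scaffold. Because the
rest of the structure is held constant, the potency difference within an
MMP can be attributed to the exchanged substituents, which makes MMPs the
unit of analysis for several medicinal-chemistry questions:

* **Activity cliffs** — MMPs whose members differ greatly in potency
  (by default ≥ 2 orders of magnitude, with a relaxed 1-order variant)
  mark small structural changes with outsized effects and expose steep
  regions of the structure–activity landscape.
* **Retrosynthetic (RECAP-style) pairs** — restricting the cut bonds to a
  configurable table of retrosynthetic bond classes (amide, ester, amine,
  urea, ether, sulfonamide, …) yields pairs whose interconversion
  corresponds to plausible chemistry, at the cost of fewer pairs.
* **SAR transfer** — two scaffolds decorated with ≥ 3 of the same
  substituents, each series spanning ≥ 2 orders of magnitude, where the
  potency ordering carries over from one scaffold to the other either
  exactly (*regular* transfer) or approximately (Spearman rank
  correlation ≥ 0.7).

Comparisons like these are only meaningful on curated data, so the
pipeline first applies a strict high-confidence filter: exact (`=`)
measurements only, direct target assignments at the highest confidence
level, Ki and IC50 handled strictly separately, potencies converted to a
negative log scale (pKi/pIC50 = 9 − log10 nM), and replicates merged by
geometric mean only when they agree within one order of magnitude
(discarded otherwise).

## Method in brief

Each molecule is fragmented at every exocyclic single bond between heavy
atoms, producing (core, substituent) cuts; an additional *hydrogen
expansion* treats each distinct H position as a cut with a hydrogen
pseudo-substituent, so H→R exchanges are found too. Cuts from all
compounds of a target set are organised into a core-keyed fragment index:
two compounds sharing a core form a candidate pair, accepted if the
exchange is chemically small —

* the core has at least twice as many heavy atoms as each exchanged
  substituent,
* the substituents differ by at most 8 heavy atoms,
* no substituent exceeds 13 heavy atoms.

A pair may qualify under several cores; a deterministic rule keeps the
single chemically smallest transformation per pair (exhaustive listing is
available via `dedup=False`). The same pairing machinery, fed only with
rule-tagged retrosynthetic cuts, produces RECAP-MMPs. An independent
brute-force all-pairs comparison (`mmp.brute_force_pairs`) is shipped as
an audit oracle for the index.

See [docs/methods.md](docs/methods.md) for the full description, all
parameters and their defaults, and the design of the synthetic fixture
generator with its combinatorial ground-truth oracle.

## Worked example

Generate a small deterministic benchmark set (two aryl scaffolds × five
substituents with additive potency effects) and run the full pipeline:

```bash
mmptk fixtures --seed 7 --out fix
# wrote 10 compounds, 10 activity records to fix
mmptk run --in fix/compounds.tsv --activities fix/activities.tsv --out run
mmptk report --run-dir run
```

The report (abridged) shows the curation summary and per-measurement-kind
results:

```json
{
  "curation": {"records_in": 10, "records_kept": 10, "dropped": {}},
  "kinds": {
    "Ki": {
      "n_targets": 1,
      "n_compounds": 10,
      "mmps":   {"n_mmps": 20, "n_mmps_exhaustive": 22, "mmp_compounds_pct": 100.0},
      "cliffs": {
        "1": {"n_cliffs": 14, "pct_of_mmps": 70.0},
        "2": {"n_cliffs": 8,  "pct_of_mmps": 40.0}
      },
      "recap": {"n_recap_mmps": 0},
      "sar_transfer": {"matching_series": 1, "transfer_series": 1, "regular_series": 1}
    }
  }
}
```

Ten compounds yield 20 MMPs (every within-scaffold substituent swap), of
which 8 are ≥ 2-order cliffs and 14 qualify at the relaxed 1-order
threshold. No retrosynthetic bond class occurs in these simple aryl
compounds, so `n_recap_mmps` is 0. The two scaffolds share all five
substituents and each series spans 3.2 log units, giving one matching
series classified as a *regular* SAR transfer:

```text
run/Ki/TGT-001/sar_transfer.tsv
core_a             core_b      n_pairs  span_a  span_b  progression  rank_correlation
*c1ccc2ccccc2c1    *c1ccccc1   5        3.2     3.2     regular      1.0
```

and the 2-order cliffs table begins:

```text
run/Ki/TGT-001/cliffs_2oom.tsv
cpd_a          cpd_b          core       transformation  pPot_a  pPot_b  delta
TGT-001-00-00  TGT-001-00-03  *c1ccccc1  *Cl>>[*][H]     5.5     7.9     2.4
TGT-001-00-00  TGT-001-00-04  *c1ccccc1  *OC>>[*][H]     5.5     8.7     3.2
```

To analyse your own data, provide a compound table (`compound_id`,
`smiles`) and an activity table (`compound_id`, `target_id`,
`measurement_kind`, `relation`, `value_nM`, `confidence_score`,
`relationship_type`, `activity_comment`); column names are remappable via
a config file (see `pipeline.RunConfig.from_file`).

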