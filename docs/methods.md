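# Methods

This note describes what `mmptk` computes, the parameters it exposes with
their defaults and rationale, the design of the synthetic fixture
generator, and the deliberate interpretation choices made where the
underlying methodology admits more than one reading.

## 1. Data curation

Input activity records carry a compound id, target id, measurement kind
(`Ki` or `IC50`), a relation qualifier, a value in nM, a target-assignment
confidence score, a relationship type, and a free-text activity comment.
A record survives curation only if all of the following hold:

* measurement kind is `Ki` or `IC50` — the two are **never** mixed, and
  every downstream quantity is computed per (measurement kind, target);
* the activity comment does not flag the record as inactive or
  inconclusive;
* the relation qualifier is exactly `=` (no `>`, `<`, `~` bounds);
* the target-assignment confidence score is 9 (direct, highest-confidence
  single-protein assignment);
* the relationship type is `D` (direct interaction);
* the value is positive and finite.

Surviving values convert to a negative log scale, `pPotency = 9 −
log10(value in nM)`, so 1 nM ↦ 9.0 and 1 µM ↦ 6.0. Structural duplicates
(records whose structures standardize to the same canonical SMILES) are
merged under the lexicographically smallest compound id before
aggregation. Replicates for one compound are merged by geometric mean of
the nM values **only** when max/min ≤ 10 (agreement within one order of
magnitude, bound inclusive up to a 1e−12 relative slack so that exactly
10× replicates are kept); otherwise the compound is discarded from that
target set. Every drop is counted by reason and surfaced in the run
report.

Structure standardization keeps the largest organic component of
multi-component inputs (salt stripping; carbon-containing fragments are
preferred, ties broken by heavy-atom count then canonical SMILES),
neutralizes chargeable groups where a neutral form exists, and emits the
RDKit canonical SMILES. Quaternary centres keep their charge.

## 2. Fragmentation and the fragment index

Every exocyclic single bond between two heavy atoms is cut in both
orientations, giving (core, substituent) pairs where each part carries
one attachment point (`*`). In addition, *hydrogen expansion* emits one
cut per symmetry-distinct hydrogen position: the core is the whole
molecule with an attachment point at that position and the substituent is
the hydrogen pseudo-fragment `[*][H]` (zero heavy atoms). This makes H→R
exchanges first-class MMPs. Symmetry-equivalent positions collapse
because cores are deduplicated by canonical SMILES. Implementation note:
the hydrogen is swapped for the attachment atom by element replacement on
the hydrogen-explicit graph, which preserves stereocentre parity — every
cut is required to reassemble to the exact parent structure, stereo
included.

Cuts from all compounds of one target set are organised into a fragment
index keyed by canonical core SMILES. Two compounds listed under the same
core with different substituents form a candidate pair, accepted iff the
exchange passes the **size restrictions** (all bounds inclusive):

| rule | default | rationale |
|---|---|---|
| core ≥ `core_multiple` × each substituent | 2 | the constant part must dominate the variable part |
| \|size(frag_a) − size(frag_b)\| ≤ `max_diff` | 8 heavy atoms | forbid grossly asymmetric exchanges |
| max substituent size ≤ `max_frag` | 13 heavy atoms | keep the exchange a "substituent", not half the molecule |

Sizes are heavy-atom counts; the attachment point and the hydrogen
pseudo-fragment count zero.

**Pair-level deduplication.** A compound pair may qualify under several
cores (e.g. both the phenyl core and a larger core containing it). By
default each pair is reported once with its canonical transformation,
chosen as the candidate minimising (largest substituent size, total
substituent size, core SMILES lexicographically) — i.e. the chemically
smallest description of the difference. The exhaustive per-core listing
is available (`assemble_mmps(..., dedup=False)`), and the run report
carries both counts (`n_mmps`, `n_mmps_exhaustive`).

**Audit oracle.** `mmp.brute_force_pairs` recomputes all pairs by
intersecting the cut sets of every compound pair directly, without the
index. The acceptance tests require exact agreement between the two
routes on twenty seeded fixture grids.

## 3. Activity cliffs

Within a target set, an MMP is a cliff at threshold *t* when the absolute
pPotency difference of its members is ≥ *t*. Defaults: *t* = 2.0 (two
orders of magnitude) plus the relaxed *t* = 1.0 variant; both tables are
written per run and 2-order cliffs are by construction a subset of
1-order cliffs. All potency comparisons (cliff thresholds, series spans)
use an absolute tolerance `POTENCY_TOL = 1e-9` so that round-trips
through the nM representation cannot flip a boundary case.

## 4. Retrosynthetic (RECAP-style) MMPs

Second-generation pairs restrict cleavable bonds to retrosynthetic bond
classes. Rules live in a plain-text, user-overridable table
(`src/mmptk/data/recap_rules.tsv`, or `--rules` on the CLI): one SMARTS
per class with exactly two mapped atoms (`:1`, `:2`) naming the cleavable
bond, an enabled flag, and a bond order. The shipped table covers the
classic retrosynthetic classes — amide, ester, amine, urea, ether,
olefin (disabled by default, double bond), quaternary nitrogen, aromatic
N–aliphatic C, lactam N–aliphatic C, aromatic C–aromatic C, sulfonamide —
plus two disabled extension slots (carbamate, thioether). The exact
membership of a retrosynthetic rule set is a convention, not a fact of
chemistry; shipping it as an editable table makes the convention
explicit and replaceable. Ring bonds never qualify; hydrogen expansion is
not applied in retro mode (a retro cut must correspond to a
reaction-formed bond). Each retro cut records the rule ids that tagged
its bond, and the pairing, size rules and cliff detection are identical
to the standard scheme, so RECAP-MMP counts can only be ≤ standard
counts on the same data.

## 5. SAR transfer

For each target set, a *substituent series* is the set of compounds
sharing a core, keyed by their substituent, with per-cut size rules
applied (core ≥ 2 × substituent, substituent ≤ 13 heavy atoms). Two
series over different cores **match** when they share at least
`min_pairs` (default 3) substituents and the potencies of the matched
compounds span at least `min_span` (default 2.0) log units *in each
series*. A matching series pair is a **transfer** series when the potency
ordering carries over:

* *regular* — the rank orderings of the matched compounds are identical
  and tie-free (ties detected within `POTENCY_TOL`); rank correlation is
  reported as exactly 1.0;
* *approximate* — otherwise, when the Spearman rank correlation over the
  matched pairs is ≥ `approx_threshold` (default 0.7).

Interpretation choices made explicit: the span requirement is evaluated
over the *matched* compounds only (unmatched members of a series say
nothing about transferability); regularity demands strict tie-free rank
identity rather than ρ = 1 (a tied pair can produce ρ = 1 without a
well-defined ordering); and the approximate class is operationalised as
a Spearman cut-off with the threshold exposed as a parameter. Regular ⊆
transfer ⊆ matching holds by construction and is asserted in the tests.

## 6. Synthetic fixtures and the combinatorial oracle

The generator (`mmptk.fixtures`) builds compound grids from a plan:
scaffolds × substituents, each combination assembled chemically
(attachment-point joining followed by full standardization) and assigned
`pPotency = base + core_effect + substituent_effect (+ noise)`. Noise-free
plans are additive by construction, so rank orderings transfer exactly
between scaffolds. Plans can plant malformed activity records (qualified
relations, low confidence, wrong relationship type, inactive comments)
that curation must drop.

Alongside the tables, `oracle_manifest` computes the expected results
*combinatorially* — by counting, not by running the pipeline: within-core
pairs from the grid structure, cliff pairs from the effect arithmetic,
retro pairs from declared junction bond classes, and matching/transfer/
regular series from the shared substituent sets and the additive model.
The curated plans are designed so this count is **exact**, not a lower
bound: scaffolds have ≥ 6 heavy atoms and substituents ≤ 4, so the
size-restriction arithmetic provably excludes any decomposition other
than the planted grid decompositions; scaffold-internal bonds are all
ring bonds (no stray acyclic cuts inside the constant part); and where
two substituents share a rooted stem (e.g. acetyl/propionyl share the
2-heavy-atom C=O stem), the plan declares the stem so the oracle accounts
for the enlarged-core description of those pairs. Derived cross-scaffold
series are kept below the 3-member matching threshold. The acceptance
tests require pipeline counts to equal the oracle manifests exactly on
all curated plans.

Random plans draw scaffolds and substituents from fixed pools with
deterministic collision handling (≤ 40 molecules); they are used for the
index-vs-brute-force and invariant (nesting, reassembly, size-rule)
checks, where correctness does not depend on knowing the expected counts.

## 7. Determinism

Given the same inputs, configuration and seed, a run writes byte-identical
output directories: all tables are sorted with fixed key orders and
written with `\n` line endings, JSON is emitted with sorted keys, and all
randomness flows from a single seed through derived generators.

## 8. Limitations

* Only single-cut MMPs are generated; multi-attachment (two- and
  three-cut) cores are out of scope.
* Curation expects activities already reduced to a flat table with nM
  values; assay-level reconciliation beyond the replicate rule is the
  caller's responsibility.
* The retrosynthetic rule table is a pragmatic reconstruction of the
  classic bond classes; users with a house convention should supply
  their own table.
* Potency effects in fixtures are additive by design; real SAR data
  contain interaction terms the generator does not attempt to model.
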