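"""Retrosynthetic (RECAP-style) bond typing and fragmentation.

Standard MMP fragmentation cuts every exocyclic single bond, so the
resulting transformation need not correspond to any chemical reaction.
Restricting the cleavable bonds to a rule set of retrosynthetically
meaningful bond classes (amide, ester, amine, urea, ether, ...) yields
second-generation "RECAP-MMPs" whose transformations are more likely
to be synthetically accessible.

Rules are SMARTS patterns with exactly two mapped atoms (:1 and :2)
defining the cleavable bond; they ship in an editable plain-text table
and can be overridden per run.  Hydrogen expansion is not applied in
retro mode: a retrosynthetic cut requires a reaction-derived bond.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from rdkit import Chem

from mmptk.fragmentation import Cut, cuts_for_bonds
from mmptk.structures import Molecule


class RuleConfigError(ValueError):
    """Raised for malformed rule files or SMARTS at load time."""


@dataclass(frozen=True)
class RetroRule:
    """One retrosynthetic bond class."""

    rule_id: str
    smarts: str
    enabled: bool = True
    bond_order: int = 1  # 2 only for olefin-type rules

    def query(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise RuleConfigError(f"rule {self.rule_id!r}: invalid SMARTS {self.smarts!r}")
        return patt


def _mapped_query_indices(patt: Chem.Mol, rule_id: str) -> tuple[int, int]:
    mapped = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()}
    if set(mapped) != {1, 2}:
        raise RuleConfigError(
            f"rule {rule_id!r}: SMARTS must map exactly two atoms :1 and :2"
        )
    return mapped[1], mapped[2]


def load_rules(path) -> list[RetroRule]:
    """Load a rule table: rule_id <tab> SMARTS <tab> enabled [<tab> bond_order].

    All rules (enabled or not) are validated at load time; a malformed
    SMARTS or missing atom maps raise :class:`RuleConfigError`.
    """
    rules: list[RetroRule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RuleConfigError(f"line {lineno}: expected rule_id<TAB>SMARTS<TAB>enabled")
            rule_id, smarts, enabled = parts[0].strip(), parts[1].strip(), parts[2].strip().lower()
            if enabled not in ("true", "false"):
                raise RuleConfigError(f"line {lineno}: enabled must be true/false, got {enabled!r}")
            bond_order = int(parts[3]) if len(parts) > 3 and parts[3].strip() else 1
            rule = RetroRule(rule_id=rule_id, smarts=smarts, enabled=enabled == "true", bond_order=bond_order)
            _mapped_query_indices(rule.query(), rule_id)  # validate eagerly
            rules.append(rule)
    if not rules:
        raise RuleConfigError(f"no rules found in {path}")
    return rules


def default_rules() -> list[RetroRule]:
    """The bundled retrosynthetic bond classes (olefin cleavage shipped disabled)."""
    with resources.as_file(resources.files("mmptk").joinpath("data/recap_rules.tsv")) as p:
        return load_rules(p)


def identify_retro_bonds(
    mol: Molecule, rules: Sequence[RetroRule]
) -> list[tuple[int, tuple[str, ...], int]]:
    """Find acyclic bonds matching enabled retrosynthetic rules.

    Returns (bond index, matching rule_ids, bond order) triples, one
    per bond — a bond matching several rules is reported once with all
    rule ids.  Ring bonds never qualify.
    """
    enabled = [r for r in rules if r.enabled]
    if not enabled:
        raise RuleConfigError("no enabled rules")
    rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
    hits: dict[int, set[str]] = {}
    orders: dict[int, int] = {}
    for rule in enabled:
        patt = rule.query()
        qi, qj = _mapped_query_indices(patt, rule.rule_id)
        for match in rdmol.GetSubstructMatches(patt, uniquify=False):
            bond = rdmol.GetBondBetweenAtoms(match[qi], match[qj])
            if bond is None or bond.IsInRing():
                continue
            expected = Chem.BondType.DOUBLE if rule.bond_order == 2 else Chem.BondType.SINGLE
            if bond.GetBondType() != expected:
                continue
            hits.setdefault(bond.GetIdx(), set()).add(rule.rule_id)
            orders[bond.GetIdx()] = max(orders.get(bond.GetIdx(), 1), rule.bond_order)
    return [(b, tuple(sorted(hits[b])), orders[b]) for b in sorted(hits)]


def enumerate_retro_cuts(mol: Molecule, rules: Sequence[RetroRule]) -> list[Cut]:
    """Single cuts restricted to retrosynthetic-rule bonds.

    Same contract as standard fragmentation (both orientations, atom
    conservation, reassembly) but each cut carries the rule ids that
    tagged its bond.  No hydrogen expansion.
    """
    tagged = identify_retro_bonds(mol, rules)
    cuts: list[Cut] = []
    for bond_idx, rule_ids, order in tagged:
        cuts.extend(
            cuts_for_bonds(mol, [bond_idx], rule_ids_by_bond={bond_idx: rule_ids}, bond_order=order)
        )
    return cuts
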