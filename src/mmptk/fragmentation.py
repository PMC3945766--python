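"""Single-cut fragmentation and the core-keyed fragment index.

A matched molecular pair differs by a structural change at a single
site, so candidate pairs are found by cutting every exocyclic single
bond between heavy atoms, once per orientation (each side serves once
as the exchangeable fragment).  Hydrogen-position expansion adds cuts
whose fragment is a hydrogen pseudo-fragment, which makes H -> group
substitutions (e.g. adding a substituted ring) reachable.

Indexing cuts by canonical core SMILES (the Hussain-Rea scheme) turns
pair detection into a per-key scan instead of an all-pairs comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem

from mmptk.curation import TargetSet
from mmptk.structures import HYDROGEN_FRAGMENT, Molecule, heavy_atoms


@dataclass(frozen=True)
class Cut:
    """One (core, fragment) decomposition of a parent molecule.

    The core and fragment each carry a single wildcard attachment atom
    (the fragment may be the hydrogen pseudo-fragment).  Heavy-atom
    counts exclude the wildcard, so core_heavy + fragment_heavy always
    equals the parent's heavy-atom count.
    """

    compound_id: str
    core_smiles: str
    fragment_smiles: str
    core_heavy: int
    fragment_heavy: int
    rule_ids: tuple[str, ...] = ()  # retrosynthetic rules tagging the cut bond, if any
    bond_order: int = 1


@dataclass
class FragmentIndex:
    """Map canonical core SMILES -> sorted (compound_id, fragment) entries."""

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def _cleavable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of acyclic single bonds between two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _split_on_bond(mol: Chem.Mol, bond_idx: int) -> tuple[str, str]:
    """Break one bond, returning the two canonical fragment SMILES."""
    fragged = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(fragged, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - guarded by acyclic-bond check
        raise RuntimeError("cut did not split the molecule into two pieces")
    a, b = (Chem.MolToSmiles(p) for p in pieces)
    return a, b


def cuts_for_bonds(
    mol: Molecule,
    bond_indices: Iterable[int],
    rule_ids_by_bond: Optional[Mapping[int, Sequence[str]]] = None,
    bond_order: int = 1,
) -> list[Cut]:
    """Cuts for explicit bond indices, both orientations per bond."""
    rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
    cuts: list[Cut] = []
    for bidx in bond_indices:
        a, b = _split_on_bond(rdmol, bidx)
        rules = tuple(sorted(rule_ids_by_bond.get(bidx, ()))) if rule_ids_by_bond else ()
        for core, frag in ((a, b), (b, a)):
            cuts.append(
                Cut(
                    compound_id=mol.compound_id,
                    core_smiles=core,
                    fragment_smiles=frag,
                    core_heavy=heavy_atoms(core),
                    fragment_heavy=heavy_atoms(frag),
                    rule_ids=rules,
                    bond_order=bond_order,
                )
            )
    return cuts


def enumerate_single_cuts(mol: Molecule) -> list[Cut]:
    """All single cuts of a molecule's exocyclic single bonds.

    Each cleavable bond contributes two cuts (each side once as the
    fragment).  Ring-internal bonds, bonds to hydrogen, and multiple
    bonds are never cut.  Molecules with no cleavable bond (e.g. plain
    rings, single atoms) return an empty list.
    """
    rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
    return cuts_for_bonds(mol, _cleavable_bonds(rdmol))


def hydrogen_expansion(mol: Molecule) -> list[Cut]:
    """Cuts exchanging a hydrogen at each symmetry-distinct position.

    For every hydrogen-bearing heavy atom, the core is the whole
    molecule with an attachment atom at that position and the fragment
    is the hydrogen pseudo-fragment.  Symmetry-equivalent positions
    collapse to one cut because cores are deduplicated by canonical
    SMILES.
    """
    # work on the hydrogen-explicit graph and swap one H per site for an
    # attachment atom: an element swap never reorders neighbours, so
    # stereocentre parity is preserved
    rdmol_h = Chem.AddHs(Chem.MolFromSmiles(mol.canonical_smiles))
    seen: set[str] = set()
    cuts: list[Cut] = []
    for atom in rdmol_h.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        h_idx = next(
            (n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1), None
        )
        if h_idx is None:
            continue
        rw = Chem.RWMol(rdmol_h)
        rw.GetAtomWithIdx(h_idx).SetAtomicNum(0)
        core_mol = Chem.RemoveHs(rw.GetMol())
        Chem.SanitizeMol(core_mol)
        core = Chem.MolToSmiles(core_mol)
        if core in seen:
            continue
        seen.add(core)
        cuts.append(
            Cut(
                compound_id=mol.compound_id,
                core_smiles=core,
                fragment_smiles=HYDROGEN_FRAGMENT,
                core_heavy=mol.heavy_atom_count,
                fragment_heavy=0,
            )
        )
    return cuts


def all_cuts(mol: Molecule, hydrogen: bool = True) -> list[Cut]:
    """Standard single cuts plus (by default) hydrogen expansion."""
    cuts = enumerate_single_cuts(mol)
    if hydrogen:
        cuts.extend(hydrogen_expansion(mol))
    return cuts


def build_index(
    target_set: TargetSet,
    cuts_by_compound: Mapping[str, Sequence[Cut]],
) -> FragmentIndex:
    """Build the core-keyed fragment index over a target set.

    Entry lists are deduplicated at the (compound, core, fragment)
    level and sorted by (compound_id, fragment) for determinism.
    """
    raw: dict[str, set[tuple[str, str]]] = {}
    for cid in target_set.members:
        for cut in cuts_by_compound.get(cid, ()):
            raw.setdefault(cut.core_smiles, set()).add((cid, cut.fragment_smiles))
    return FragmentIndex(
        entries={core: sorted(raw[core]) for core in sorted(raw)}
    )


def reattach(core_smiles: str, fragment_smiles: str, bond_order: int = 1) -> str:
    """Rejoin a core and fragment at their attachment atoms.

    Returns the canonical SMILES of the reassembled parent.  The
    hydrogen pseudo-fragment simply removes the core's attachment atom
    (its valence is refilled by an implicit hydrogen).
    """
    if fragment_smiles == HYDROGEN_FRAGMENT:
        # turn the attachment atom back into a hydrogen: the element swap
        # preserves neighbour order, hence stereocentre parity
        rw = Chem.RWMol(Chem.MolFromSmiles(core_smiles))
        for atom in rw.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomicNum(1)
                break
        mol = Chem.RemoveHs(rw.GetMol())
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    core = Chem.MolFromSmiles(core_smiles)
    frag = Chem.MolFromSmiles(fragment_smiles)
    if core is None or frag is None:
        raise ValueError("unparsable core or fragment SMILES")
    rw = Chem.RWMol(Chem.CombineMols(core, frag))
    dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 2:
        raise ValueError("core and fragment must carry exactly one attachment atom each")
    neighbors = [rw.GetAtomWithIdx(d).GetNeighbors()[0].GetIdx() for d in dummies]
    order = Chem.BondType.DOUBLE if bond_order == 2 else Chem.BondType.SINGLE
    rw.AddBond(neighbors[0], neighbors[1], order)
    for d in sorted(dummies, reverse=True):
        rw.RemoveAtom(d)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
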