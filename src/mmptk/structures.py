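"""Structure ingestion and standardization.

Every molecule entering the pipeline is standardized once: the largest
organic covalent component is retained (salts and solvents stripped),
charges are neutralized where a proton can be added or removed without
violating standard valence, and a canonical SMILES is computed.  All
size restrictions downstream are expressed in heavy (non-hydrogen) atom
counts, so the standardized record carries that count too.

Stereochemistry is preserved as given; tautomers are not canonicalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Sentinel SMILES for the hydrogen pseudo-fragment used by
#: hydrogen-position expansion (zero heavy atoms by definition).
HYDROGEN_FRAGMENT = "[*][H]"

_UNCHARGER = rdMolStandardize.Uncharger()


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""


@dataclass(frozen=True)
class Molecule:
    """A standardized structure.

    Attributes
    ----------
    compound_id : str
        Opaque identifier carried through from the input table.
    input_smiles : str
        SMILES string as read.
    canonical_smiles : str
        Canonical SMILES after salt stripping and neutralization;
        always a single covalently connected component.
    heavy_atom_count : int
        Number of non-hydrogen atoms.
    """

    compound_id: str
    input_smiles: str
    canonical_smiles: str
    heavy_atom_count: int


def _largest_organic_component(mol: Chem.Mol) -> Chem.Mol:
    """Pick the largest covalent component, preferring carbon-containing ones.

    Ties on heavy-atom count are broken by lexicographically smallest
    canonical SMILES so output is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic if organic else list(frags)
    return min(pool, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def standardize(raw_smiles: str, compound_id: str = "") -> Molecule:
    """Standardize a raw SMILES into a :class:`Molecule`.

    Keeps the largest organic component, neutralizes protonation-state
    charges, and canonicalizes.  Raises :class:`StandardizationError`
    for unparsable input; callers in the pipeline log and skip such
    records rather than aborting.
    """
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {raw_smiles!r}")
    mol = _largest_organic_component(mol)
    mol = _UNCHARGER.uncharge(mol)
    canonical = Chem.MolToSmiles(mol)
    if "." in canonical:  # should be unreachable after component selection
        raise StandardizationError(f"disconnected after standardization: {canonical!r}")
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 1:
        raise StandardizationError(f"no heavy atoms in {raw_smiles!r}")
    return Molecule(
        compound_id=compound_id,
        input_smiles=raw_smiles,
        canonical_smiles=canonical,
        heavy_atom_count=n_heavy,
    )


def heavy_atoms(fragment_smiles: str) -> int:
    """Count heavy atoms in a fragment SMILES carrying one attachment point.

    The wildcard attachment atom ``*`` is never counted.  The hydrogen
    pseudo-fragment counts as zero.  More than one attachment atom
    violates the single-cut contract and raises ``ValueError``.
    """
    if fragment_smiles == HYDROGEN_FRAGMENT:
        return 0
    mol = Chem.MolFromSmiles(fragment_smiles)
    if mol is None:
        raise ValueError(f"unparsable fragment SMILES: {fragment_smiles!r}")
    n_wild = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    if n_wild > 1:
        raise ValueError(
            f"fragment has {n_wild} attachment points (single-cut contract): {fragment_smiles!r}"
        )
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def canonical_smiles(smiles: str) -> str:
    """Canonical form of a SMILES (fragments with wildcards included)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def read_smiles_file(path) -> list[Molecule]:
    """Read a .smi-style file: one record per line, SMILES whitespace identifier.

    Unparsable records are logged and skipped.
    """
    out: list[Molecule] = []
    n_bad = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{i}"
            try:
                out.append(standardize(smi, compound_id=cid))
            except StandardizationError as exc:
                n_bad += 1
                logger.warning("skipping record %s: %s", cid, exc)
    if n_bad:
        logger.info("skipped %d unparsable records", n_bad)
    return out
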