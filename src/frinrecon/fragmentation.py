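"""RECAP tree-leaf fragmentation of ligands with parent-atom mapping.

Ligands are decomposed with the RECAP retrosynthetic rules (rdkit
implementation, tree-leaves mode: terminal fragments only, no recombined
internal nodes).  Each leaf is canonicalised after capping its open valences
and mapped back onto the parent molecule so that per-atom interaction records
can later be assigned to the fragment that mediates them.

Atom identifiers are plain strings.  For molecules parsed from SMILES they
are the rdkit atom indices of the ligand's *stored canonical* SMILES
rendered as strings ("0", "1", ...), so interaction records must index
atoms in that same order; abstract (pre-fragmented) corpora may use any
opaque scheme as long as records and atom maps share it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Recap

RDLogger.DisableLog("rdApp.*")

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class FragmentationStatus(str, Enum):
    FRAGMENTED = "fragmented"
    NON_FRAGMENTABLE = "non_fragmentable"
    MAPPING_FAILED = "mapping_failed"


class InputError(ValueError):
    """Raised for malformed user input (unparsable SMILES, bad tables)."""


def is_inchikey(key: str) -> bool:
    """True if *key* has the standard 14-10-1 uppercase InChIKey layout."""
    return bool(_INCHIKEY_RE.match(key))


@dataclass(frozen=True)
class Ligand:
    """A compound keyed by an opaque identifier (HET code, external ID...)."""

    compound_id: str
    smiles: str
    inchikey: str
    mw: float

    def __post_init__(self) -> None:
        if not is_inchikey(self.inchikey):
            raise ValueError(f"invalid InChIKey {self.inchikey!r} for {self.compound_id}")
        if not self.mw > 0:
            raise ValueError(f"non-positive MW for {self.compound_id}")


@dataclass(frozen=True)
class Fragment:
    """One RECAP leaf occurrence inside a parent ligand.

    ``parent_atom_map`` lists the parent-ligand atom identifiers covered by
    this occurrence; a leaf appearing k times in one compound is stored as k
    Fragment instances sharing ``frag_inchikey`` but with disjoint maps.
    """

    frag_smiles: str
    frag_inchikey: str
    mw: float
    parent_atom_map: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parent_atom_map) == 0:
            raise ValueError("empty parent_atom_map")
        if len(set(self.parent_atom_map)) != len(self.parent_atom_map):
            raise ValueError("duplicate atoms in parent_atom_map")
        if not self.mw > 0:
            raise ValueError("non-positive fragment MW")


@dataclass(frozen=True)
class FragmentationOutcome:
    ligand: Ligand
    fragments: tuple[Fragment, ...]
    status: FragmentationStatus

    @property
    def distinct_inchikeys(self) -> tuple[str, ...]:
        """Distinct leaf identities, in first-occurrence order.

        This is the multiplicity unit for "fragment is part of compound"
        statistics and for the compound-proportion denominator.
        """
        seen: dict[str, None] = {}
        for f in self.fragments:
            seen.setdefault(f.frag_inchikey, None)
        return tuple(seen)


def compute_identity(smiles: str, compound_id: str | None = None) -> tuple[str, str, float]:
    """Canonical SMILES, standard InChIKey and molecular weight for *smiles*.

    Deterministic across runs; raises :class:`InputError` (naming
    *compound_id* when given) if the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for compound {compound_id!r}" if compound_id else ""
        raise InputError(f"unparsable SMILES {smiles!r}{who}")
    return Chem.MolToSmiles(mol), Chem.MolToInchiKey(mol), Descriptors.MolWt(mol)


def ligand_from_smiles(compound_id: str, smiles: str) -> Ligand:
    canonical, inchikey, mw = compute_identity(smiles, compound_id)
    return Ligand(compound_id=compound_id, smiles=canonical, inchikey=inchikey, mw=mw)


def _cap_dummies(mol: Chem.Mol) -> Chem.Mol:
    """Replace RECAP attachment points ([*]) with hydrogens and strip them.

    Fragment identity (canonical SMILES, InChIKey, MW) must not depend on
    cleavage context, so the open valences are H-capped before
    canonicalisation.
    """
    editable = Chem.RWMol(mol)
    for atom in editable.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
    capped = Chem.RemoveHs(editable.GetMol())
    Chem.SanitizeMol(capped)
    return capped


def map_fragment_atoms(
    parent: Chem.Mol,
    fragment: Chem.Mol,
    claimed: set[int] | None = None,
) -> tuple[str, ...] | None:
    """Map a capped fragment onto the parent molecule.

    The query is the H-capped fragment (attachment points removed): RECAP
    writes single bonds to its dummy atoms even where the parent bond was
    double, so the dummy form does not embed in the parent; the capped core
    does, with hydrogen counts and stereochemistry ignored during matching.

    Returns the matched parent atom indices as strings, or None when no
    chemically consistent substructure match exists (the occurrence is then
    dropped, mirroring the loss of fragments whose capped form no longer
    embeds in the parent).

    Ambiguous matches are resolved deterministically: prefer the match with
    the largest overlap with atoms not yet *claimed* by other fragments, then
    the lexicographically smallest parent index tuple.
    """
    matches = parent.GetSubstructMatches(fragment, uniquify=True, maxMatches=2048)
    if not matches:
        return None
    claimed = claimed or set()
    candidates = sorted({tuple(sorted(m)) for m in matches})
    best = min(candidates, key=lambda atoms: (len(set(atoms) & claimed), atoms))
    return tuple(str(i) for i in best)


def fragment_compound(ligand: Ligand) -> FragmentationOutcome:
    """Decompose *ligand* into RECAP tree leaves mapped onto the parent.

    Leaves whose capped structure cannot be matched back onto the parent are
    excluded; if every leaf fails, the outcome carries status
    ``mapping_failed``.  A compound with no applicable RECAP cleavage rule is
    ``non_fragmentable`` (kept out of fragment-level analysis but retained in
    evaluation subsets).
    """
    parent = Chem.MolFromSmiles(ligand.smiles)
    if parent is None:
        raise InputError(f"unparsable SMILES for compound {ligand.compound_id!r}")
    tree = Recap.RecapDecompose(parent)
    leaves = sorted(tree.GetLeaves())
    if not leaves:
        return FragmentationOutcome(ligand, (), FragmentationStatus.NON_FRAGMENTABLE)

    fragments: list[Fragment] = []
    claimed: set[int] = set()
    any_leaf = False
    for leaf_smiles in leaves:
        leaf = Chem.MolFromSmiles(leaf_smiles)
        if leaf is None:  # pragma: no cover - rdkit leaves always reparse
            continue
        any_leaf = True
        capped = _cap_dummies(leaf)
        canonical = Chem.MolToSmiles(capped)
        inchikey = Chem.MolToInchiKey(capped)
        mw = Descriptors.MolWt(capped)
        # one occurrence per substructure embedding, greedily claiming atoms
        n_occurrences = _count_occurrences(parent, capped)
        for _ in range(n_occurrences):
            atom_map = map_fragment_atoms(parent, capped, claimed)
            if atom_map is None:
                break
            atoms = {int(a) for a in atom_map}
            if atoms <= claimed:
                break
            claimed |= atoms
            fragments.append(
                Fragment(
                    frag_smiles=canonical,
                    frag_inchikey=inchikey,
                    mw=mw,
                    parent_atom_map=atom_map,
                )
            )
    if not fragments:
        status = (
            FragmentationStatus.MAPPING_FAILED if any_leaf else FragmentationStatus.NON_FRAGMENTABLE
        )
        return FragmentationOutcome(ligand, (), status)
    return FragmentationOutcome(ligand, tuple(fragments), FragmentationStatus.FRAGMENTED)


def _count_occurrences(parent: Chem.Mol, fragment: Chem.Mol) -> int:
    """Upper bound on distinct embeddings of the capped fragment in *parent*."""
    matches = parent.GetSubstructMatches(fragment, uniquify=True, maxMatches=2048)
    return max(1, len({tuple(sorted(m)) for m in matches}))


def fragment_many(ligands: Iterable[Ligand]) -> list[FragmentationOutcome]:
    return [fragment_compound(lig) for lig in ligands]
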