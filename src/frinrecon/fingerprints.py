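"""500-bin interaction fingerprints for protein-ligand complexes.

Each non-covalent contact reported by an interaction profiler (PLIP-style) is
reduced to a feature triple — interaction type, interacting ligand functional
group, interacting target residue identity — and hashed into one of 500 bins.
A complex (or a fragment within a complex) is then a binary fingerprint over
those bins; all geometric detail (distances, angles, residue numbering) is
deliberately discarded.

The bin assignment is a pinned, platform-stable function (``HASH_ALGORITHM``)
so fingerprints are reproducible across releases; golden test vectors are
frozen in the test suite.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_BINS = 500
HASH_ALGORITHM = "crc32-mod500"

# 3-letter <-> 1-letter amino-acid codes; residue *identity* (not position)
# enters the hash.
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3LETTER = frozenset(AA_1TO3.values())
# non-protein partners that PLIP can report on the receptor side
EXTRA_RESIDUES = frozenset({"HOH", "MET_ION", "UNK"})


class InteractionType(str, Enum):
    HYDROGEN_BOND = "hydrogen_bond"
    HYDROPHOBIC = "hydrophobic"
    PI_STACK = "pi_stack"
    PI_CATION = "pi_cation"
    SALT_BRIDGE = "salt_bridge"
    WATER_BRIDGE = "water_bridge"
    HALOGEN_BOND = "halogen_bond"
    METAL_COMPLEX = "metal_complex"


def normalize_residue(residue: str) -> str:
    """Canonical 3-letter upper-case residue code.

    Accepts 1- or 3-letter codes; water and metal pseudo-residues pass
    through.  Raises ValueError for anything else.
    """
    res = residue.strip().upper()
    if len(res) == 1:
        if res not in AA_1TO3:
            raise ValueError(f"unknown 1-letter residue code {residue!r}")
        return AA_1TO3[res]
    if res in AA_3LETTER or res in EXTRA_RESIDUES:
        return res
    raise ValueError(f"unknown residue code {residue!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One non-covalent contact in one complex.

    ``complex_uid`` follows the PDB:HETID:CHAIN:POS convention; ``ligand_atoms``
    are parent-ligand atom identifiers in the same space the fragmentation
    stage uses.
    """

    complex_uid: str
    interaction_type: InteractionType
    ligand_atoms: tuple[str, ...]
    functional_group: str
    residue: str
    target_uniprot: str

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError(f"record in {self.complex_uid} has no ligand atoms")
        object.__setattr__(self, "residue", normalize_residue(self.residue))
        object.__setattr__(
            self, "functional_group", self.functional_group.strip().casefold()
        )


@dataclass(frozen=True)
class ComplexProfile:
    """All interaction records of one ligand instance in one structure."""

    complex_uid: str
    target_uniprot: str
    compound_inchikey: str
    records: tuple[InteractionRecord, ...]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.complex_uid != self.complex_uid:
                raise ValueError(
                    f"record uid {rec.complex_uid} != profile uid {self.complex_uid}"
                )


class BinaryFingerprint:
    """Fixed-length 500-bin indicator vector (bins indexed 1..500)."""

    __slots__ = ("bins",)

    def __init__(self, bins: Iterable[int] = ()):
        bins = frozenset(int(b) for b in bins)
        for b in bins:
            if not 1 <= b <= N_BINS:
                raise ValueError(f"bin {b} outside [1, {N_BINS}]")
        self.bins: frozenset[int] = bins

    @property
    def popcount(self) -> int:
        return len(self.bins)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(N_BINS, dtype=bool)
        if self.bins:
            arr[np.fromiter(self.bins, dtype=int) - 1] = True
        return arr

    def to_string(self) -> str:
        """500-character 0/1 serialisation (bin 1 first)."""
        return "".join("1" if b + 1 in self.bins else "0" for b in range(N_BINS))

    @classmethod
    def from_string(cls, s: str) -> "BinaryFingerprint":
        if len(s) != N_BINS or set(s) - {"0", "1"}:
            raise ValueError("fingerprint string must be 500 characters of 0/1")
        return cls(i + 1 for i, c in enumerate(s) if c == "1")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryFingerprint) and self.bins == other.bins

    def __hash__(self) -> int:
        return hash(self.bins)

    def __or__(self, other: "BinaryFingerprint") -> "BinaryFingerprint":
        return BinaryFingerprint(self.bins | other.bins)

    def __repr__(self) -> str:
        return f"BinaryFingerprint({sorted(self.bins)!r})"


def hash_feature(
    interaction_type: InteractionType | str, functional_group: str, residue: str
) -> int:
    """Bin index in [1, 500] for a feature triple.

    The triple is normalised (enum value, case-folded group, 3-letter
    residue), joined with '|' and hashed with CRC-32; distinct triples may
    collide by construction (500-bin pigeonhole) but identical triples always
    agree, on every platform.
    """
    itype = InteractionType(interaction_type).value
    key = f"{itype}|{functional_group.strip().casefold()}|{normalize_residue(residue)}"
    return zlib.crc32(key.encode("utf-8")) % N_BINS + 1


def encode_fingerprint(records: Sequence[InteractionRecord]) -> BinaryFingerprint:
    """Binary fingerprint of a record set: order-invariant, geometry-blind."""
    return BinaryFingerprint(
        hash_feature(r.interaction_type, r.functional_group, r.residue) for r in records
    )


def restrict_to_fragment(
    profile: ComplexProfile, parent_atom_map: Sequence[str]
) -> tuple[InteractionRecord, ...]:
    """Records of *profile* mediated by the fragment's atoms.

    Membership is any-atom: a record belongs to the fragment if at least one
    of its ligand atoms is in the fragment's parent-atom map (the profiler
    reports single ligand atoms for most interaction types).
    """
    atoms = set(parent_atom_map)
    return tuple(r for r in profile.records if atoms.intersection(r.ligand_atoms))
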