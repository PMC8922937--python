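"""In-memory corpus: ligands, their RECAP leaves, and complex profiles.

The central working object downstream of parsing/fragmentation is the
*fingerprint table*: one row per (fragment identity, complex), carrying the
fragment-restricted binary fingerprint of that complex.  Conservation
scoring, filtering and reconstruction all operate on this table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .fingerprints import (
    BinaryFingerprint,
    ComplexProfile,
    encode_fingerprint,
    restrict_to_fragment,
)
from .fragmentation import Fragment, FragmentationOutcome, Ligand

logger = logging.getLogger(__name__)

FP_COLUMNS = [
    "frag_inchikey",
    "frag_smiles",
    "frag_mw",
    "complex_uid",
    "target_uniprot",
    "compound_inchikey",
    "fingerprint",
]


class ConsistencyError(ValueError):
    """Atom-identifier spaces of profiles and fragments do not line up."""


@dataclass
class Corpus:
    """Ligands with fragmentation outcomes plus per-complex profiles."""

    ligands: dict[str, Ligand] = field(default_factory=dict)  # by inchikey
    fragments: dict[str, tuple[Fragment, ...]] = field(default_factory=dict)
    profiles: list[ComplexProfile] = field(default_factory=list)

    def add_outcome(self, outcome: FragmentationOutcome) -> None:
        key = outcome.ligand.inchikey
        self.ligands[key] = outcome.ligand
        self.fragments[key] = outcome.fragments

    def profile_by_uid(self) -> dict[str, ComplexProfile]:
        return {p.complex_uid: p for p in self.profiles}

    def compound_fingerprints(self) -> pd.DataFrame:
        """Compound-level fingerprint per complex (unrestricted record list)."""
        rows = [
            {
                "complex_uid": p.complex_uid,
                "target_uniprot": p.target_uniprot,
                "compound_inchikey": p.compound_inchikey,
                "fingerprint": encode_fingerprint(p.records),
            }
            for p in self.profiles
            if p.records
        ]
        return pd.DataFrame(rows, columns=["complex_uid", "target_uniprot", "compound_inchikey", "fingerprint"])


def build_fingerprint_table(corpus: Corpus, check_atoms: bool = True) -> pd.DataFrame:
    """Fragment-level fingerprints for every complex in *corpus*.

    A fragment occurring several times in one complex contributes a single
    row: its per-complex fingerprint is the union over occurrences (each
    occurrence's records are gathered through its own atom map first).
    Complexes with no interaction records are dropped up front; fragments
    whose atoms intersect no record in a complex yield all-zero fingerprints
    and are dropped too (they carry no binding-mode information there).

    With ``check_atoms`` a profile whose records never touch any fragment
    atom of a fragmented compound raises :class:`ConsistencyError` — that
    pattern indicates mismatched atom-identifier spaces, not real chemistry.
    """
    rows: list[dict] = []
    n_empty = 0
    for profile in corpus.profiles:
        if not profile.records:
            n_empty += 1
            continue
        frags = corpus.fragments.get(profile.compound_inchikey, ())
        if not frags:
            continue  # non-fragmentable compounds carry no fragment rows
        per_identity: dict[str, set[int]] = {}
        meta: dict[str, Fragment] = {}
        matched_any = False
        for frag in frags:
            records = restrict_to_fragment(profile, frag.parent_atom_map)
            if not records:
                continue
            matched_any = True
            fp = encode_fingerprint(records)
            per_identity.setdefault(frag.frag_inchikey, set()).update(fp.bins)
            meta.setdefault(frag.frag_inchikey, frag)
        if not matched_any:
            if check_atoms:
                raise ConsistencyError(
                    f"profile {profile.complex_uid}: no record atom matches any "
                    f"fragment atom of compound {profile.compound_inchikey}"
                )
            continue
        for key, bins in sorted(per_identity.items()):
            frag = meta[key]
            rows.append(
                {
                    "frag_inchikey": key,
                    "frag_smiles": frag.frag_smiles,
                    "frag_mw": frag.mw,
                    "complex_uid": profile.complex_uid,
                    "target_uniprot": profile.target_uniprot,
                    "compound_inchikey": profile.compound_inchikey,
                    "fingerprint": BinaryFingerprint(bins),
                }
            )
    if n_empty:
        logger.info("dropped %d complexes without interaction records", n_empty)
    return pd.DataFrame(rows, columns=FP_COLUMNS)
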