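"""Readers and writers for the pipeline's tabular dialects.

All on-disk artifacts are plain TSV (or JSON for configs/truth metadata):

* ligand table      — compound_id, smiles [, inchikey, mw]
* fragment table    — compound_id, compound_inchikey, frag_inchikey,
                      frag_smiles, mw, parent_atom_map (comma-joined), status
* interaction table — complex_uid, target_uniprot, compound_inchikey,
                      interaction_type, ligand_atoms (comma-joined),
                      functional_group, residue
* fingerprint table — fragment-level rows with the 500-character 0/1 string
* conservation / reconstruction / grid tables

Writers prepend ``# key=value`` header comments (config hash, seed) which all
readers skip.  An optional reader ingests PLIP XML reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from lxml import etree

from .corpus import FP_COLUMNS, Corpus
from .fingerprints import (
    BinaryFingerprint,
    ComplexProfile,
    InteractionRecord,
    InteractionType,
)
from .fragmentation import (
    Fragment,
    FragmentationOutcome,
    FragmentationStatus,
    InputError,
    Ligand,
    ligand_from_smiles,
)

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kw)


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


# -- ligands ---------------------------------------------------------------

def read_ligands(path: str | Path) -> list[Ligand]:
    """Ligand table; identity columns are computed from SMILES when absent."""
    df = _read_tsv(path)
    for col in ("compound_id", "smiles"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    ligands = []
    for i, row in df.iterrows():
        if {"inchikey", "mw"} <= set(df.columns) and row["inchikey"]:
            ligands.append(
                Ligand(
                    compound_id=row["compound_id"],
                    smiles=row["smiles"],
                    inchikey=row["inchikey"],
                    mw=float(row["mw"]),
                )
            )
        else:
            try:
                ligands.append(ligand_from_smiles(row["compound_id"], row["smiles"]))
            except InputError as exc:
                raise InputError(f"{path}, line {i + 2}: {exc}") from exc
    return ligands


def write_ligands(ligands: "list[Ligand]", path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"compound_id": l.compound_id, "smiles": l.smiles, "inchikey": l.inchikey, "mw": l.mw}
            for l in ligands
        ],
        columns=["compound_id", "smiles", "inchikey", "mw"],
    )
    write_tsv(df, path, meta)


# -- fragments -------------------------------------------------------------

def write_fragments(
    outcomes: "list[FragmentationOutcome]",
    path: str | Path,
    keep_nonfragmentable: bool = False,
    meta: dict | None = None,
) -> None:
    rows = []
    for o in outcomes:
        if not o.fragments and not keep_nonfragmentable:
            continue
        if not o.fragments:
            rows.append(
                {
                    "compound_id": o.ligand.compound_id,
                    "compound_inchikey": o.ligand.inchikey,
                    "compound_smiles": o.ligand.smiles,
                    "compound_mw": o.ligand.mw,
                    "frag_inchikey": "",
                    "frag_smiles": "",
                    "mw": "",
                    "parent_atom_map": "",
                    "status": o.status.value,
                }
            )
            continue
        for f in o.fragments:
            rows.append(
                {
                    "compound_id": o.ligand.compound_id,
                    "compound_inchikey": o.ligand.inchikey,
                    "compound_smiles": o.ligand.smiles,
                    "compound_mw": o.ligand.mw,
                    "frag_inchikey": f.frag_inchikey,
                    "frag_smiles": f.frag_smiles,
                    "mw": f.mw,
                    "parent_atom_map": ",".join(f.parent_atom_map),
                    "status": o.status.value,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "compound_inchikey", "compound_smiles", "compound_mw",
            "frag_inchikey", "frag_smiles", "mw", "parent_atom_map", "status",
        ],
    )
    write_tsv(df, path, meta)


def read_fragments(path: str | Path) -> list[FragmentationOutcome]:
    df = _read_tsv(path)
    outcomes = []
    for (cid, ckey, csmi, cmw, status), sub in df.groupby(
        ["compound_id", "compound_inchikey", "compound_smiles", "compound_mw", "status"],
        sort=False,
    ):
        ligand = Ligand(compound_id=cid, smiles=csmi, inchikey=ckey, mw=float(cmw))
        frags = tuple(
            Fragment(
                frag_smiles=r["frag_smiles"],
                frag_inchikey=r["frag_inchikey"],
                mw=float(r["mw"]),
                parent_atom_map=tuple(r["parent_atom_map"].split(",")),
            )
            for _, r in sub.iterrows()
            if r["frag_inchikey"]
        )
        outcomes.append(FragmentationOutcome(ligand, frags, FragmentationStatus(status)))
    return outcomes


# -- interaction profiles --------------------------------------------------

PROFILE_COLUMNS = [
    "complex_uid", "target_uniprot", "compound_inchikey",
    "interaction_type", "ligand_atoms", "functional_group", "residue",
]


def parse_profiles(path: str | Path, dialect: str = "tsv") -> list[ComplexProfile]:
    """Parse per-complex interaction records (native TSV/JSON or PLIP XML).

    Complexes with zero interaction records are dropped with a log message,
    mirroring the removal of compounds without profiler data.
    """
    if dialect == "tsv":
        profiles = _parse_profiles_tsv(path)
    elif dialect == "json":
        profiles = _parse_profiles_json(path)
    elif dialect == "plip-xml":
        profiles = _parse_profiles_plip_xml(path)
    else:
        raise InputError(f"unknown profile dialect {dialect!r}")
    kept = [p for p in profiles if p.records]
    if len(kept) < len(profiles):
        logger.warning("dropped %d complexes without interactions", len(profiles) - len(kept))
    if not kept:
        logger.warning("no complexes with interaction records in %s", path)
    return kept


def _coerce_type(value: str, where: str) -> InteractionType:
    try:
        return InteractionType(value.strip().casefold())
    except ValueError:
        accepted = ", ".join(t.value for t in InteractionType)
        raise InputError(f"{where}: unknown interaction_type {value!r}; accepted: {accepted}")


def _parse_profiles_tsv(path: str | Path) -> list[ComplexProfile]:
    df = _read_tsv(path)
    if df.empty:
        return []
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    grouped: dict[str, list[InteractionRecord]] = {}
    keys: dict[str, tuple[str, str]] = {}
    for i, row in df.iterrows():
        where = f"{path}, line {i + 2}"
        itype = _coerce_type(row["interaction_type"], where)
        atoms = tuple(a for a in row["ligand_atoms"].split(",") if a)
        if not atoms:
            raise InputError(f"{where}: empty ligand_atoms")
        try:
            rec = InteractionRecord(
                complex_uid=row["complex_uid"],
                interaction_type=itype,
                ligand_atoms=atoms,
                functional_group=row["functional_group"],
                residue=row["residue"],
                target_uniprot=row["target_uniprot"],
            )
        except ValueError as exc:
            raise InputError(f"{where}: {exc}") from exc
        grouped.setdefault(row["complex_uid"], []).append(rec)
        keys[row["complex_uid"]] = (row["target_uniprot"], row["compound_inchikey"])
    return [
        ComplexProfile(uid, keys[uid][0], keys[uid][1], tuple(recs))
        for uid, recs in grouped.items()
    ]


def _parse_profiles_json(path: str | Path) -> list[ComplexProfile]:
    data = json.loads(Path(path).read_text())
    profiles = []
    for entry in data:
        records = tuple(
            InteractionRecord(
                complex_uid=entry["complex_uid"],
                interaction_type=_coerce_type(r["interaction_type"], str(path)),
                ligand_atoms=tuple(r["ligand_atoms"]),
                functional_group=r["functional_group"],
                residue=r["residue"],
                target_uniprot=entry["target_uniprot"],
            )
            for r in entry.get("records", [])
        )
        profiles.append(
            ComplexProfile(
                complex_uid=entry["complex_uid"],
                target_uniprot=entry["target_uniprot"],
                compound_inchikey=entry["compound_inchikey"],
                records=records,
            )
        )
    return profiles


# PLIP XML: (tag holding the interaction elements, our type, ligand-atom
# fields, functional-group strategy)
_PLIP_SECTIONS = {
    "hydrophobic_interactions": (InteractionType.HYDROPHOBIC, ["ligcarbonidx"], "hydrophobic"),
    "hydrogen_bonds": (InteractionType.HYDROGEN_BOND, None, None),
    "water_bridges": (InteractionType.WATER_BRIDGE, None, None),
    "salt_bridges": (InteractionType.SALT_BRIDGE, ["lig_idx_list"], "lig_group"),
    "pi_stacks": (InteractionType.PI_STACK, ["lig_idx_list"], "aromatic"),
    "pi_cation_interactions": (InteractionType.PI_CATION, ["lig_idx_list"], "lig_group"),
    "halogen_bonds": (InteractionType.HALOGEN_BOND, ["don_idx"], "donortype"),
    "metal_complexes": (InteractionType.METAL_COMPLEX, ["target_idx"], "target_type"),
}


def _parse_profiles_plip_xml(path: str | Path) -> list[ComplexProfile]:
    """Reader for PLIP report XML.

    The complex UID is assembled as PDB:HETID:CHAIN:POS from the report's
    pdbid and the binding site's identifiers; the protein residue (restype)
    is used as the interacting residue, including for water bridges.
    UniProt accession and compound InChIKey are taken from <uniprot_id> /
    <inchikey> elements when present (our fixtures carry them), else empty.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    pdbid = (root.findtext("pdbid") or "UNKN").upper()
    profiles = []
    for site in root.iter("bindingsite"):
        ids = site.find("identifiers")
        hetid = ids.findtext("hetid") if ids is not None else "LIG"
        chain = ids.findtext("chain") if ids is not None else "A"
        pos = ids.findtext("position") if ids is not None else "0"
        uid = f"{pdbid}:{hetid}:{chain}:{pos}"
        uniprot = (ids.findtext("uniprot_id") if ids is not None else "") or ""
        inchikey = (ids.findtext("inchikey") if ids is not None else "") or ""
        records: list[InteractionRecord] = []
        interactions = site.find("interactions")
        if interactions is None:
            continue
        for section in interactions:
            spec = _PLIP_SECTIONS.get(section.tag)
            if spec is None:
                continue
            itype, atom_fields, group_rule = spec
            for el in section:
                residue = el.findtext("restype") or ""
                if itype is InteractionType.HYDROGEN_BOND or itype is InteractionType.WATER_BRIDGE:
                    protisdon = (el.findtext("protisdon") or "").strip().lower() == "true"
                    atom_field = "acceptoridx" if protisdon else "donoridx"
                    atoms = [el.findtext(atom_field) or ""]
                    group = "acceptor" if protisdon else "donor"
                else:
                    atoms = []
                    for f in atom_fields:
                        node = el.find(f)
                        if node is None:
                            continue
                        if len(node):  # idx list container
                            atoms.extend(x.text for x in node)
                        else:
                            atoms.append(node.text)
                    group = group_rule if group_rule in (
                        "hydrophobic", "aromatic"
                    ) else (el.findtext(group_rule) or group_rule)
                atoms = tuple(a for a in atoms if a)
                if not atoms or not residue:
                    continue
                records.append(
                    InteractionRecord(
                        complex_uid=uid,
                        interaction_type=itype,
                        ligand_atoms=atoms,
                        functional_group=group,
                        residue=residue,
                        target_uniprot=uniprot,
                    )
                )
        profiles.append(ComplexProfile(uid, uniprot, inchikey, tuple(records)))
    return profiles


def write_profiles(profiles: "list[ComplexProfile]", path: str | Path, meta: dict | None = None) -> None:
    rows = [
        {
            "complex_uid": r.complex_uid,
            "target_uniprot": r.target_uniprot,
            "compound_inchikey": p.compound_inchikey,
            "interaction_type": r.interaction_type.value,
            "ligand_atoms": ",".join(r.ligand_atoms),
            "functional_group": r.functional_group,
            "residue": r.residue,
        }
        for p in profiles
        for r in p.records
    ]
    write_tsv(pd.DataFrame(rows, columns=PROFILE_COLUMNS), path, meta)


# -- fingerprint tables ----------------------------------------------------

def write_fingerprint_table(table: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    df = table.copy()
    df["fingerprint"] = [fp.to_string() for fp in df["fingerprint"]]
    write_tsv(df, path, meta)


def read_fingerprint_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["frag_mw"] = df["frag_mw"].astype(float)
    df["fingerprint"] = [BinaryFingerprint.from_string(s) for s in df["fingerprint"]]
    return df[FP_COLUMNS]


# -- corpus directories ----------------------------------------------------

def write_corpus(corpus: Corpus, outdir: str | Path, meta: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcomes = [
        FragmentationOutcome(corpus.ligands[k], corpus.fragments.get(k, ()),
                             FragmentationStatus.FRAGMENTED if corpus.fragments.get(k)
                             else FragmentationStatus.NON_FRAGMENTABLE)
        for k in sorted(corpus.ligands)
    ]
    write_ligands([corpus.ligands[k] for k in sorted(corpus.ligands)], outdir / "ligands.tsv", meta)
    write_fragments(outcomes, outdir / "fragments.tsv", keep_nonfragmentable=True, meta=meta)
    write_profiles(corpus.profiles, outdir / "profiles.tsv", meta)


def read_corpus(corpus_dir: str | Path) -> Corpus:
    corpus_dir = Path(corpus_dir)
    corpus = Corpus()
    for outcome in read_fragments(corpus_dir / "fragments.tsv"):
        corpus.add_outcome(outcome)
    corpus.profiles = parse_profiles(corpus_dir / "profiles.tsv", dialect="tsv")
    return corpus
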