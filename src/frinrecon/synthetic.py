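"""Seeded synthetic corpora with tunable binding-mode conservation.

The generator emulates the statistical structure the conservation analysis
assumes: every fragment-target pair owns a *canonical* set of interaction
feature triples (its "true" binding mode), and each complex containing the
fragment displays an independent thinning of that set — every canonical
record appears with probability ``conservation_p`` — plus Poisson-distributed
spurious records drawn from a noise vocabulary.  Under this model the
expected pairwise TIS of two complexes of the same fragment-target pair is
p / (2 - p) when noise is off, which gives an analytic limit for the whole
encode-and-compare path.

Two corpus modes exist:

* ``abstract`` (default test surface): fragment membership, atom maps and
  identities are synthesised directly, with valid-layout InChIKeys and
  fragment-sized molecular weights, so the chemistry layer is bypassed and
  tests are independent of fragmentation-library versioning;
* ``chemical``: compounds are small amides assembled from an acyl x amine
  building-block vocabulary, fragmented with the real RECAP rules (the amide
  cleavage yields exactly the intended leaves), and interactions are
  attached to the true parent-atom maps.

Canonical triples are rejection-sampled so that the triples of one
fragment-target pair occupy distinct fingerprint bins and the noise
vocabulary occupies bins disjoint from every canonical bin; signal and noise
are therefore separable in the truth metadata.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import Context, FilterConfig, conservation_table
from .corpus import Corpus, build_fingerprint_table
from .fingerprints import (
    AA_1TO3,
    ComplexProfile,
    InteractionRecord,
    InteractionType,
    hash_feature,
)
from .fragmentation import (
    Fragment,
    FragmentationOutcome,
    FragmentationStatus,
    Ligand,
    fragment_compound,
    ligand_from_smiles,
)

_RESIDUES = sorted(AA_1TO3.values())
_TYPES = list(InteractionType)

# chemical-mode building blocks: R-C(=O)-N(H)-R' amides; RECAP's amide rule
# cleaves the C(=O)-N bond, so the leaves are the capped acyl and amine parts
_ACYL = ["CC", "CCC", "CC(C)", "CCCC", "CC(C)C", "C1CC1"]
_AMINE = ["c1ccccc1", "Cc1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "C1CCCCC1", "Cc1ccco1"]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus; generation is pure in (spec, seed).

    ``conservation_p`` may be a single keep-probability or a sequence of
    block values assigned to fragments round-robin (fragment i gets
    ``p[i % len(p)]``); the assigned value applies to every target of the
    fragment and is recorded in the truth metadata.
    """

    n_targets: int = 14
    n_fragments: int = 12
    n_compounds: int = 30
    fragments_per_compound: tuple[int, int] = (2, 4)
    targets_per_compound: tuple[int, int] = (2, 5)
    complexes_per_pair: tuple[int, int] = (1, 3)
    canonical_set_size: int = 6
    conservation_p: "float | tuple[float, ...]" = 0.8
    noise_rate: float = 0.5
    noise_vocab_size: int = 30
    rng_seed: int = 0
    mode: str = "abstract"

    def __post_init__(self) -> None:
        ps = self.p_values()
        if any(not 0.0 <= p <= 1.0 for p in ps):
            raise ValueError("conservation_p values must lie in [0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be non-negative")
        for lo, hi in (
            self.fragments_per_compound,
            self.targets_per_compound,
            self.complexes_per_pair,
        ):
            if not 1 <= lo <= hi:
                raise ValueError("integer ranges must satisfy 1 <= lo <= hi")
        if self.fragments_per_compound[1] > self.n_fragments:
            raise ValueError("fragment vocabulary smaller than fragments_per_compound")
        if self.targets_per_compound[1] > self.n_targets:
            raise ValueError("target vocabulary smaller than targets_per_compound")
        if self.mode not in ("abstract", "chemical"):
            raise ValueError(f"unknown corpus mode {self.mode!r}")
        if self.mode == "chemical" and self.n_compounds > len(_ACYL) * len(_AMINE):
            raise ValueError("chemical mode supports at most "
                             f"{len(_ACYL) * len(_AMINE)} compounds")

    def p_values(self) -> tuple[float, ...]:
        p = self.conservation_p
        return (float(p),) if isinstance(p, (int, float)) else tuple(float(v) for v in p)


class Triple(NamedTuple):
    interaction_type: InteractionType
    functional_group: str
    residue: str

    @property
    def bin(self) -> int:
        return hash_feature(*self)


@dataclass
class CorpusTruth:
    """Ground truth of a generated corpus, for recovery tests."""

    spec: CorpusSpec
    canonical: dict[tuple[str, str], tuple[Triple, ...]]  # (frag, target) -> triples
    p: dict[tuple[str, str], float]
    noise_vocab: tuple[Triple, ...]
    noise_bins: frozenset[int]

    def canonical_bins(self, frag: str, target: str) -> frozenset[int]:
        return frozenset(t.bin for t in self.canonical[(frag, target)])


def _letters(index: int, width: int) -> str:
    """Base-26 uppercase rendering of *index*, zero-padded to *width*."""
    digits = []
    index = int(index)
    while index:
        index, r = divmod(index, 26)
        digits.append(string.ascii_uppercase[r])
    return "".join(reversed(digits)).rjust(width, "A")


def synthetic_inchikey(index: int, kind: str) -> str:
    """Valid-layout (14-10-1) synthetic InChIKey; *kind* tags the middle block."""
    blocks = {"fragment": "SYNTHETICF", "compound": "SYNTHETICC"}
    return f"SYN{_letters(index, 11)}-{blocks[kind]}-N"


def _sample_triples(
    rng: np.random.Generator, n: int, forbidden_bins: set[int], group_prefix: str
) -> list[Triple]:
    """Rejection-sample *n* triples with mutually distinct bins outside
    *forbidden_bins*."""
    out: list[Triple] = []
    used: set[int] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100_000:  # pragma: no cover
            raise RuntimeError("bin vocabulary exhausted; lower canonical_set_size")
        t = Triple(
            _TYPES[rng.integers(len(_TYPES))],
            f"{group_prefix}{rng.integers(400)}",
            _RESIDUES[rng.integers(len(_RESIDUES))],
        )
        b = t.bin
        if b in forbidden_bins or b in used:
            continue
        used.add(b)
        out.append(t)
    return out


def _abstract_outcomes(spec: CorpusSpec, rng: np.random.Generator) -> list[FragmentationOutcome]:
    frag_keys = [synthetic_inchikey(i, "fragment") for i in range(spec.n_fragments)]
    frag_mw = {k: float(rng.uniform(60.0, 280.0)) for k in frag_keys}
    outcomes = []
    for ci in range(spec.n_compounds):
        lo, hi = spec.fragments_per_compound
        n_frags = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(spec.n_fragments, size=n_frags, replace=False).tolist())
        fragments = []
        atom = 0
        for fi in members:
            atoms = tuple(f"a{atom + j}" for j in range(5))
            atom += 5
            fragments.append(
                Fragment(
                    frag_smiles=f"[synthetic:{fi}]",
                    frag_inchikey=frag_keys[fi],
                    mw=frag_mw[frag_keys[fi]],
                    parent_atom_map=atoms,
                )
            )
        ligand = Ligand(
            compound_id=f"CPD{ci:04d}",
            smiles=f"[synthetic-compound:{ci}]",
            inchikey=synthetic_inchikey(ci, "compound"),
            mw=sum(f.mw for f in fragments),
        )
        outcomes.append(
            FragmentationOutcome(ligand, tuple(fragments), FragmentationStatus.FRAGMENTED)
        )
    return outcomes


def _chemical_outcomes(spec: CorpusSpec, rng: np.random.Generator) -> list[FragmentationOutcome]:
    combos = list(itertools.product(_ACYL, _AMINE))
    idx = rng.choice(len(combos), size=spec.n_compounds, replace=False)
    outcomes = []
    for ci in sorted(idx.tolist()):
        acyl, amine = combos[ci]
        ligand = ligand_from_smiles(f"AMD{ci:04d}", f"{acyl}C(=O)N{amine}")
        outcomes.append(fragment_compound(ligand))
    return outcomes


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, CorpusTruth]:
    """Generate a corpus and its ground truth; pure function of the spec."""
    rng = np.random.default_rng(spec.rng_seed)
    targets = [f"P{10000 + i:05d}" for i in range(spec.n_targets)]
    outcomes = (
        _abstract_outcomes(spec, rng) if spec.mode == "abstract" else _chemical_outcomes(spec, rng)
    )

    noise_vocab = _sample_triples(rng, spec.noise_vocab_size, set(), "noise")
    noise_bins = {t.bin for t in noise_vocab}

    ps = spec.p_values()
    frag_keys = sorted({f.frag_inchikey for o in outcomes for f in o.fragments})
    frag_p = {k: ps[i % len(ps)] for i, k in enumerate(frag_keys)}

    canonical: dict[tuple[str, str], tuple[Triple, ...]] = {}
    p_truth: dict[tuple[str, str], float] = {}

    corpus = Corpus()
    uid_counter = 0
    for outcome in outcomes:
        corpus.add_outcome(outcome)
        if not outcome.fragments:
            continue
        lo, hi = spec.targets_per_compound
        n_t = int(rng.integers(lo, hi + 1))
        bound = sorted(rng.choice(spec.n_targets, size=n_t, replace=False).tolist())
        all_atoms = [a for f in outcome.fragments for a in f.parent_atom_map]
        for ti in bound:
            target = targets[ti]
            for frag in outcome.fragments:
                key = (frag.frag_inchikey, target)
                if key not in canonical:
                    canonical[key] = tuple(
                        _sample_triples(rng, spec.canonical_set_size, noise_bins, "grp")
                    )
                    p_truth[key] = frag_p[frag.frag_inchikey]
            lo_c, hi_c = spec.complexes_per_pair
            for _ in range(int(rng.integers(lo_c, hi_c + 1))):
                uid = f"{_letters(uid_counter, 4)}:LIG:A:{100 + uid_counter}"
                uid_counter += 1
                records: list[InteractionRecord] = []
                for frag in outcome.fragments:
                    key = (frag.frag_inchikey, target)
                    keep = rng.random(len(canonical[key])) < p_truth[key]
                    for triple, kept in zip(canonical[key], keep):
                        if not kept:
                            continue
                        atom = frag.parent_atom_map[rng.integers(len(frag.parent_atom_map))]
                        records.append(
                            InteractionRecord(
                                complex_uid=uid,
                                interaction_type=triple.interaction_type,
                                ligand_atoms=(atom,),
                                functional_group=triple.functional_group,
                                residue=triple.residue,
                                target_uniprot=target,
                            )
                        )
                for _ in range(rng.poisson(spec.noise_rate)):
                    triple = noise_vocab[rng.integers(len(noise_vocab))]
                    atom = all_atoms[rng.integers(len(all_atoms))]
                    records.append(
                        InteractionRecord(
                            complex_uid=uid,
                            interaction_type=triple.interaction_type,
                            ligand_atoms=(atom,),
                            functional_group=triple.functional_group,
                            residue=triple.residue,
                            target_uniprot=target,
                        )
                    )
                corpus.profiles.append(
                    ComplexProfile(
                        complex_uid=uid,
                        target_uniprot=target,
                        compound_inchikey=outcome.ligand.inchikey,
                        records=tuple(records),
                    )
                )
    truth = CorpusTruth(
        spec=spec,
        canonical=canonical,
        p=p_truth,
        noise_vocab=tuple(noise_vocab),
        noise_bins=frozenset(noise_bins),
    )
    return corpus, truth


BRIVUDINE_SMILES = "OC[C@H]1O[C@@H](C[C@@H]1O)N1C=C(/C=C/Br)C(=O)NC1=O"
BRIVUDINE_UID = "2VQS:BVD:C:1210"
KINASE_UNIPROT = "Q9XZT6"  # deoxynucleoside kinase


def worked_example_corpus(rng_seed: int = 0) -> tuple[Corpus, dict]:
    """Demo corpus around brivudine on deoxynucleoside kinase.

    Brivudine is fragmented with the real RECAP rules into its three leaves
    (a methyl-uracil, a deoxyribose-like ring, and a small bromine-containing
    leaf).  Synthetic companion compounds give the uracil and sugar leaves
    ample structural data — at least five distinct compounds, more than ten
    targets, and a well-conserved binding mode on the kinase — while the
    bromine leaf appears in fewer than five compounds and is therefore
    dropped by the fragment-set filter.  Reconstructing brivudine on the
    kinase then uses 2 of its 3 leaves: compound proportion 2/3.

    Returns the corpus and an info dict with the compound/target/complex ids
    and the per-leaf identities.
    """
    rng = np.random.default_rng(rng_seed)
    briv = ligand_from_smiles("BVD", BRIVUDINE_SMILES)
    outcome = fragment_compound(briv)
    if len(outcome.distinct_inchikeys) != 3:  # pragma: no cover
        raise RuntimeError("RECAP no longer yields 3 brivudine leaves")
    leaves = {f.frag_inchikey: f for f in outcome.fragments}
    bromine_key = next(k for k, f in leaves.items() if "Br" in f.frag_smiles)
    rich_keys = sorted(k for k in leaves if k != bromine_key)

    corpus = Corpus()
    corpus.add_outcome(outcome)
    targets = [KINASE_UNIPROT] + [f"P{20000 + i:05d}" for i in range(12)]

    canonical: dict[tuple[str, str], list[Triple]] = {}
    forbidden: set[int] = set()

    def triples_for(frag_key: str, target: str, n: int = 6) -> list[Triple]:
        key = (frag_key, target)
        if key not in canonical:
            ts = _sample_triples(rng, n, forbidden, "grp")
            forbidden.update(t.bin for t in ts)
            canonical[key] = ts
        return canonical[key]

    uid_counter = 0

    def add_complex(
        compound_key: str, target: str, frags: Sequence[Fragment], p: float,
        uid: str | None = None,
    ) -> None:
        nonlocal uid_counter
        if uid is None:
            uid = f"{_letters(uid_counter, 4)}:LIG:A:{200 + uid_counter}"
            uid_counter += 1
        records = []
        for frag in frags:
            for triple in triples_for(frag.frag_inchikey, target):
                if rng.random() >= p:
                    continue
                atom = frag.parent_atom_map[rng.integers(len(frag.parent_atom_map))]
                records.append(
                    InteractionRecord(
                        complex_uid=uid,
                        interaction_type=triple.interaction_type,
                        ligand_atoms=(atom,),
                        functional_group=triple.functional_group,
                        residue=triple.residue,
                        target_uniprot=target,
                    )
                )
        corpus.profiles.append(
            ComplexProfile(uid, target, compound_key, tuple(records))
        )

    def companion(index: int, frag_key: str, bound: Sequence[str], p: float) -> None:
        frag = leaves[frag_key]
        syn = Fragment(
            frag_smiles=frag.frag_smiles,
            frag_inchikey=frag.frag_inchikey,
            mw=frag.mw,
            parent_atom_map=tuple(f"c{index}a{j}" for j in range(5)),
        )
        lig = Ligand(
            compound_id=f"CMP{index:03d}",
            smiles=f"[companion:{index}]",
            inchikey=synthetic_inchikey(1000 + index, "compound"),
            mw=max(frag.mw, 1.0) + 100.0,
        )
        corpus.add_outcome(
            FragmentationOutcome(lig, (syn,), FragmentationStatus.FRAGMENTED)
        )
        for target in bound:
            for _ in range(2):
                add_complex(lig.inchikey, target, (syn,), p)

    idx = 0
    for frag_key in rich_keys:
        for i in range(6):
            bound = [KINASE_UNIPROT, targets[1 + (2 * i) % 12], targets[2 + (2 * i) % 12]]
            companion(idx, frag_key, bound, p=0.95)
            idx += 1
    for i in range(2):  # bromine leaf: deliberately < 5 compounds
        companion(idx, bromine_key, [targets[1 + i]], p=0.95)
        idx += 1

    # brivudine's own complex on the kinase: full canonical sets of the two
    # data-rich leaves, mediated through the real RECAP atom maps
    own_frags = [f for f in outcome.fragments if f.frag_inchikey in rich_keys]
    add_complex(briv.inchikey, KINASE_UNIPROT, own_frags, p=1.0, uid=BRIVUDINE_UID)
    info = {
        "compound_inchikey": briv.inchikey,
        "target_uniprot": KINASE_UNIPROT,
        "complex_uid": BRIVUDINE_UID,
        "bromine_leaf": leaves[bromine_key].frag_smiles,
        "rich_leaves": [leaves[k].frag_smiles for k in rich_keys],
        "outcome": outcome,
    }
    return corpus, info


class RecoveryResult(NamedTuple):
    table: pd.DataFrame
    spearman_rho: float  # NaN when the truth has a single distinct p


def recover_conservation(
    corpus: Corpus, truth: CorpusTruth, cfg: FilterConfig | None = None
) -> RecoveryResult:
    """Compare empirical per-(fragment, target) mTIS against the truth's p.

    With no filter config the raw fingerprint table is scored, so every
    fragment-target pair with >=2 complexes from >=2 compounds contributes.
    Reports the Spearman correlation between the generating keep-probability
    and the recovered mTIS (NaN, with a degenerate-ranking flag, when only
    one p value is present).
    """
    table = build_fingerprint_table(corpus)
    cons = conservation_table(table, cfg)
    cons = cons[cons["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value]
    rows = []
    for r in cons.itertuples():
        key = (r.frag_inchikey, r.target_uniprot)
        if key not in truth.p:
            continue
        rows.append(
            {
                "frag_inchikey": r.frag_inchikey,
                "target_uniprot": r.target_uniprot,
                "true_p": truth.p[key],
                "mtis": r.mtis,
                "n_complexes": r.n_complexes,
            }
        )
    out = pd.DataFrame(
        rows, columns=["frag_inchikey", "target_uniprot", "true_p", "mtis", "n_complexes"]
    )
    if out.empty or out["true_p"].nunique() < 2:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(out["true_p"], out["mtis"]).statistic)
    return RecoveryResult(table=out, spearman_rho=rho)
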