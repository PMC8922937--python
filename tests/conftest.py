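import numpy as np
import pytest

from frinrecon.fingerprints import BinaryFingerprint, ComplexProfile, InteractionRecord
from frinrecon.synthetic import CorpusSpec, generate_corpus


def make_record(
    uid="1ABC:LIG:A:100",
    itype="hydrogen_bond",
    atoms=("0",),
    group="donor",
    residue="ARG",
    target="P00001",
):
    return InteractionRecord(
        complex_uid=uid,
        interaction_type=itype,
        ligand_atoms=tuple(atoms),
        functional_group=group,
        residue=residue,
        target_uniprot=target,
    )


def make_profile(records, uid="1ABC:LIG:A:100", target="P00001", compound="SYNAAAAAAAAAAA-SYNTHETICC-N"):
    return ComplexProfile(
        complex_uid=uid, target_uniprot=target, compound_inchikey=compound, records=tuple(records)
    )


def random_fingerprint(rng: np.random.Generator, density: float = 0.02) -> BinaryFingerprint:
    mask = rng.random(500) < density
    return BinaryFingerprint(int(i) + 1 for i in np.flatnonzero(mask))


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic default-condition synthetic corpus."""
    return generate_corpus(CorpusSpec(rng_seed=7))
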