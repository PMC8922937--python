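"""Representative fingerprints, gates and the reconstruction estimator."""

import numpy as np
import pandas as pd
import pytest

from frinrecon.conservation import FilterConfig
from frinrecon.fingerprints import BinaryFingerprint
from frinrecon.reconstruction import (
    BindingModeReconstructor,
    ReconstructionStatus,
    ReconstructionThresholds,
    compound_proportion,
    merge_fragment_fingerprints,
    representative_fingerprint,
    select_usable_fragments,
)
from frinrecon.synthetic import CorpusSpec, generate_corpus

RELAXED = dict(min_compounds=2, min_targets=2)


class TestRepresentativeFingerprint:
    def test_single_fingerprint_is_its_own_representative(self):
        fp = BinaryFingerprint([1, 5])
        rep = representative_fingerprint([fp])
        assert np.array_equal(rep.freqs, fp.to_array().astype(float))
        assert rep.n_source_fps == 1

    def test_bin_active_in_two_of_three_scores_two_thirds(self):
        fps = [BinaryFingerprint([1, 2]), BinaryFingerprint([1]), BinaryFingerprint([3])]
        rep = representative_fingerprint(fps)
        assert rep.freqs[0] == pytest.approx(2 / 3)
        assert rep.freqs[1] == pytest.approx(1 / 3)

    def test_exclusion_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        fps = [
            BinaryFingerprint((int(b) + 1 for b in np.flatnonzero(rng.random(500) < 0.01)) or [1])
            for _ in range(30)
        ]
        uids = [f"U{i}" for i in range(30)]
        rep = representative_fingerprint(fps, uids=uids, exclude_uid="U7")
        counts = np.zeros(500)
        for u, fp in zip(uids, fps):
            if u != "U7":
                counts += fp.to_array()
        assert rep.n_source_fps == 29
        assert np.allclose(rep.freqs, counts / 29)
        assert "U7" not in rep.source_uids

    def test_empty_after_exclusion(self):
        assert representative_fingerprint([BinaryFingerprint([1])], uids=["U1"], exclude_uid="U1") is None


class TestCompoundProportion:
    def test_two_of_three(self):
        assert compound_proportion(2, 3) == pytest.approx(2 / 3)

    def test_extremes(self):
        assert compound_proportion(0, 4) == 0.0
        assert compound_proportion(4, 4) == 1.0

    def test_non_fragmentable_rejected(self):
        with pytest.raises(ValueError):
            compound_proportion(0, 0)


class TestMerge:
    def test_single_representative_unchanged(self):
        rep = representative_fingerprint([BinaryFingerprint([2, 9])])
        assert np.array_equal(merge_fragment_fingerprints([rep]), rep.freqs)

    def test_mean_over_active_representatives(self):
        r1 = representative_fingerprint([BinaryFingerprint([1]), BinaryFingerprint([1, 2])])
        r2 = representative_fingerprint([BinaryFingerprint([1])])
        merged = merge_fragment_fingerprints([r1, r2])
        assert merged[0] == pytest.approx((0.5 + 1.0) / 2) or merged[0] == pytest.approx(1.0)
        # bin 1: r1 freq 1.0, r2 freq 1.0 -> 1.0 ; bin 2: active only in r1 -> 0.5
        assert merged[0] == pytest.approx(1.0)
        assert merged[1] == pytest.approx(0.5)

    def test_active_mean_vs_all_mean(self):
        r1 = representative_fingerprint([BinaryFingerprint([1]), BinaryFingerprint([2])])  # 0.5/0.5
        r2 = representative_fingerprint([BinaryFingerprint([3])])
        active = merge_fragment_fingerprints([r1, r2], mode="active")
        over_all = merge_fragment_fingerprints([r1, r2], mode="all")
        assert active[0] == pytest.approx(0.5)
        assert over_all[0] == pytest.approx(0.25)

    def test_union_of_activated_bins(self):
        rng = np.random.default_rng(2)
        reps = [
            representative_fingerprint(
                [BinaryFingerprint(int(b) + 1 for b in rng.choice(500, size=5, replace=False))]
            )
            for _ in range(3)
        ]
        merged = merge_fragment_fingerprints(reps)
        union = set().union(*(set(np.flatnonzero(r.freqs > 0)) for r in reps))
        assert set(np.flatnonzero(merged > 0)) == union
        # brute-force per-bin recomputation
        for b in union:
            vals = [r.freqs[b] for r in reps if r.freqs[b] > 0]
            assert merged[b] == pytest.approx(np.mean(vals))


@pytest.fixture(scope="module")
def fitted():
    corpus, _ = generate_corpus(CorpusSpec(rng_seed=1, conservation_p=0.9))
    est = BindingModeReconstructor(**RELAXED).fit(corpus)
    return corpus, est


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        est = BindingModeReconstructor(bm_conservation=0.7)
        assert est.get_params()["bm_conservation"] == 0.7
        est.set_params(compound_proportion=0.8)
        assert est.compound_proportion == 0.8

    def test_reconstructed_bins_subset_of_source_union(self, fitted):
        corpus, est = fitted
        done = 0
        for p in corpus.profiles[:80]:
            if not p.records or p.compound_inchikey not in est.fragments_by_compound_:
                continue
            res = est.reconstruct(p.compound_inchikey, p.target_uniprot)
            if res.status is not ReconstructionStatus.RECONSTRUCTED:
                continue
            done += 1
            union = set()
            for frag in res.fragments_used:
                sub = est.table_[
                    (est.table_["frag_inchikey"] == frag)
                    & (est.table_["target_uniprot"] == p.target_uniprot)
                ]
                for fp in sub["fingerprint"]:
                    union |= fp.bins
            assert res.active_bins <= union
        assert done > 0

    def test_gate_monotonicity_over_threshold_pairs(self, fitted):
        corpus, est = fitted
        pairs = sorted(
            {
                (p.compound_inchikey, p.target_uniprot)
                for p in corpus.profiles
                if p.records and p.compound_inchikey in est.fragments_by_compound_
            }
        )

        def reconstructed_at(pt, ct):
            est.set_params(compound_proportion=pt, bm_conservation=ct)
            return {
                pair
                for pair in pairs
                if est.reconstruct(*pair).status is ReconstructionStatus.RECONSTRUCTED
            }

        loose = reconstructed_at(0.5, 0.5)
        strict = reconstructed_at(1.0, 1.0)
        middle = reconstructed_at(0.7, 0.7)
        assert strict <= middle <= loose

    def test_perfect_conservation_no_threshold_escapes(self):
        corpus, _ = generate_corpus(CorpusSpec(rng_seed=4, conservation_p=1.0, noise_rate=0.0))
        est = BindingModeReconstructor(bm_conservation=1.0, **RELAXED).fit(corpus)
        assert all(v == pytest.approx(1.0) for v in est.mtis_.values())

    def test_full_conservation_gate_admits_only_perfect_fragments(self):
        corpus, _ = generate_corpus(CorpusSpec(rng_seed=1, conservation_p=0.6))
        est = BindingModeReconstructor(bm_conservation=1.0, **RELAXED).fit(corpus)
        for (frag, target), mtis in list(est.mtis_.items())[:20]:
            _, usable = est.usable_fragments([frag], target)
            assert (usable == [frag]) == (mtis >= 1.0)


class TestLeaveOneOut:
    def test_own_fingerprint_never_read(self):
        """Instrumented source tracking: the excluded complex appears in no
        representative's sources."""
        corpus, _ = generate_corpus(CorpusSpec(rng_seed=2, conservation_p=0.9))
        est = BindingModeReconstructor(**RELAXED).fit(corpus)
        checked = 0
        for p in corpus.profiles:
            if not p.records or p.compound_inchikey not in est.fragments_by_compound_:
                continue
            res = est.reconstruct(
                p.compound_inchikey, p.target_uniprot, exclude_uid=p.complex_uid
            )
            if res.status is ReconstructionStatus.RECONSTRUCTED:
                checked += 1
                assert p.complex_uid not in res.source_uids
        assert checked > 10

    def test_self_only_corpus_yields_no_fragment_data(self):
        """If a compound's fragments occur only in its own complexes,
        leave-one-out exclusion empties every source pool."""
        # a single compound: its fragments occur in no other complex, so
        # leave-one-out exclusion of each complex empties every source pool
        spec = CorpusSpec(
            n_targets=2, n_fragments=4, n_compounds=1,
            fragments_per_compound=(2, 2), targets_per_compound=(1, 1),
            complexes_per_pair=(1, 1), conservation_p=1.0, noise_rate=0.0, rng_seed=0,
        )
        corpus, _ = generate_corpus(spec)
        est = BindingModeReconstructor(
            min_compounds=1, min_targets=1, mtis_floor=0.0, bm_conservation=0.0
        ).fit(corpus)
        for p in corpus.profiles:
            res = est.reconstruct(
                p.compound_inchikey, p.target_uniprot, exclude_uid=p.complex_uid
            )
            assert res.status is ReconstructionStatus.NO_FRAGMENT_DATA


class TestSelectUsableFragments:
    CONS = pd.DataFrame(
        {
            "frag_inchikey": ["F1", "F2", "F3", "F1"],
            "context": ["diff_compounds_same_target"] * 4,
            "target_uniprot": ["T1", "T1", "T1", "T2"],
            "n_complexes": [30, 32, 4, 8],
            "min_tis": [0.5, 0.3, 0.1, 0.2],
            "max_tis": [1.0, 0.9, 0.9, 0.9],
            "mtis": [0.88, 0.63, 0.40, 0.55],
        }
    )

    def test_conserved_fragments_kept_at_06(self):
        """Two well-conserved fragments (mTIS 0.88 and 0.63) pass the 0.6
        gate; the poorly conserved one does not."""
        got = select_usable_fragments(
            ["F1", "F2", "F3"], "T1", self.CONS, ReconstructionThresholds(0.6, 0.6)
        )
        assert got == ["F1", "F2"]

    def test_floor_applies_even_with_loose_threshold(self):
        got = select_usable_fragments(
            ["F1"], "T2", self.CONS, ReconstructionThresholds(0.5, 0.0), mtis_floor=0.5
        )
        assert got == ["F1"]
        got = select_usable_fragments(
            ["F3"], "T1", self.CONS, ReconstructionThresholds(0.5, 0.0), mtis_floor=0.5
        )
        assert got == []

    def test_matches_brute_force_scan(self):
        thresholds = ReconstructionThresholds(0.5, 0.55)
        got = select_usable_fragments(["F1", "F2", "F3"], "T1", self.CONS, thresholds)
        oracle = [
            f
            for f in ["F1", "F2", "F3"]
            if any(
                (r.frag_inchikey == f)
                and (r.target_uniprot == "T1")
                and (r.mtis >= max(0.5, thresholds.bm_conservation))
                for r in self.CONS.itertuples()
            )
        ]
        assert got == oracle
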