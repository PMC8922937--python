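"""Pairwise TIS, mTIS statistics, grouping contexts and fragment filters."""

import numpy as np
import pandas as pd
import pytest

from frinrecon.conservation import (
    Context,
    FilterConfig,
    conservation_table,
    filter_fragment_set,
    group_contexts,
    mean_tis,
    tanimoto_similarity,
)
from frinrecon.corpus import build_fingerprint_table
from frinrecon.fingerprints import BinaryFingerprint
from frinrecon.synthetic import CorpusSpec, generate_corpus
from tests.conftest import random_fingerprint


def oracle_tanimoto(fp1, fp2):
    """Independent bit-array route: |a & b| / |a | b|."""
    a, b = fp1.to_array(), fp2.to_array()
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 0.0


class TestTanimoto:
    def test_identical_fingerprints(self):
        fp = BinaryFingerprint([3, 7, 100])
        assert tanimoto_similarity(fp, fp) == 1.0

    def test_disjoint_fingerprints(self):
        assert tanimoto_similarity(BinaryFingerprint([1, 2]), BinaryFingerprint([3, 4])) == 0.0

    def test_partial_overlap(self):
        got = tanimoto_similarity(BinaryFingerprint([1, 2, 3]), BinaryFingerprint([2, 3, 4]))
        assert got == pytest.approx(0.5)

    def test_empty_vs_empty_defined_as_zero(self):
        assert tanimoto_similarity(BinaryFingerprint(), BinaryFingerprint()) == 0.0

    def test_agrees_with_oracle_on_random_pairs(self):
        """1,000 random 500-bin pairs against the set-arithmetic oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            f1 = random_fingerprint(rng, density=rng.uniform(0.0, 0.1))
            f2 = random_fingerprint(rng, density=rng.uniform(0.0, 0.1))
            assert tanimoto_similarity(f1, f2) == pytest.approx(oracle_tanimoto(f1, f2))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            f1, f2 = random_fingerprint(rng), random_fingerprint(rng)
            s12, s21 = tanimoto_similarity(f1, f2), tanimoto_similarity(f2, f1)
            assert s12 == s21 and 0.0 <= s12 <= 1.0
            if f1.bins and s12 == 1.0:
                assert f1.bins == f2.bins


class TestMeanTIS:
    def test_identical_fingerprints_score_one(self):
        fps = [BinaryFingerprint([1, 2, 3])] * 5
        assert mean_tis(fps) == (1.0, 1.0, 1.0)

    def test_single_pair(self):
        stats = mean_tis([BinaryFingerprint([1, 2]), BinaryFingerprint([2, 3])])
        assert stats.min == stats.max == stats.mean == pytest.approx(1 / 3)

    def test_matches_brute_force_pairwise_loop(self):
        rng = np.random.default_rng(11)
        fps = [random_fingerprint(rng, 0.05) for _ in range(6)]
        values = [
            oracle_tanimoto(fps[i], fps[j])
            for i in range(len(fps))
            for j in range(i + 1, len(fps))
        ]
        stats = mean_tis(fps)
        assert stats.mean == pytest.approx(np.mean(values))
        assert stats.min == pytest.approx(min(values))
        assert stats.max == pytest.approx(max(values))

    def test_adding_disjoint_fingerprint_lowers_mean(self):
        fps = [BinaryFingerprint([1, 2, 3])] * 4
        lowered = mean_tis(fps + [BinaryFingerprint([400])])
        assert lowered.mean < 1.0

    def test_fewer_than_two_is_undefined(self):
        with pytest.raises(ValueError):
            mean_tis([BinaryFingerprint([1])])


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "frag_inchikey", "frag_smiles", "frag_mw", "complex_uid",
            "target_uniprot", "compound_inchikey", "fingerprint",
        ],
    )


def _row(frag="F1", uid="U1", target="T1", compound="C1", mw=100.0, bins=(1,)):
    return {
        "frag_inchikey": frag, "frag_smiles": frag, "frag_mw": mw, "complex_uid": uid,
        "target_uniprot": target, "compound_inchikey": compound,
        "fingerprint": BinaryFingerprint(bins),
    }


class TestGroupContexts:
    def test_single_compound_single_target_has_no_per_target_group(self):
        t = _table([_row(uid="U1"), _row(uid="U2")])
        g = group_contexts(t)
        assert (g["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value).sum() == 0
        assert (g["context"] == Context.ALL_TARGETS.value).sum() == 1

    def test_two_compounds_same_target_form_one_group(self):
        t = _table([_row(uid="U1", compound="C1"), _row(uid="U2", compound="C2")])
        g = group_contexts(t)
        per_target = g[g["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value]
        assert len(per_target) == 1
        assert len(per_target.iloc[0]["complex_uids"]) == 2

    def test_same_compound_needs_two_targets(self):
        t = _table([_row(uid="U1", target="T1"), _row(uid="U2", target="T1")])
        g = group_contexts(t)
        assert (g["context"] == Context.SAME_COMPOUND_DIFF_TARGETS.value).sum() == 0
        t2 = _table([_row(uid="U1", target="T1"), _row(uid="U2", target="T2")])
        g2 = group_contexts(t2)
        assert (g2["context"] == Context.SAME_COMPOUND_DIFF_TARGETS.value).sum() == 1

    def test_group_sizes_match_brute_force_oracle(self, small_corpus):
        corpus, _ = small_corpus
        table = build_fingerprint_table(corpus)
        groups = group_contexts(table)
        rows = list(table.itertuples())
        for g in groups[
            groups["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value
        ].itertuples():
            oracle = {
                r.complex_uid
                for r in rows
                if r.frag_inchikey == g.frag_inchikey and r.target_uniprot == g.target_uniprot
            }
            compounds = {
                r.compound_inchikey
                for r in rows
                if r.frag_inchikey == g.frag_inchikey and r.target_uniprot == g.target_uniprot
            }
            assert set(g.complex_uids) == oracle and len(compounds) >= 2


class TestFilterFragmentSet:
    CFG = FilterConfig(min_compounds=2, min_targets=2, rng_seed=5)

    def test_mw_window_is_strict(self):
        rows = [
            _row(frag="BIG", mw=350.0, uid=f"U{i}", compound=f"C{i}", target=f"T{i}")
            for i in range(3)
        ]
        assert filter_fragment_set(_table(rows), self.CFG).empty

    def test_rare_fragment_excluded(self):
        """A fragment in too few compounds is dropped even at valid MW."""
        rows = [_row(frag="BR", mw=80.0, uid=f"U{i}", compound="C1", target=f"T{i}") for i in range(4)]
        assert filter_fragment_set(_table(rows), self.CFG).empty

    def test_cap_keeps_one_complex_per_pair_deterministically(self):
        cfg = FilterConfig(min_compounds=2, min_targets=2, max_complexes=500, rng_seed=9)
        rows = []
        uid = 0
        # 550 (target, compound) pairs; some pairs have 2 complexes -> 600 total
        for i in range(550):
            target, compound = f"T{i % 25:02d}", f"C{i:03d}"
            n = 2 if i < 50 else 1
            for _ in range(n):
                rows.append(_row(frag="F", mw=120.0, uid=f"U{uid:04d}", target=target, compound=compound))
                uid += 1
        t = _table(rows)
        out1 = filter_fragment_set(t, cfg)
        out2 = filter_fragment_set(t, cfg)
        assert out1["complex_uid"].nunique() == 550
        assert list(out1["complex_uid"]) == list(out2["complex_uid"])
        # independent reference sampler with the same pinned seed
        rng = np.random.default_rng(cfg.rng_seed)
        expected = set()
        for _, pair_sub in t.groupby(["target_uniprot", "compound_inchikey"], sort=True):
            uids = sorted(pair_sub["complex_uid"].unique())
            expected.add(uids[rng.integers(len(uids))])
        assert set(out1["complex_uid"]) == expected

    def test_idempotence(self):
        corpus, _ = generate_corpus(CorpusSpec(rng_seed=3))
        table = build_fingerprint_table(corpus)
        cfg = FilterConfig(min_compounds=3, min_targets=5, rng_seed=3)
        once = filter_fragment_set(table, cfg)
        twice = filter_fragment_set(once, cfg)
        pd.testing.assert_frame_equal(once, twice)


class TestConservationTable:
    def test_identical_fingerprints_score_one(self):
        rows = [
            _row(frag="F", uid=f"U{i}", compound=f"C{i}", target="T1", bins=(1, 2, 3))
            for i in range(4)
        ]
        cons = conservation_table(_table(rows))
        assert (cons["mtis"] == 1.0).all()
        assert (cons["min_tis"] <= cons["mtis"]).all()
        assert (cons["mtis"] <= cons["max_tis"]).all()

    def test_empty_table_gives_empty_output(self):
        cons = conservation_table(_table([]))
        assert cons.empty

    def test_conserved_at_06_is_subset_of_05(self, small_corpus):
        """The mTIS >= 0.6 fragment set nests inside the mTIS >= 0.5 set."""
        corpus, _ = small_corpus
        cons = conservation_table(build_fingerprint_table(corpus))
        per_target = cons[cons["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value]
        strict = set(per_target[per_target["mtis"] >= 0.6]["frag_inchikey"])
        permissive = set(per_target[per_target["mtis"] >= 0.5]["frag_inchikey"])
        assert strict <= permissive

    def test_mean_mtis_increases_with_conservation_parameter(self):
        """Corpus-level mTIS responds monotonically to the generator's p."""
        means = []
        for p in (0.3, 0.6, 0.9):
            vals = []
            for seed in range(3):
                corpus, _ = generate_corpus(
                    CorpusSpec(rng_seed=seed, conservation_p=p, noise_rate=0.2)
                )
                cons = conservation_table(build_fingerprint_table(corpus))
                sub = cons[cons["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value]
                vals.append(sub["mtis"].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
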