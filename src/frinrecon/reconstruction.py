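"""Fragment-based reconstruction of compound-target interaction fingerprints.

A compound's binding mode on a target is assembled from the binding modes of
its RECAP leaf fragments on that same target (target-based transfer):

1. the compound is fragmented into leaves;
2. fragments with structural data on the target, a conservation score
   mtis >= max(0.5, bm_conservation) in the different-compounds/same-target
   context, and passing the fragment-set filters are *usable*;
3. the compound proportion (usable / total distinct leaves) must reach the
   ``compound_proportion`` threshold;
4. each usable fragment gets a *representative fingerprint*: per bin, the
   frequency with which the bin is active over all of the fragment's
   complexes on the target (the held-out complex is excluded in
   leave-one-out evaluation);
5. representatives are merged into one frequency fingerprint over the union
   of their active bins.

The pipeline is exposed as :class:`BindingModeReconstructor`, a scikit-learn
style estimator: ``fit`` ingests a fingerprinted corpus and precomputes the
filtered fragment subset, conservation scores and per-(fragment, target)
fingerprint pools; ``reconstruct``/``predict`` then evaluate compound-target
pairs.  The module-level functions are thin wrappers over the same steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .conservation import Context, FilterConfig, conservation_table, filter_fragment_set
from .corpus import Corpus, build_fingerprint_table
from .fingerprints import N_BINS, BinaryFingerprint

logger = logging.getLogger(__name__)


class ReconstructionStatus(str, Enum):
    RECONSTRUCTED = "reconstructed"
    NO_FRAGMENT_DATA = "no_fragment_data"
    BELOW_PROPORTION = "below_proportion"
    BELOW_CONSERVATION = "below_conservation"


@dataclass(frozen=True)
class RepresentativeFingerprint:
    """Frequency-valued consensus fingerprint of a fragment on one target.

    ``freqs[b-1]`` is (number of source fingerprints with bin b active) /
    ``n_source_fps``; ``source_uids`` records the complexes aggregated, for
    leave-one-out audit.
    """

    frag_inchikey: str
    target_uniprot: str
    freqs: np.ndarray
    n_source_fps: int
    source_uids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.freqs.shape != (N_BINS,):
            raise ValueError("freqs must have length 500")
        if self.n_source_fps < 1:
            raise ValueError("representative needs at least one source fingerprint")


@dataclass(frozen=True)
class ReconstructionThresholds:
    compound_proportion: float = 0.6
    bm_conservation: float = 0.6

    def __post_init__(self) -> None:
        for v in (self.compound_proportion, self.bm_conservation):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class ReconstructionResult:
    compound_inchikey: str
    target_uniprot: str
    status: ReconstructionStatus
    fingerprint: np.ndarray | None
    fragments_used: tuple[str, ...]
    proportion_achieved: float
    n_total_fragments: int
    source_uids: tuple[str, ...] = ()

    @property
    def active_bins(self) -> frozenset[int]:
        if self.fingerprint is None:
            return frozenset()
        return frozenset(int(b) + 1 for b in np.flatnonzero(self.fingerprint > 0))


def compound_proportion(n_usable_fragments: int, n_total_fragments: int) -> float:
    """Fraction of a compound's distinct leaf fragments that are usable.

    The denominator counts all distinct RECAP leaves of the compound,
    including those lacking structural data; a non-fragmentable compound
    (zero leaves) cannot be reconstructed by this pipeline.
    """
    if n_total_fragments < 1:
        raise ValueError("compound has no leaf fragments: not reconstructable")
    if not 0 <= n_usable_fragments <= n_total_fragments:
        raise ValueError("usable fragment count outside [0, total]")
    return n_usable_fragments / n_total_fragments


def representative_fingerprint(
    fps: Sequence[BinaryFingerprint],
    frag_inchikey: str = "",
    target_uniprot: str = "",
    uids: Sequence[str] | None = None,
    exclude_uid: str | None = None,
) -> RepresentativeFingerprint | None:
    """Per-bin activation frequency over a fragment's source fingerprints.

    When *exclude_uid* is given, fingerprints of that complex contribute
    nothing (leave-one-out).  Returns None if no fingerprint remains.
    """
    uids = list(uids) if uids is not None else [""] * len(fps)
    if exclude_uid is None:
        kept = list(zip(uids, fps))
    else:
        kept = [(u, fp) for u, fp in zip(uids, fps) if u != exclude_uid]
    if not kept:
        return None
    counts = np.zeros(N_BINS, dtype=float)
    for _, fp in kept:
        counts += fp.to_array()
    return RepresentativeFingerprint(
        frag_inchikey=frag_inchikey,
        target_uniprot=target_uniprot,
        freqs=counts / len(kept),
        n_source_fps=len(kept),
        source_uids=tuple(u for u, _ in kept),
    )


def merge_fragment_fingerprints(
    reps: Sequence[RepresentativeFingerprint], mode: str = "active"
) -> np.ndarray:
    """Merge fragment representatives into one compound frequency fingerprint.

    The activated-bin set is the union over representatives.  With
    ``mode="active"`` (default) each bin's value is the mean frequency over
    the representatives in which the bin is active, so a bin's score reflects
    how often it was observed, not how many unrelated fragments the compound
    has; ``mode="all"`` averages over all representatives instead.
    """
    if not reps:
        raise ValueError("nothing to merge")
    if mode not in ("active", "all"):
        raise ValueError(f"unknown merge mode {mode!r}")
    stack = np.stack([r.freqs for r in reps])
    if mode == "all":
        return stack.mean(axis=0)
    active = stack > 0
    n_active = active.sum(axis=0)
    with np.errstate(invalid="ignore"):
        merged = np.where(n_active > 0, stack.sum(axis=0) / np.maximum(n_active, 1), 0.0)
    return merged


class BindingModeReconstructor(BaseEstimator):
    """Reconstruct compound-target interaction fingerprints from fragments.

    Parameters
    ----------
    compound_proportion, bm_conservation : float, default 0.6
        The two tunable reconstruction gates (compared with >=).
    mtis_floor : float, default 0.5
        Hard lower bound on the conservation score for a fragment-target
        pair to belong to the usable subset, applied even when
        ``bm_conservation`` is lower.
    mw_min, mw_max, min_compounds, min_targets, max_complexes :
        Fragment-set filter thresholds (see :class:`FilterConfig`).
    merge : {"active", "all"}, default "active"
        Bin-frequency averaging rule on the final merge.
    random_state : int, default 0
        Seed for the representative-complex selection of the 500-complex cap.

    Attributes (after ``fit``)
    --------------------------
    table_ : filtered fingerprint table (one row per fragment x complex)
    conservation_ : conservation records in the different-compounds /
        same-target context
    mtis_ : dict mapping (frag_inchikey, target_uniprot) -> mTIS
    n_fragments_fitted_ : number of distinct fragments surviving the filters
    """

    def __init__(
        self,
        compound_proportion: float = 0.6,
        bm_conservation: float = 0.6,
        mtis_floor: float = 0.5,
        mw_min: float = 40.0,
        mw_max: float = 300.0,
        min_compounds: int = 5,
        min_targets: int = 10,
        max_complexes: int = 500,
        merge: str = "active",
        random_state: int = 0,
    ):
        self.compound_proportion = compound_proportion
        self.bm_conservation = bm_conservation
        self.mtis_floor = mtis_floor
        self.mw_min = mw_min
        self.mw_max = mw_max
        self.min_compounds = min_compounds
        self.min_targets = min_targets
        self.max_complexes = max_complexes
        self.merge = merge
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            mw_min=self.mw_min,
            mw_max=self.mw_max,
            min_compounds=self.min_compounds,
            min_targets=self.min_targets,
            max_complexes=self.max_complexes,
            rng_seed=self.random_state,
        )

    def fit(self, X: Corpus | pd.DataFrame, y: None = None) -> "BindingModeReconstructor":
        """Learn fragment binding modes from a corpus.

        *X* is either a :class:`Corpus` or an already-built fingerprint
        table.  Thresholds are *not* baked in at fit time: the fitted state
        depends only on the filter configuration, so the same fit serves a
        whole threshold grid.
        """
        ReconstructionThresholds(self.compound_proportion, self.bm_conservation)
        if isinstance(X, Corpus):
            table = build_fingerprint_table(X)
            self.fragments_by_compound_ = {
                ck: tuple(dict.fromkeys(f.frag_inchikey for f in frags))
                for ck, frags in X.fragments.items()
            }
        else:
            table = X
            self.fragments_by_compound_ = {}
        self.table_ = filter_fragment_set(table, self.filter_config())
        cons = conservation_table(self.table_)
        self.conservation_ = cons[
            cons["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value
        ].reset_index(drop=True)
        self.mtis_ = {
            (r.frag_inchikey, r.target_uniprot): r.mtis
            for r in self.conservation_.itertuples()
        }
        self._pools = {}
        for (frag, target), sub in self.table_.groupby(
            ["frag_inchikey", "target_uniprot"], sort=True
        ):
            uids = sub["complex_uid"].tolist()
            arr = np.stack([fp.to_array().astype(float) for fp in sub["fingerprint"]])
            self._pools[(frag, target)] = (tuple(uids), arr)
        self.n_fragments_fitted_ = int(self.table_["frag_inchikey"].nunique())
        return self

    # -- reconstruction ----------------------------------------------------

    def usable_fragments(
        self, fragment_keys: Sequence[str], target_uniprot: str, exclude_uid: str | None = None
    ) -> tuple[list[str], list[str]]:
        """Split fragment identities into (with-data, usable) on a target."""
        gate = max(self.mtis_floor, self.bm_conservation)
        with_data: list[str] = []
        usable: list[str] = []
        for frag in fragment_keys:
            pool = self._pools.get((frag, target_uniprot))
            if pool is None:
                continue
            uids, _ = pool
            if all(u == exclude_uid for u in uids):
                continue
            with_data.append(frag)
            mtis = self.mtis_.get((frag, target_uniprot))
            if mtis is not None and mtis >= gate:
                usable.append(frag)
        return with_data, usable

    def representative(
        self, frag_inchikey: str, target_uniprot: str, exclude_uid: str | None = None
    ) -> RepresentativeFingerprint | None:
        pool = self._pools.get((frag_inchikey, target_uniprot))
        if pool is None:
            return None
        uids, arr = pool
        mask = np.array([u != exclude_uid for u in uids])
        if not mask.any():
            return None
        kept = arr[mask]
        return RepresentativeFingerprint(
            frag_inchikey=frag_inchikey,
            target_uniprot=target_uniprot,
            freqs=kept.sum(axis=0) / kept.shape[0],
            n_source_fps=int(kept.shape[0]),
            source_uids=tuple(u for u, m in zip(uids, mask) if m),
        )

    def reconstruct(
        self,
        compound_inchikey: str,
        target_uniprot: str,
        exclude_uid: str | None = None,
        fragment_keys: Sequence[str] | None = None,
    ) -> ReconstructionResult:
        """Reconstruct one compound-target pair.

        *fragment_keys* (distinct leaf InChIKeys) may be passed for compounds
        absent from the fitted corpus; otherwise they are looked up from it.
        *exclude_uid* removes one complex from every representative
        (leave-one-out validation).
        """
        if fragment_keys is None:
            fragment_keys = self.fragments_by_compound_.get(compound_inchikey, ())
        n_total = len(fragment_keys)
        if n_total == 0:
            raise ValueError(
                f"compound {compound_inchikey} has no leaf fragments: not reconstructable"
            )
        with_data, usable = self.usable_fragments(fragment_keys, target_uniprot, exclude_uid)

        def failed(status: ReconstructionStatus, frags: Sequence[str] = ()) -> ReconstructionResult:
            return ReconstructionResult(
                compound_inchikey=compound_inchikey,
                target_uniprot=target_uniprot,
                status=status,
                fingerprint=None,
                fragments_used=tuple(frags),
                proportion_achieved=compound_proportion(len(usable), n_total),
                n_total_fragments=n_total,
            )

        if not with_data:
            return failed(ReconstructionStatus.NO_FRAGMENT_DATA)
        if not usable:
            return failed(ReconstructionStatus.BELOW_CONSERVATION)
        proportion = compound_proportion(len(usable), n_total)
        if proportion < self.compound_proportion:
            return failed(ReconstructionStatus.BELOW_PROPORTION, usable)
        reps = [self.representative(f, target_uniprot, exclude_uid) for f in usable]
        reps = [r for r in reps if r is not None]
        merged = merge_fragment_fingerprints(reps, mode=self.merge)
        return ReconstructionResult(
            compound_inchikey=compound_inchikey,
            target_uniprot=target_uniprot,
            status=ReconstructionStatus.RECONSTRUCTED,
            fingerprint=merged,
            fragments_used=tuple(usable),
            proportion_achieved=proportion,
            n_total_fragments=n_total,
            source_uids=tuple(sorted({u for r in reps for u in r.source_uids})),
        )

    def predict(
        self, pairs: Iterable[tuple[str, str]] | pd.DataFrame
    ) -> list[ReconstructionResult]:
        """Reconstruct (compound_inchikey, target_uniprot) pairs."""
        if isinstance(pairs, pd.DataFrame):
            pairs = list(zip(pairs["compound_inchikey"], pairs["target_uniprot"]))
        return [self.reconstruct(c, t) for c, t in pairs]


def select_usable_fragments(
    compound_fragments: Sequence[str],
    target_uniprot: str,
    conservation: pd.DataFrame,
    thresholds: ReconstructionThresholds,
    mtis_floor: float = 0.5,
) -> list[str]:
    """Fragments of a compound usable for reconstruction on a target.

    Thin functional counterpart of the fitted estimator's gate: keeps
    fragments with a conservation record on this target whose mTIS passes
    max(mtis_floor, thresholds.bm_conservation).  *conservation* must hold
    the different-compounds/same-target context records.
    """
    gate = max(mtis_floor, thresholds.bm_conservation)
    sub = conservation[
        (conservation["context"] == Context.DIFF_COMPOUNDS_SAME_TARGET.value)
        & (conservation["target_uniprot"] == target_uniprot)
        & (conservation["mtis"] >= gate)
    ]
    usable = set(sub["frag_inchikey"])
    return [f for f in compound_fragments if f in usable]


def reconstruct(
    compound_inchikey: str,
    target_uniprot: str,
    corpus: Corpus,
    thresholds: ReconstructionThresholds = ReconstructionThresholds(),
    cfg: FilterConfig = FilterConfig(),
    exclude_uid: str | None = None,
    merge: str = "active",
) -> ReconstructionResult:
    """One-shot functional wrapper: fit on *corpus*, reconstruct one pair."""
    est = BindingModeReconstructor(
        compound_proportion=thresholds.compound_proportion,
        bm_conservation=thresholds.bm_conservation,
        mw_min=cfg.mw_min,
        mw_max=cfg.mw_max,
        min_compounds=cfg.min_compounds,
        min_targets=cfg.min_targets,
        max_complexes=cfg.max_complexes,
        merge=merge,
        random_state=cfg.rng_seed,
    ).fit(corpus)
    return est.reconstruct(compound_inchikey, target_uniprot, exclude_uid=exclude_uid)
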