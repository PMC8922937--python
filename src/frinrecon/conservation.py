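"""Binding-mode conservation of fragments: pairwise TIS and mean TIS.

The Tanimoto Interaction Similarity (TIS) of two complexes sharing a fragment
is the Jaccard index over activated fingerprint bins:

    TIS(C1, C2) = |C1 ∩ C2| / (|C1| + |C2| − |C1 ∩ C2|)

and a fragment's binding-mode conservation score (mTIS) is the mean of all
unordered pairwise TIS values within a grouping context:

* ``all_targets`` — every complex containing the fragment, across all
  compounds and targets;
* ``same_compound_diff_targets`` — complexes of one parent compound that
  binds at least two different targets;
* ``diff_compounds_same_target`` — complexes on one target contributed by at
  least two different parent compounds (the context the reconstruction
  pipeline consumes).

Targets are identified by UniProt accession, compounds by InChIKey.  Before
scoring, the fragment set is filtered: fragment-sized molecular weight
(40 < MW < 300 Da by default), at least 5 distinct parent compounds, at least
10 distinct targets, and a cap for over-represented fragments — a fragment
with more than 500 complexes is reduced to one seeded-randomly chosen
representative complex per (target, compound) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fingerprints import N_BINS, BinaryFingerprint

logger = logging.getLogger(__name__)


class Context(str, Enum):
    ALL_TARGETS = "all_targets"
    SAME_COMPOUND_DIFF_TARGETS = "same_compound_diff_targets"
    DIFF_COMPOUNDS_SAME_TARGET = "diff_compounds_same_target"


@dataclass(frozen=True)
class FilterConfig:
    """Fragment-set filter thresholds (strict MW window, inclusive minima)."""

    mw_min: float = 40.0
    mw_max: float = 300.0
    min_compounds: int = 5
    min_targets: int = 10
    max_complexes: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if min(self.min_compounds, self.min_targets, self.max_complexes) < 1:
            raise ValueError("count thresholds must be positive")


class TISStats(NamedTuple):
    min: float
    max: float
    mean: float


def tanimoto_similarity(fp1: BinaryFingerprint, fp2: BinaryFingerprint) -> float:
    """Jaccard index over activated bins; symmetric, in [0, 1].

    The degenerate empty-vs-empty case is defined as 0.0 and logged:
    complexes without interactions are removed upstream, so it only arises
    from pipeline misuse.
    """
    if not fp1.bins and not fp2.bins:
        logger.warning("TIS of two empty fingerprints: defined as 0.0")
        return 0.0
    inter = len(fp1.bins & fp2.bins)
    return inter / (len(fp1.bins) + len(fp2.bins) - inter)


def _pairwise_tis(fps: Sequence[BinaryFingerprint]) -> np.ndarray:
    """Condensed vector of TIS over all unordered pairs (self-pairs excluded)."""
    n = len(fps)
    arr = np.zeros((n, N_BINS), dtype=np.int32)
    for i, fp in enumerate(fps):
        arr[i] = fp.to_array()
    inter = arr @ arr.T
    pop = arr.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tis = np.where(union[iu] > 0, inter[iu] / np.maximum(union[iu], 1), 0.0)
    return tis


def mean_tis(fps: Sequence[BinaryFingerprint]) -> TISStats:
    """(min, max, mean) TIS over all n(n-1)/2 unordered fingerprint pairs.

    Fewer than two fingerprints leave conservation undefined — the fragment
    cannot be scored — signalled with ValueError.
    """
    if len(fps) < 2:
        raise ValueError("conservation undefined for fewer than 2 fingerprints")
    tis = _pairwise_tis(fps)
    return TISStats(float(tis.min()), float(tis.max()), float(tis.mean()))


def group_contexts(table: pd.DataFrame) -> pd.DataFrame:
    """Complex groups per fragment for each conservation context.

    Returns a DataFrame with columns ``frag_inchikey``, ``context``,
    ``target_uniprot`` (None except in the per-target context),
    ``group_key`` and ``complex_uids`` (sorted tuple).  Only groups with at
    least two complexes and satisfying the context's diversity requirement
    (>=2 targets for the same-compound context, >=2 compounds for the
    same-target context) are emitted.
    """
    out: list[dict] = []
    for frag, sub in table.groupby("frag_inchikey", sort=True):
        uids = tuple(sorted(sub["complex_uid"].unique()))
        if len(uids) >= 2:
            out.append(
                {
                    "frag_inchikey": frag,
                    "context": Context.ALL_TARGETS.value,
                    "target_uniprot": None,
                    "group_key": frag,
                    "complex_uids": uids,
                }
            )
        for compound, csub in sub.groupby("compound_inchikey", sort=True):
            cuids = tuple(sorted(csub["complex_uid"].unique()))
            if len(cuids) >= 2 and csub["target_uniprot"].nunique() >= 2:
                out.append(
                    {
                        "frag_inchikey": frag,
                        "context": Context.SAME_COMPOUND_DIFF_TARGETS.value,
                        "target_uniprot": None,
                        "group_key": f"{frag}|{compound}",
                        "complex_uids": cuids,
                    }
                )
        for target, tsub in sub.groupby("target_uniprot", sort=True):
            tuids = tuple(sorted(tsub["complex_uid"].unique()))
            if len(tuids) >= 2 and tsub["compound_inchikey"].nunique() >= 2:
                out.append(
                    {
                        "frag_inchikey": frag,
                        "context": Context.DIFF_COMPOUNDS_SAME_TARGET.value,
                        "target_uniprot": target,
                        "group_key": f"{frag}|{target}",
                        "complex_uids": tuids,
                    }
                )
    return pd.DataFrame(
        out, columns=["frag_inchikey", "context", "target_uniprot", "group_key", "complex_uids"]
    )


def filter_fragment_set(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Apply the fragment-set filters to a fingerprint table.

    Keeps fragments with cfg.mw_min < MW < cfg.mw_max, at least
    cfg.min_compounds distinct parent compounds and cfg.min_targets distinct
    targets; a fragment with more than cfg.max_complexes complexes is thinned
    to one seeded-randomly selected representative complex per
    (target UniProt, compound InChIKey) pair.  Deterministic given
    cfg.rng_seed, and idempotent.
    """
    if table.empty:
        return table.copy()
    t = table[(table["frag_mw"] > cfg.mw_min) & (table["frag_mw"] < cfg.mw_max)]
    stats = t.groupby("frag_inchikey").agg(
        n_compounds=("compound_inchikey", "nunique"),
        n_targets=("target_uniprot", "nunique"),
    )
    ok = stats[
        (stats["n_compounds"] >= cfg.min_compounds) & (stats["n_targets"] >= cfg.min_targets)
    ].index
    t = t[t["frag_inchikey"].isin(ok)]

    rng = np.random.default_rng(cfg.rng_seed)
    parts: list[pd.DataFrame] = []
    for frag, sub in t.groupby("frag_inchikey", sort=True):
        uids = sub["complex_uid"].unique()
        if len(uids) <= cfg.max_complexes:
            parts.append(sub)
            continue
        chosen: set[str] = set()
        for _, pair_sub in sub.groupby(["target_uniprot", "compound_inchikey"], sort=True):
            pair_uids = sorted(pair_sub["complex_uid"].unique())
            chosen.add(pair_uids[rng.integers(len(pair_uids))])
        parts.append(sub[sub["complex_uid"].isin(chosen)])
        logger.info(
            "fragment %s capped: %d complexes -> %d representatives", frag, len(uids), len(chosen)
        )
    if not parts:
        return t.iloc[0:0].copy()
    return pd.concat(parts, axis=0).sort_index()


def conservation_table(table: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-(fragment, context[, target]) conservation statistics.

    *table* is a fingerprint table (filtered first when *cfg* is given).
    Within each context the per-compound groups of the same-compound context
    are pooled into a single record per fragment, so the output is keyed by
    (frag_inchikey, context, target_uniprot) exactly.
    """
    if cfg is not None:
        table = filter_fragment_set(table, cfg)
    if table.empty:
        logger.warning("conservation_table: empty (filtered) fingerprint table")
        return pd.DataFrame(
            columns=["frag_inchikey", "context", "target_uniprot", "n_complexes", "min_tis", "max_tis", "mtis"]
        )
    fp_by = {
        (r.frag_inchikey, r.complex_uid): r.fingerprint
        for r in table.itertuples()
    }
    groups = group_contexts(table)
    records: list[dict] = []
    keyed: dict[tuple[str, str, str | None], list[float]] = {}
    n_cplx: dict[tuple[str, str, str | None], set[str]] = {}
    for g in groups.itertuples():
        fps = [fp_by[(g.frag_inchikey, uid)] for uid in g.complex_uids]
        tis = _pairwise_tis(fps)
        key = (g.frag_inchikey, g.context, g.target_uniprot)
        keyed.setdefault(key, []).extend(tis.tolist())
        n_cplx.setdefault(key, set()).update(g.complex_uids)
    for (frag, context, target), values in sorted(
        keyed.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] or "")
    ):
        arr = np.asarray(values)
        records.append(
            {
                "frag_inchikey": frag,
                "context": context,
                "target_uniprot": target,
                "n_complexes": len(n_cplx[(frag, context, target)]),
                "min_tis": float(arr.min()),
                "max_tis": float(arr.max()),
                "mtis": float(arr.mean()),
            }
        )
    return pd.DataFrame(
        records,
        columns=["frag_inchikey", "context", "target_uniprot", "n_complexes", "min_tis", "max_tis", "mtis"],
    )
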