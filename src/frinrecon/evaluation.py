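"""Leave-one-out validation of reconstructed binding modes.

Every complex in the corpus whose compound is fragmentable defines an
evaluation pair: its original compound-level fingerprint (all interaction
records, unrestricted) versus the fingerprint reconstructed for the same
compound-target pair *without* the complex's own structural data.  Pair
quality is the Tanimoto similarity over activated bins — a reconstructed bin
counts as activated when its frequency exceeds the activation cutoff
(default: any strictly positive frequency, since every reconstructed
frequency stems from a real observation) — and the Reconstruction Similarity
Score (RSS) of a threshold cell is the mean over its reconstructed pairs.

``run_validation_grid`` sweeps the (compound proportion x BM conservation)
threshold grid and reports, per cell, the number of reconstructed pairs and
their RSS; counts are checked to be non-increasing along both axes (tighter
gates can only lose pairs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import FilterConfig, tanimoto_similarity
from .corpus import Corpus
from .fingerprints import N_BINS, BinaryFingerprint
from .reconstruction import (
    BindingModeReconstructor,
    ReconstructionResult,
    ReconstructionStatus,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def binarize(freqs: np.ndarray, cutoff: float = 0.0) -> BinaryFingerprint:
    """Activated-bin fingerprint of a frequency vector (freq > cutoff)."""
    if freqs.shape != (N_BINS,):
        raise ValueError("frequency vector must have length 500")
    return BinaryFingerprint(int(b) + 1 for b in np.flatnonzero(freqs > cutoff))


def pair_similarity(
    original: BinaryFingerprint, reconstructed: np.ndarray, cutoff: float = 0.0
) -> float:
    """Tanimoto similarity between an original binary fingerprint and a
    reconstructed frequency fingerprint, over activated-bin sets."""
    return tanimoto_similarity(original, binarize(reconstructed, cutoff))


def rss(similarities: "list[float] | np.ndarray") -> float:
    """Mean of reconstructed-original pair similarities (undefined if empty)."""
    arr = np.asarray(similarities, dtype=float)
    if arr.size == 0:
        raise ValueError("RSS undefined for zero reconstructed pairs")
    return float(arr.mean())


@dataclass
class RSSReport:
    """Validation outcome of one threshold cell."""

    compound_proportion: float
    bm_conservation: float
    n_reconstructed: int
    rss: float | None
    per_pair: list[tuple[str, float]] = field(default_factory=list)
    n_failed: dict[str, int] = field(default_factory=dict)


@dataclass
class GridReport:
    grid: tuple[float, ...]
    cells: dict[tuple[float, float], RSSReport]
    per_pair_tables: dict[tuple[float, float], pd.DataFrame] = field(default_factory=dict)

    def counts_frame(self) -> pd.DataFrame:
        """Reconstructed-pair counts, proportion on rows, conservation on columns."""
        return pd.DataFrame(
            [[self.cells[(p, c)].n_reconstructed for c in self.grid] for p in self.grid],
            index=pd.Index(self.grid, name="compound_proportion"),
            columns=pd.Index(self.grid, name="bm_conservation"),
        )

    def rss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(p, c)].rss for c in self.grid] for p in self.grid],
            index=pd.Index(self.grid, name="compound_proportion"),
            columns=pd.Index(self.grid, name="bm_conservation"),
        )

    def check_monotonic(self) -> None:
        """Counts must be non-increasing along both threshold axes."""
        counts = self.counts_frame().to_numpy()
        if (np.diff(counts, axis=0) > 0).any() or (np.diff(counts, axis=1) > 0).any():
            raise AssertionError("reconstruction counts increase along a threshold axis")


def evaluation_pairs(corpus: Corpus) -> pd.DataFrame:
    """Evaluable (complex, compound, target) rows with original fingerprints."""
    fps = corpus.compound_fingerprints()
    fragmentable = {ck for ck, frags in corpus.fragments.items() if frags}
    return fps[fps["compound_inchikey"].isin(fragmentable)].reset_index(drop=True)


def run_validation_grid(
    corpus: Corpus,
    grid: tuple[float, ...] = DEFAULT_GRID,
    cfg: FilterConfig = FilterConfig(),
    merge: str = "active",
    activation_cutoff: float = 0.0,
    keep_tables: bool = False,
) -> GridReport:
    """Leave-one-out threshold-grid validation on a fingerprinted corpus.

    The corpus is fitted once (filters, conservation, fingerprint pools);
    each grid cell then re-runs only the gates and the leave-one-out
    representative construction.  Pairs that fail a gate in a cell are
    tallied per failure status and excluded from that cell's RSS.
    """
    est = BindingModeReconstructor(
        mw_min=cfg.mw_min,
        mw_max=cfg.mw_max,
        min_compounds=cfg.min_compounds,
        min_targets=cfg.min_targets,
        max_complexes=cfg.max_complexes,
        merge=merge,
        random_state=cfg.rng_seed,
    ).fit(corpus)
    pairs = evaluation_pairs(corpus)
    ligands = corpus.ligands
    cells: dict[tuple[float, float], RSSReport] = {}
    tables: dict[tuple[float, float], pd.DataFrame] = {}
    grid = tuple(grid)
    for p_thr, c_thr in itertools.product(grid, grid):
        est.set_params(compound_proportion=p_thr, bm_conservation=c_thr)
        sims: list[tuple[str, float]] = []
        failures: dict[str, int] = {}
        rows: list[dict] = []
        for row in pairs.itertuples():
            result: ReconstructionResult = est.reconstruct(
                row.compound_inchikey,
                row.target_uniprot,
                exclude_uid=row.complex_uid,
            )
            if result.status is not ReconstructionStatus.RECONSTRUCTED:
                failures[result.status.value] = failures.get(result.status.value, 0) + 1
                continue
            sim = pair_similarity(row.fingerprint, result.fingerprint, activation_cutoff)
            sims.append((row.complex_uid, sim))
            if keep_tables:
                lig = ligands.get(row.compound_inchikey)
                rows.append(
                    {
                        "complex_uid": row.complex_uid,
                        "smiles": lig.smiles if lig else "",
                        "target_uniprot": row.target_uniprot,
                        "mw": lig.mw if lig else float("nan"),
                        "original_fingerprint": row.fingerprint.to_string(),
                        "reconstructed_fingerprint": _sparse(result.fingerprint),
                        "fragments_used": ",".join(result.fragments_used),
                        "similarity": sim,
                    }
                )
        cells[(p_thr, c_thr)] = RSSReport(
            compound_proportion=p_thr,
            bm_conservation=c_thr,
            n_reconstructed=len(sims),
            rss=rss([s for _, s in sims]) if sims else None,
            per_pair=sims,
            n_failed=failures,
        )
        if keep_tables:
            tables[(p_thr, c_thr)] = pd.DataFrame(
                rows,
                columns=[
                    "complex_uid", "smiles", "target_uniprot", "mw",
                    "original_fingerprint", "reconstructed_fingerprint",
                    "fragments_used", "similarity",
                ],
            )
    report = GridReport(grid=grid, cells=cells, per_pair_tables=tables)
    report.check_monotonic()
    return report


def _sparse(freqs: np.ndarray) -> str:
    """bin:freq serialisation of a frequency fingerprint (active bins only)."""
    idx = np.flatnonzero(freqs > 0)
    return ";".join(f"{int(b) + 1}:{freqs[b]:.6g}" for b in idx)
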