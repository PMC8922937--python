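"""Run configuration, provenance stamping and logging.

A run is fully described by one JSON-serialisable :class:`RunConfig`; every
source of randomness flows from its single ``rng_seed`` and every output
table carries the configuration hash in its header, so the representative
selection of the 500-complex cap (and everything downstream) is auditable
and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import rdkit

from .conservation import FilterConfig
from .fingerprints import HASH_ALGORITHM
from .reconstruction import ReconstructionThresholds

DEFAULT_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class RunConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ReconstructionThresholds = field(default_factory=ReconstructionThresholds)
    grid: tuple[float, ...] = DEFAULT_GRID
    merge: str = "active"
    activation_cutoff: float = 0.0
    profile_dialect: str = "tsv"
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["versions"] = version_pins()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        """Header stamped into every output table."""
        return {"config_hash": self.config_hash, "seed": self.rng_seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("versions", None)
        filters = FilterConfig(**d.pop("filters", {}))
        thresholds = ReconstructionThresholds(**d.pop("thresholds", {}))
        grid = tuple(d.pop("grid", DEFAULT_GRID))
        return cls(filters=filters, thresholds=thresholds, grid=grid, **d)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self,
            rng_seed=seed,
            filters=dataclasses.replace(self.filters, rng_seed=seed),
        )


def version_pins() -> dict:
    """Library/algorithm versions a fingerprint or leaf set depends on."""
    from . import __version__

    return {
        "frinrecon": __version__,
        "rdkit": rdkit.__version__,
        "fingerprint_hash": HASH_ALGORITHM,
    }


def write_run_meta(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_meta.json").write_text(cfg.to_json() + "\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
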