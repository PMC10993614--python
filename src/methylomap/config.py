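"""Run configuration and provenance recording.

A single YAML file drives the CLI: input paths (probe set, reference betas,
annotations, superclass map, genome table), the analysis parameters, and
mode flags.  Validation enumerates *all* problems before any computation.
Every run writes a machine-readable provenance record (config hash, seed,
input checksums) so identical provenance implies identical numeric output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import DEFAULT_K, UmapParams
from .cnv import BIN_CLAMP, DEFAULT_MIN_MAPQ, TARGET_READS_PER_BIN
from .harmonize import DEFAULT_LLR_THRESHOLD

__all__ = ["RunConfig", "write_provenance"]


@dataclass
class RunConfig:
    """Validated configuration for CLI runs."""

    # paths
    manifest: str | None = None
    blacklist: str | None = None
    reference_betas: str | None = None
    annotations: str | None = None
    superclass_map: str | None = None
    genome_table: str | None = None
    # parameters
    seed: int = 0
    n_tdmp: int = 5000
    k: int = DEFAULT_K
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    llr_threshold: float = DEFAULT_LLR_THRESHOLD
    target_per_bin: int = TARGET_READS_PER_BIN
    clamp: tuple = BIN_CLAMP
    mapq_min: int = DEFAULT_MIN_MAPQ
    min_covered: int = 1000
    # mode flags
    strict: bool = False
    include_sex_chroms: bool = False
    tdmp_with_query: bool = False
    errors: list = field(default_factory=list, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "errors"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clamp" in raw:
            raw["clamp"] = tuple(raw["clamp"])
        return cls(**raw)

    def umap_params(self, n_tdmp=None) -> UmapParams:
        return UmapParams(
            seed=self.seed,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            metric=self.metric,
            n_tdmp=self.n_tdmp if n_tdmp is None else n_tdmp,
        )

    def validate(self, require=()) -> list:
        """Collect every validation failure; raise only at the end."""
        problems = []
        for name in require:
            if getattr(self, name) is None:
                problems.append(f"required path {name!r} not configured")
        for name in (
            "manifest", "blacklist", "reference_betas", "annotations",
            "superclass_map", "genome_table",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: path does not exist: {p}")
        if self.k < 1:
            problems.append("k must be >= 1")
        if self.n_tdmp < 1:
            problems.append("n_tdmp must be >= 1")
        if self.llr_threshold <= 0:
            problems.append("llr_threshold must be positive")
        if self.target_per_bin < 1:
            problems.append("target_per_bin must be >= 1")
        if not (0 < self.clamp[0] <= self.clamp[1]):
            problems.append("clamp must satisfy 0 < lower <= upper")
        if self.mapq_min < 0:
            problems.append("mapq_min must be >= 0")
        self.errors = problems
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
        return problems

    def content_hash(self) -> str:
        d = asdict(self)
        d.pop("errors", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_provenance(config: RunConfig, inputs, out_path):
    """Record config hash, seed, and input checksums for reproducibility."""
    record = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "inputs": {str(p): _file_checksum(p) for p in inputs if p and Path(p).exists()},
    }
    Path(out_path).write_text(json.dumps(record, indent=1, sort_keys=True))
    return record
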