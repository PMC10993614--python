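"""Harmonized overlap-CpG probe space and compact binary beta storage.

Methylation measurements from Illumina 450K/EPIC arrays, targeted methylation
sequencing and nanopore sequencing are comparable only on the CpG sites shared
by all platforms ("overlap CpGs", oCpGs).  A :class:`ProbeSet` pins down that
shared feature space: an ordered, sex-chromosome-depleted, blacklist-filtered
list of probes with genomic coordinates.  Every beta vector or matrix in the
package is aligned to one ProbeSet, and per-sample vectors are persisted as
raw little-endian float32 payloads (4 bytes per probe, no embedded header) so
that large reference cohorts load at disk bandwidth.

Uncovered probes carry the neutral sentinel value ``FILL_VALUE == 0.49``,
chosen to sit just off the midpoint so filled positions are distinguishable
from genuinely hemi-methylated sites while remaining uninformative for
variance-based probe ranking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FILL_VALUE",
    "CHROMOSOMES",
    "SEX_CHROMOSOMES",
    "ProbeSet",
    "BetaVector",
    "BetaMatrix",
    "build_probeset",
    "save_betas",
    "load_betas",
]

#: Neutral fill used for probes a platform did not cover.
FILL_VALUE = 0.49

#: Declared chromosome vocabulary, in canonical genome order.
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name into the ``chr1``..``chrY`` vocabulary.

    Bare ensembl-style names (``1``..``22``, ``X``, ``Y``) get the ``chr``
    prefix.  Unknown names raise ``ValueError``.
    """
    c = str(chrom)
    if not c.startswith("chr"):
        c = "chr" + c
    if c not in _CHROM_RANK:
        raise ValueError(f"chromosome {chrom!r} not in declared vocabulary")
    return c


@dataclass(frozen=True)
class ProbeSet:
    """Ordered, filtered overlap-CpG index with genomic coordinates.

    Probes are unique, autosomal, non-blacklisted, and sorted by
    (chromosome order, position).  The order is canonical: every
    :class:`BetaVector`/:class:`BetaMatrix` referencing this set stores values
    in exactly this order.
    """

    probe_ids: tuple
    chroms: tuple
    positions: tuple
    version_tag: str = ""

    # lazily built lookup tables
    _index_of: dict = field(default_factory=dict, repr=False, compare=False)
    _pos_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.probe_ids) != len(set(self.probe_ids)):
            raise ValueError("duplicate probe ids in ProbeSet")
        for c in set(self.chroms):
            if c in SEX_CHROMOSOMES:
                raise ValueError("ProbeSet must not contain sex-chromosome probes")
            if c not in _CHROM_RANK:
                raise ValueError(f"chromosome {c!r} outside declared vocabulary")
        if any(p <= 0 for p in self.positions):
            raise ValueError("probe positions must be positive 1-based integers")
        object.__setattr__(
            self, "_index_of", {p: i for i, p in enumerate(self.probe_ids)}
        )
        object.__setattr__(
            self,
            "_pos_index",
            {(c, p): i for i, (c, p) in enumerate(zip(self.chroms, self.positions))},
        )
        if not self.version_tag:
            h = hashlib.md5(("\n".join(self.probe_ids)).encode()).hexdigest()[:12]
            object.__setattr__(self, "version_tag", f"probeset-{len(self)}-{h}")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def index_of(self, probe_id: str) -> int:
        return self._index_of[probe_id]

    def index_at(self, chrom: str, pos: int):
        """Probe index at a 1-based genomic coordinate, or None."""
        return self._pos_index.get((chrom, int(pos)))

    def __contains__(self, probe_id) -> bool:
        return probe_id in self._index_of


@dataclass
class BetaVector:
    """One sample's methylation fractions aligned to a ProbeSet.

    ``fill_mask`` flags positions that were neutral-filled (value exactly
    ``FILL_VALUE``) rather than measured.
    """

    sample_id: str
    values: np.ndarray
    fill_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("BetaVector values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite beta values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.fill_mask is not None:
            self.fill_mask = np.asarray(self.fill_mask, dtype=bool)
            if self.fill_mask.shape != self.values.shape:
                raise ValueError("fill_mask shape mismatch")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class BetaMatrix:
    """Samples x probes methylation fractions aligned to a ProbeSet."""

    sample_ids: list
    matrix: np.ndarray
    probeset: ProbeSet
    fill_mask: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("BetaMatrix must be two-dimensional")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.matrix.shape[1] != len(self.probeset):
            raise ValueError("column count does not match ProbeSet size")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def row(self, sample_id: str) -> BetaVector:
        i = self.sample_ids.index(sample_id)
        mask = self.fill_mask[i] if self.fill_mask is not None else None
        return BetaVector(sample_id, self.matrix[i].copy(), mask)


def build_probeset(
    manifest_records: Iterable[tuple],
    blacklist: Iterable[str] = (),
    platforms: Sequence[Iterable[str]] | None = None,
    version_tag: str = "",
) -> ProbeSet:
    """Build the harmonized probe space from manifest records.

    Parameters
    ----------
    manifest_records
        Iterable of ``(probe_id, chrom, pos)`` with 1-based positions.
    blacklist
        Probe ids to exclude (cross-reactive / polymorphic probes).
    platforms
        Optional per-platform probe-id collections; when given, only probes
        present on *every* platform (the overlap set) are kept.

    The result is deterministic: probes sorted by (chromosome order,
    position), independent of manifest input order.
    """
    records = list(manifest_records)
    if not records:
        raise ValueError("manifest is empty")
    seen = set()
    parsed = []
    for probe_id, chrom, pos in records:
        if probe_id in seen:
            raise ValueError(f"duplicate probe_id {probe_id!r} in manifest")
        seen.add(probe_id)
        parsed.append((str(probe_id), normalize_chrom(chrom), int(pos)))

    keep = seen
    if platforms:
        for plat in platforms:
            keep = keep & set(plat)
    black = set(blacklist)

    kept = [
        rec
        for rec in parsed
        if rec[0] in keep and rec[0] not in black and rec[1] not in SEX_CHROMOSOMES
    ]
    if not kept:
        raise ValueError(
            "no probes survive filtering: platform sets, blacklist and "
            "sex-chromosome removal left an empty overlap set"
        )
    kept.sort(key=lambda r: (_CHROM_RANK[r[1]], r[2], r[0]))
    ids, chroms, poss = zip(*kept)
    return ProbeSet(ids, chroms, poss, version_tag=version_tag)


def save_betas(vector: BetaVector, destination, probeset: ProbeSet | None = None):
    """Persist a BetaVector as a raw little-endian float32 payload.

    Layout: one ``<f4`` per probe in ProbeSet order, no embedded header;
    file size is exactly ``4 * n_probes`` bytes.  A JSON sidecar
    (``<destination>.meta.json``) records sample id, probeset version tag and
    the indices of neutral-filled positions.
    """
    destination = Path(destination)
    if probeset is not None and len(vector) != len(probeset):
        raise ValueError(
            f"vector length {len(vector)} does not match ProbeSet size {len(probeset)}"
        )
    payload = np.asarray(vector.values, dtype="<f4").tobytes()
    destination.write_bytes(payload)
    meta = {
        "sample_id": vector.sample_id,
        "probeset_version": probeset.version_tag if probeset is not None else "",
        "n_probes": len(vector),
        "dtype": "<f4",
        "fill_value": FILL_VALUE,
        "fill_indices": (
            np.nonzero(vector.fill_mask)[0].tolist()
            if vector.fill_mask is not None
            else []
        ),
    }
    sidecar = destination.with_name(destination.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return destination


def load_betas(source, probeset: ProbeSet) -> BetaVector:
    """Load a binary beta payload aligned to ``probeset``.

    Raises if the payload size disagrees with the ProbeSet (wrong probeset
    version), contains non-finite values (corrupt file), or values outside
    [0, 1].
    """
    source = Path(source)
    payload = source.read_bytes()
    expected = 4 * len(probeset)
    if len(payload) != expected:
        raise ValueError(
            f"payload size mismatch for {source.name}: expected {expected} bytes "
            f"({len(probeset)} probes x 4), got {len(payload)} — wrong probeset version?"
        )
    values = np.frombuffer(payload, dtype="<f4").astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"corrupt beta file {source.name}: non-finite values")
    if values.min() < 0 or values.max() > 1:
        raise ValueError(f"beta values outside [0, 1] in {source.name}")

    sample_id = source.stem
    fill_mask = None
    sidecar = source.with_name(source.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sample_id = meta.get("sample_id", sample_id)
        idx = meta.get("fill_indices", [])
        if idx:
            fill_mask = np.zeros(values.size, dtype=bool)
            fill_mask[np.asarray(idx, dtype=int)] = True
    return BetaVector(sample_id, values, fill_mask)
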