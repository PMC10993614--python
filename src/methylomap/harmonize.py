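"""Project sequencing-based methylation measurements onto the probe space.

Two sequencing routes feed the classifier:

* **Targeted methylation sequencing** (MethylDackel-style bedGraph with
  methylated ``#M`` and unmethylated ``#N`` read counts per CpG).  The
  methylation fraction is recomputed at full precision as ``#M / (#M + #N)``;
  probes the panel does not cover receive the neutral 0.49 fill so the vector
  stays comparable to array references.
* **Nanopore per-site calls** (f5c/nanopolish-style log-likelihood ratios).
  Shallow whole-genome runs cover only a few thousand overlap CpGs, so this
  path produces a *sparse* vector over the confidently-called probes; the
  reference matrix is later subset to those columns instead of filling.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probe_store import (
    FILL_VALUE,
    BetaMatrix,
    BetaVector,
    ProbeSet,
    normalize_chrom,
)

__all__ = [
    "BedGraphRecord",
    "SiteCall",
    "SparseBetaVector",
    "LoadReport",
    "DEFAULT_LLR_THRESHOLD",
    "bedgraph_to_betas",
    "nanopore_calls_to_betas",
    "read_beta_table",
]

logger = logging.getLogger(__name__)

#: Default confidence gate on |log-likelihood ratio| for nanopore calls
#: (community convention for nanopolish/f5c call filtering).
DEFAULT_LLR_THRESHOLD = 2.5


@dataclass(frozen=True)
class BedGraphRecord:
    """One CpG row of a MethylDackel-dialect bedGraph.

    ``start`` is 0-based, ``end`` exclusive; ``ratio_rounded`` is the
    percentage the caller printed (discarded here — the fraction is
    recomputed from the counts).
    """

    chrom: str
    start: int
    end: int
    ratio_rounded: float
    m_count: int
    u_count: int

    def __post_init__(self):
        if self.m_count < 0 or self.u_count < 0:
            raise ValueError(
                f"negative counts in bedGraph record {self.chrom}:{self.start}"
            )


@dataclass(frozen=True)
class SiteCall:
    """A per-site (or per-read) nanopore methylation call."""

    chrom: str
    pos: int  # 1-based CpG position
    llr: float
    n_reads: int = 1

    def __post_init__(self):
        if self.n_reads < 1:
            raise ValueError("SiteCall.n_reads must be >= 1")


@dataclass
class SparseBetaVector:
    """Methylation fractions on the covered probe subset only."""

    sample_id: str
    entries: dict  # probe index -> fraction in [0, 1]

    def __post_init__(self):
        for idx, v in self.entries.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fraction {v} at probe index {idx} outside [0, 1]")

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(sorted(self.entries), dtype=int)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LoadReport:
    """Ingestion accounting: how records mapped onto the ProbeSet."""

    n_records: int = 0
    n_matched: int = 0
    n_unmatched: int = 0
    n_covered_probes: int = 0
    n_filled_probes: int = 0
    used_strand_fallback: bool = False
    warnings: list = field(default_factory=list)


def _match_records(records, probeset: ProbeSet, strand_merge: str):
    """Map bedGraph records to probe indices; returns per-probe count pairs.

    A record matches the probe at 1-based position ``start + 1``.  When strict
    matching assigns fewer than half the records, the reverse-strand offset
    (record at the CpG's G, ``start == pos``) is additionally tried — CpG
    methylation is symmetric, so both offsets report the same site.
    """
    strict_hits = []
    for rec in records:
        chrom = normalize_chrom(rec.chrom)
        idx = probeset.index_at(chrom, rec.start + 1)
        strict_hits.append(idx)

    n_strict = sum(i is not None for i in strict_hits)
    fallback = n_strict < 0.5 * len(records)
    counts: dict = {}
    n_matched = 0
    for rec, idx in zip(records, strict_hits):
        if idx is None and fallback:
            idx = probeset.index_at(normalize_chrom(rec.chrom), rec.start)
        if idx is None:
            continue
        n_matched += 1
        if idx in counts:
            if strand_merge == "sum":
                m, u = counts[idx]
                counts[idx] = (m + rec.m_count, u + rec.u_count)
            # "first": keep the existing pair
        else:
            counts[idx] = (rec.m_count, rec.u_count)
    return counts, n_matched, fallback


def bedgraph_to_betas(
    records,
    probeset: ProbeSet,
    sample_id: str = "methylseq",
    strand_merge: str = "sum",
    return_report: bool = False,
):
    """Convert bedGraph count records into a dense, fill-completed BetaVector.

    For each probe matched by position the value is the recomputed fraction
    ``#M / (#M + #N)``.  Probes with no matching record, or a zero total
    count, receive exactly ``FILL_VALUE`` (0.49) and are flagged in
    ``fill_mask``.  Records matching no probe are ignored but counted in the
    :class:`LoadReport`.

    Duplicate records at one position (strand-split bedGraph dialects) have
    their counts summed before the ratio by default (``strand_merge="sum"``);
    ``"first"`` keeps the first record seen.
    """
    if strand_merge not in ("sum", "first"):
        raise ValueError("strand_merge must be 'sum' or 'first'")
    records = list(records)
    report = LoadReport(n_records=len(records))
    values = np.full(len(probeset), FILL_VALUE, dtype=np.float64)
    fill_mask = np.ones(len(probeset), dtype=bool)

    if records:
        counts, n_matched, fallback = _match_records(records, probeset, strand_merge)
        report.n_matched = n_matched
        report.n_unmatched = len(records) - n_matched
        report.used_strand_fallback = fallback
        for idx, (m, u) in counts.items():
            total = m + u
            if total == 0:
                continue  # stays neutral-filled
            values[idx] = m / total
            fill_mask[idx] = False

    report.n_covered_probes = int((~fill_mask).sum())
    report.n_filled_probes = int(fill_mask.sum())
    if report.n_unmatched:
        logger.info(
            "%d/%d bedGraph records matched no probe", report.n_unmatched, len(records)
        )
    vector = BetaVector(sample_id, values, fill_mask)
    return (vector, report) if return_report else vector


def nanopore_calls_to_betas(
    calls,
    probeset: ProbeSet,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
    sample_id: str = "nanopore",
) -> SparseBetaVector:
    """Aggregate per-site nanopore calls into a sparse beta vector.

    Only probes with at least one confident call (``|llr| >= llr_threshold``)
    appear; the per-probe value is the fraction of methylated calls
    (``llr > 0``) among confident calls.  Probes whose every call fails the
    gate are absent — the nanopore path subsets the reference to the covered
    probes instead of neutral-filling.
    """
    if llr_threshold <= 0:
        raise ValueError("llr_threshold must be positive")
    meth: dict = {}
    tot: dict = {}
    any_matched = False
    for call in calls:
        idx = probeset.index_at(normalize_chrom(call.chrom), call.pos)
        if idx is None:
            continue
        any_matched = True
        if abs(call.llr) < llr_threshold:
            continue
        tot[idx] = tot.get(idx, 0) + 1
        if call.llr > 0:
            meth[idx] = meth.get(idx, 0) + 1
    if not any_matched:
        raise ValueError(
            "no nanopore calls matched any probe — genome build or "
            "coordinate convention mismatch?"
        )
    entries = {idx: meth.get(idx, 0) / n for idx, n in tot.items()}
    return SparseBetaVector(sample_id, entries)


def read_beta_table(table_source, probeset: ProbeSet) -> BetaMatrix:
    """Read a samples x probes beta table (TSV/CSV, probe ids as header).

    The matrix is re-aligned to ProbeSet order regardless of column order in
    the file.  Missing cells receive the 0.49 neutral fill (flagged in
    ``fill_mask``); columns naming unknown probes are ignored with a logged
    count.  Non-numeric cells raise, naming the offending row and column.
    """
    if isinstance(table_source, (str, Path)):
        sep = "," if str(table_source).endswith(".csv") else "\t"
        df = pd.read_csv(table_source, sep=sep, index_col=0, dtype=str)
    elif isinstance(table_source, _io.IOBase):
        df = pd.read_csv(table_source, sep="\t", index_col=0, dtype=str)
    else:
        df = pd.DataFrame(table_source).astype(str)

    known = [c for c in df.columns if c in probeset]
    unknown = len(df.columns) - len(known)
    if not known:
        raise ValueError("no table columns overlap the ProbeSet probe ids")
    if unknown:
        logger.warning("%d unknown probe columns ignored", unknown)

    n, p = df.shape[0], len(probeset)
    matrix = np.full((n, p), FILL_VALUE, dtype=np.float64)
    fill_mask = np.ones((n, p), dtype=bool)
    for col in known:
        j = probeset.index_of(col)
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"non-numeric beta value at row {row!r}, column {col!r}")
        present = numeric.notna()
        matrix[present.to_numpy(), j] = numeric[present].to_numpy()
        fill_mask[present.to_numpy(), j] = False
    return BetaMatrix(list(df.index), matrix, probeset, fill_mask)
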