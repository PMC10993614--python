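"""Readers and writers for the plain-text interchange formats.

Every format the synthetic generators emit is read back through these
functions, so the parsers are exercised by the package's own output:
probe manifests and blacklists, beta tables, MethylDackel-dialect bedGraph,
per-site nanopore call tables, annotation and superclass TSVs, BED read
positions and UCSC chrom.sizes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import AnnotationTable
from .cnv import ReadPosition
from .harmonize import BedGraphRecord, SiteCall
from .probe_store import BetaMatrix, ProbeSet

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_blacklist",
    "read_annotations",
    "write_annotations",
    "read_superclass_map",
    "write_superclass_map",
    "write_beta_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_site_calls",
    "write_site_calls",
    "write_reads_bed",
    "write_chrom_sizes",
]


def read_manifest(path) -> list:
    """Probe manifest TSV: columns probe_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return list(df[["probe_id", "chrom", "pos"]].itertuples(index=False, name=None))


def write_manifest(probeset: ProbeSet, path):
    pd.DataFrame(
        {
            "probe_id": probeset.probe_ids,
            "chrom": probeset.chroms,
            "pos": probeset.positions,
        }
    ).to_csv(path, sep="\t", index=False)


def read_blacklist(path) -> set:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_annotations(path) -> dict:
    """Annotation TSV: sample_id, mc."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "mc"}.issubset(df.columns):
        raise ValueError("annotation table must have columns sample_id, mc")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in annotation table: {dup}")
    return dict(zip(df["sample_id"], df["mc"]))


def write_annotations(mc_of: dict, path):
    pd.DataFrame(
        {"sample_id": list(mc_of), "mc": [mc_of[s] for s in mc_of]}
    ).to_csv(path, sep="\t", index=False)


def read_superclass_map(path) -> dict:
    """Superclass TSV: mc, sc (each MC at most once)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mc", "sc"}.issubset(df.columns):
        raise ValueError("superclass map must have columns mc, sc")
    if df["mc"].duplicated().any():
        raise ValueError("an MC appears more than once in the superclass map")
    return dict(zip(df["mc"], df["sc"]))


def write_superclass_map(sc_of: dict, path):
    pd.DataFrame({"mc": list(sc_of), "sc": [sc_of[m] for m in sc_of]}).to_csv(
        path, sep="\t", index=False
    )


def load_annotation_table(annotation_path, superclass_path=None) -> AnnotationTable:
    sc_of = read_superclass_map(superclass_path) if superclass_path else {}
    return AnnotationTable(read_annotations(annotation_path), sc_of)


def write_beta_table(matrix: BetaMatrix, path):
    """Samples x probes beta table with probe-id header (TSV or CSV)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.DataFrame(
        matrix.matrix, index=matrix.sample_ids, columns=matrix.probeset.probe_ids
    )
    df.to_csv(path, sep=sep, float_format="%.6f")


def read_bedgraph(path) -> list:
    """MethylDackel-dialect bedGraph: chrom start end ratio #M #N."""
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"bedGraph line {ln}: expected 6 columns, got {len(parts)}")
        chrom, start, end, ratio, m, u = parts[:6]
        records.append(
            BedGraphRecord(chrom, int(start), int(end), float(ratio), int(m), int(u))
        )
    return records


def write_bedgraph(records, path):
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.ratio_rounded:g}\t"
                f"{r.m_count}\t{r.u_count}\n"
            )


def read_site_calls(path) -> list:
    """Per-site call TSV: chrom, pos (1-based), llr, n_reads."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"chrom", "pos", "llr"}
    if not required.issubset(df.columns):
        raise ValueError(f"call table must have columns {sorted(required)}")
    n_reads = df["n_reads"] if "n_reads" in df.columns else np.ones(len(df), dtype=int)
    return [
        SiteCall(str(c), int(p), float(l), int(n))
        for c, p, l, n in zip(df["chrom"], df["pos"], df["llr"], n_reads)
    ]


def write_site_calls(calls, path):
    pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "llr": [c.llr for c in calls],
            "n_reads": [c.n_reads for c in calls],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_reads_bed(reads, path, read_length: int = 5000):
    """3-column BED of read start positions."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.start + read_length}\n")


def write_chrom_sizes(genome, path):
    with open(path, "w") as fh:
        for chrom, length in zip(genome.chroms, genome.lengths):
            fh.write(f"{chrom}\t{length}\n")
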