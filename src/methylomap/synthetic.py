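"""Synthetic fixture generators for every input the pipeline consumes.

All generators are pure functions of (spec, seed): fixed seed means
bit-identical output.  They emulate the statistical shape of real inputs —
bimodal array betas with entity-specific clusters, structureless degraded-DNA
profiles, binomial count noise in targeted sequencing panels, confident/weak
nanopore calls, and read densities scaled by local copy number — without
modelling read lengths, sequencing error profiles or bisulfite chemistry.

Methylation arrays are empirically bimodal (most CpGs near 0 or 1), so class
centroids are drawn from a two-component beta mixture: "low" probes from
Beta(2, 10), "high" probes from Beta(10, 2).  A configurable fraction of
probes is *discriminative*: the low/high state is re-drawn per class, giving
classes distinct centroids on those probes while the rest form a shared
backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import DNADEG_LABEL, AnnotationTable
from .cnv import GenomeTable, ReadPosition
from .harmonize import BedGraphRecord, SiteCall
from .probe_store import BetaMatrix, BetaVector, ProbeSet, build_probeset

__all__ = [
    "CohortSpec",
    "CnvSpec",
    "synthetic_probeset",
    "gen_cohort",
    "gen_dnadeg",
    "gen_reads",
    "gen_bedgraph",
    "gen_nanopore_calls",
    "make_superclass_map",
]

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a class-structured synthetic methylation cohort.

    Defaults give eight well-separated tumour-like classes of twenty samples
    each: 30% of probes discriminative, per-sample Gaussian noise with
    sd 0.05 around the class centroid (clipped to [0, 1]).
    """

    n_classes: int = 8
    samples_per_class: int = 20
    n_probes: int = 2000
    discriminative_fraction: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_probes < 1 or self.samples_per_class < 1:
            raise ValueError("degenerate cohort spec: zero classes/samples/probes")
        if not (0 < self.discriminative_fraction <= 1):
            raise ValueError("discriminative_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CnvSpec:
    """A read-sampling scenario: genome plus copy-altered segments.

    ``segments`` are ``(chrom, start, end, copy_ratio)``; read density is
    proportional to the local ratio (1.0 outside segments).
    """

    genome: GenomeTable
    n_reads: int
    segments: tuple = ()

    def __post_init__(self):
        for chrom, start, end, ratio in self.segments:
            if ratio <= 0:
                raise ValueError("copy_ratio must be positive")
            if chrom not in self.genome:
                raise ValueError(f"segment chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= self.genome.length_of(chrom)):
                raise ValueError(f"segment out of bounds on {chrom}")


def synthetic_probeset(n_probes: int, seed: int = 0) -> ProbeSet:
    """A small autosomal manifest: probes spread across chr1..chr22."""
    rng = np.random.default_rng(seed)
    chroms = rng.choice(len(_AUTOSOMES), size=n_probes)
    offsets = rng.integers(1, 10_000_000, size=n_probes)
    records = []
    per_chrom_count: dict = {}
    for i in range(n_probes):
        chrom = _AUTOSOMES[chroms[i]]
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        # strictly increasing positions per chromosome: unique coordinates
        pos = (k + 1) * 10_000_000 + int(offsets[i]) % 9_000_000
        records.append((f"cgS{i:06d}", chrom, pos))
    return build_probeset(records, version_tag=f"synthetic-{n_probes}-{seed}")


def _class_centroids(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n_disc = int(round(spec.discriminative_fraction * spec.n_probes))
    disc = rng.choice(spec.n_probes, size=n_disc, replace=False)

    def draw(high_state: np.ndarray) -> np.ndarray:
        low = rng.beta(2, 10, size=high_state.shape)
        high = rng.beta(10, 2, size=high_state.shape)
        return np.where(high_state, high, low)

    backbone = draw(rng.random(spec.n_probes) < 0.5)
    centroids = np.tile(backbone, (spec.n_classes, 1))
    for c in range(spec.n_classes):
        centroids[c, disc] = draw(rng.random(n_disc) < 0.5)
    return centroids


def gen_cohort(spec: CohortSpec):
    """Generate (BetaMatrix, AnnotationTable, ProbeSet) for a class cohort.

    Sample ids are ``MC_<class>_s<index>``; the annotation assigns each
    sample its generating class ``MC_<class>``.
    """
    rng = np.random.default_rng(spec.seed)
    probeset = synthetic_probeset(spec.n_probes, seed=spec.seed)
    centroids = _class_centroids(spec, rng)

    sample_ids, rows, mc_of = [], [], {}
    for c in range(spec.n_classes):
        label = f"MC_{c:02d}"
        for s in range(spec.samples_per_class):
            sid = f"{label}_s{s:02d}"
            betas = np.clip(
                centroids[c] + rng.normal(0, spec.noise_sd, spec.n_probes), 0, 1
            )
            sample_ids.append(sid)
            rows.append(betas)
            mc_of[sid] = label
    matrix = BetaMatrix(sample_ids, np.vstack(rows), probeset)
    return matrix, AnnotationTable(mc_of), probeset


def gen_queries(spec: CohortSpec, n_per_class: int, seed: int):
    """Held-out query samples: fresh noise draws around the cohort centroids.

    Re-derives the class centroids deterministically from ``spec`` (so the
    queries come from the same population as :func:`gen_cohort`'s reference)
    and draws ``n_per_class`` new samples per class with noise seeded by
    ``seed``.  Returns ``(query_vectors, truths)`` where ``truths`` maps
    query id to its generating class.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = _class_centroids(spec, rng)
    qrng = np.random.default_rng(seed)
    queries, truths = [], {}
    for c in range(spec.n_classes):
        label = f"MC_{c:02d}"
        for s in range(n_per_class):
            sid = f"query_{label}_q{s:02d}"
            betas = np.clip(
                centroids[c] + qrng.normal(0, spec.noise_sd, spec.n_probes), 0, 1
            )
            queries.append(BetaVector(sid, betas))
            truths[sid] = label
    return queries, truths


def gen_dnadeg(
    n: int,
    n_probes: int | None = None,
    seed: int = 0,
    probeset: ProbeSet | None = None,
) -> BetaMatrix:
    """Structureless degraded-DNA profiles: heavy uniform noise around 0.5.

    Such samples lack the bimodal class structure entirely; in a joint
    embedding they cluster with each other and apart from tumour classes,
    emulating the DNADEG artefact class.  Pass ``probeset`` to align with an
    existing cohort, or ``n_probes`` to build a fresh one.
    """
    if probeset is None:
        if n_probes is None:
            raise ValueError("give either probeset or n_probes")
        probeset = synthetic_probeset(n_probes, seed=seed)
    rng = np.random.default_rng(seed + 7)
    matrix = rng.uniform(0.02, 0.98, size=(n, len(probeset)))
    ids = [f"{DNADEG_LABEL}_s{i:02d}" for i in range(n)]
    return BetaMatrix(ids, matrix, probeset)


def gen_reads(spec: CnvSpec, seed: int = 0) -> list:
    """Sample aligned read starts with density scaled by local copy ratio.

    The genome is partitioned into constant-ratio intervals; intervals are
    drawn with probability proportional to ``ratio * width`` and positions
    uniformly within.  Exactly ``spec.n_reads`` reads are returned.
    """
    rng = np.random.default_rng(seed)
    intervals = []  # (chrom, start, end, ratio)
    for chrom, length in zip(spec.genome.chroms, spec.genome.lengths):
        cuts = {0, length}
        segs = [s for s in spec.segments if s[0] == chrom]
        for _c, start, end, _r in segs:
            cuts.update((start, end))
        edges = sorted(cuts)
        for a, b in zip(edges[:-1], edges[1:]):
            ratio = 1.0
            for _c, start, end, r in segs:
                if start <= a and b <= end:
                    ratio = r
                    break
            intervals.append((chrom, a, b, ratio))

    weights = np.asarray([(b - a) * r for _c, a, b, r in intervals], dtype=np.float64)
    weights /= weights.sum()
    choice = rng.choice(len(intervals), size=spec.n_reads, p=weights)
    reads = []
    for i in choice:
        chrom, a, b, _r = intervals[i]
        reads.append(ReadPosition(chrom, int(rng.integers(a, b))))
    return reads


def gen_bedgraph(
    betas: BetaVector,
    probeset: ProbeSet,
    mean_depth: float = 30,
    coverage_fraction: float = 1.0,
    seed: int = 0,
) -> list:
    """Emit bedGraph count records emulating a targeted methylation panel.

    Exactly ``round(coverage_fraction * n_probes)`` probes are covered (a
    seeded random subset); per covered probe the read depth is
    Poisson(``mean_depth``) clipped to >= 1 and the methylated count is
    Binomial(depth, beta).  Records are genome-ordered, 0-based half-open.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    if len(betas) != len(probeset):
        raise ValueError("beta vector not aligned to probeset")
    rng = np.random.default_rng(seed)
    n_cov = int(round(coverage_fraction * len(probeset)))
    covered = np.sort(rng.choice(len(probeset), size=n_cov, replace=False))
    depths = np.maximum(1, rng.poisson(mean_depth, size=n_cov))
    records = []
    for idx, depth in zip(covered, depths):
        beta = betas.values[idx]
        m = int(rng.binomial(depth, beta))
        u = int(depth) - m
        pos = probeset.positions[idx]
        records.append(
            BedGraphRecord(
                chrom=probeset.chroms[idx],
                start=pos - 1,
                end=pos,
                ratio_rounded=round(100 * m / depth),
                m_count=m,
                u_count=u,
            )
        )
    return records


def gen_nanopore_calls(
    betas: BetaVector,
    probeset: ProbeSet,
    n_sites: int,
    reads_per_site: int = 3,
    confident_fraction: float = 0.9,
    llr_threshold: float = 2.5,
    seed: int = 0,
) -> list:
    """Emit per-read nanopore-style site calls for a random probe subset.

    Per covered probe, ``reads_per_site`` calls are generated: methylated
    with probability beta, with |llr| above the confidence gate for
    ``confident_fraction`` of calls and below it otherwise.
    """
    rng = np.random.default_rng(seed)
    n_sites = min(n_sites, len(probeset))
    covered = np.sort(rng.choice(len(probeset), size=n_sites, replace=False))
    calls = []
    for idx in covered:
        beta = betas.values[idx]
        for _ in range(reads_per_site):
            methylated = rng.random() < beta
            confident = rng.random() < confident_fraction
            mag = (
                rng.uniform(llr_threshold + 0.5, 4 * llr_threshold)
                if confident
                else rng.uniform(0, 0.9 * llr_threshold)
            )
            calls.append(
                SiteCall(
                    chrom=probeset.chroms[idx],
                    pos=probeset.positions[idx],
                    llr=mag if methylated else -mag,
                )
            )
    return calls


def make_superclass_map(mc_labels, n_superclasses: int = 2) -> dict:
    """A deterministic surjective coarsening: MC i -> SC (i mod n)."""
    labels = sorted(set(mc_labels))
    return {mc: f"SC_{i % n_superclasses}" for i, mc in enumerate(labels)}
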