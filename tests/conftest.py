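"""Shared fixtures: the synthetic study cohorts and their classifications.

UMAP runs are the expensive part of the suite, so the canonical cohort
(8 classes x 20 samples, 2000 probes) and its derived classifications are
session-scoped and shared between module tests and the acceptance checks.
"""

import warnings

import numpy as np
import pytest

from methylomap.classify import (
    DNADEG_LABEL,
    AnnotationTable,
    UmapParams,
    classify_queries,
)
from methylomap.probe_store import BetaMatrix, BetaVector
from methylomap.synthetic import (
    CohortSpec,
    gen_cohort,
    gen_dnadeg,
    gen_queries,
    make_superclass_map,
)

# fixed analysis parameters for the label-recovery experiment:
# 500 of 2000 probes selected (25%), seed pinned for reproducibility
COHORT_PARAMS = UmapParams(seed=7, n_tdmp=500)
COHORT_SPEC = CohortSpec(seed=11)  # 8 classes x 20 samples x 2000 probes
QUERY_SEED = 23
N_QUERIES_PER_CLASS = 5


@pytest.fixture(autouse=True)
def _quiet_umap():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        yield


@pytest.fixture(scope="session")
def cohort():
    """(spec, reference, annotations+2-SC map, probeset, queries, truths)."""
    ref, ann, ps = gen_cohort(COHORT_SPEC)
    annotations = AnnotationTable(
        ann.mc_of, make_superclass_map(ann.mc_of.values(), n_superclasses=2)
    )
    queries, truths = gen_queries(COHORT_SPEC, N_QUERIES_PER_CLASS, seed=QUERY_SEED)
    return COHORT_SPEC, ref, annotations, ps, queries, truths


@pytest.fixture(scope="session")
def cohort_results(cohort):
    """Classification of the 40 held-out queries against the 160 references."""
    _spec, ref, annotations, _ps, queries, truths = cohort
    results, embedding = classify_queries(ref, queries, annotations, COHORT_PARAMS)
    return results, embedding, truths


@pytest.fixture(scope="session")
def dnadeg_run(cohort):
    """Joint run: tumour + DNADEG reference, degraded + clean queries.

    Reference: the 160 tumour samples plus 40 DNADEG-annotated degraded
    profiles.  Queries: 20 fresh degraded profiles and the 40 clean held-out
    cohort queries, classified in one embedding.
    """
    _spec, ref, annotations, ps, clean_queries, _truths = cohort
    deg_ref = gen_dnadeg(40, probeset=ps, seed=31)
    big = BetaMatrix(
        ref.sample_ids + deg_ref.sample_ids,
        np.vstack([ref.matrix, deg_ref.matrix]),
        ps,
    )
    mc = dict(annotations.mc_of)
    mc.update({sid: DNADEG_LABEL for sid in deg_ref.sample_ids})
    ann = AnnotationTable(mc, annotations.sc_of)

    deg_block = gen_dnadeg(20, probeset=ps, seed=57)
    deg_queries = [
        BetaVector(f"degquery_{i:02d}", deg_block.matrix[i]) for i in range(20)
    ]
    results, embedding = classify_queries(
        big, deg_queries + clean_queries, ann, COHORT_PARAMS
    )
    deg_ids = {q.sample_id for q in deg_queries}
    degraded = [r for r in results if r.query_id in deg_ids]
    clean = [r for r in results if r.query_id not in deg_ids]
    return degraded, clean


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 4-class cohort for determinism / CLI / plumbing tests."""
    spec = CohortSpec(
        n_classes=4, samples_per_class=10, n_probes=400, seed=3
    )
    ref, ann, ps = gen_cohort(spec)
    annotations = AnnotationTable(
        ann.mc_of, make_superclass_map(ann.mc_of.values(), n_superclasses=2)
    )
    queries, truths = gen_queries(spec, 2, seed=5)
    return spec, ref, annotations, ps, queries, truths


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the code paths they check)

def sd_rank_oracle(matrix: np.ndarray, n: int):
    """Full sort by population SD, ties by column index."""
    sds = [float(np.sqrt(np.mean((col - np.mean(col)) ** 2))) for col in matrix.T]
    order = sorted(range(matrix.shape[1]), key=lambda j: (-sds[j], j))
    return order[:n]


def knn_oracle(coords: dict, query_id: str, mc_of: dict, k: int):
    """Exhaustive all-pairs distance sort over annotated samples."""
    qx, qy = coords[query_id]
    scored = []
    for sid, (x, y) in coords.items():
        if sid == query_id or sid not in mc_of:
            continue
        d = ((x - qx) ** 2 + (y - qy) ** 2) ** 0.5
        scored.append((d, sid))
    scored.sort()
    return [sid for _d, sid in scored[:k]]


def modal_class_oracle(labels):
    """Counting oracle; returns None on ties."""
    counts = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    top = max(counts.values())
    tied = [l for l, c in counts.items() if c == top]
    return tied[0] if len(tied) == 1 else None


def match_oracle(calls, truths):
    n = sum(1 for sid, label in calls if truths[sid] == label)
    return n, len(calls)


def histogram_oracle(reads, genome, bin_size):
    """Dict-based per-bin read counting."""
    out = {}
    for chrom, length in zip(genome.chroms, genome.lengths):
        nbins = -(-length // bin_size)
        out[chrom] = [0] * nbins
    for r in reads:
        if r.chrom in out:
            out[r.chrom][r.start // bin_size] += 1
    return out
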