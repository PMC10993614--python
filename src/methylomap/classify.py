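"""Unsupervised tumour classification by UMAP embedding and neighbour vote.

The classifier makes no use of training: reference methylomes (annotated with
a methylation class, MC) and query samples are embedded *jointly* into two
dimensions with UMAP, and each query is assigned the most abundant MC among
its k nearest annotated neighbours in the plot (k = 15 by default, matching
typical reference-cohort entity sizes).  MC calls are optionally coarsened
into clinically oriented superclasses (SC).  A query whose neighbourhood is
dominated by the DNADEG artefact class (degraded-DNA profiles, which cluster
together) is flagged as not interpretable.

Two input routes are supported:

* **array path** — query shares the full ProbeSet; the most variable probes
  (TDMP, ranked by standard deviation across the reference) are selected on
  the reference alone, then reference and queries are embedded on those
  columns;
* **nanopore path** — the query covers only a few thousand probes; the
  reference is subset to exactly the query's covered columns (no TDMP
  selection) and embedded jointly with the query.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .harmonize import SparseBetaVector
from .probe_store import BetaMatrix, BetaVector

__all__ = [
    "DEFAULT_K",
    "DNADEG_LABEL",
    "AnnotationTable",
    "UmapParams",
    "Embedding",
    "ClassificationResult",
    "select_tdmp",
    "embed",
    "nearest_annotated",
    "vote",
    "qc_dnadeg",
    "classify_queries",
]

logger = logging.getLogger(__name__)

#: Number of annotated neighbours considered for the vote.
DEFAULT_K = 15
#: Annotation label of the degraded-DNA artefact class.
DNADEG_LABEL = "DNADEG"


@dataclass
class AnnotationTable:
    """Sample -> methylation class (MC), plus MC -> superclass (SC) map.

    Samples absent from ``mc_of`` are unannotated: they appear in embeddings
    but never contribute to votes.
    """

    mc_of: dict
    sc_of: dict = field(default_factory=dict)

    def is_annotated(self, sample_id) -> bool:
        return sample_id in self.mc_of

    def superclass(self, mc: str) -> str:
        """SC for an MC; an unmapped MC is its own superclass (warned once)."""
        if mc in self.sc_of:
            return self.sc_of[mc]
        logger.warning("MC %r has no superclass mapping; using MC as SC", mc)
        return mc


@dataclass(frozen=True)
class UmapParams:
    """UMAP hyperparameters plus the probe-selection size.

    ``n_neighbors`` defaults to 15 to match the k = 15 voting rule;
    ``seed`` is mandatory — embeddings are only reproducible at fixed seed.
    """

    seed: int
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    n_tdmp: int | None = 5000

    def replace(self, **kw) -> "UmapParams":
        return replace(self, **kw)


@dataclass
class Embedding:
    """2-D UMAP coordinates per sample, with the parameters that made them."""

    coords: dict  # sample_id -> (x, y)
    params: UmapParams
    n_features: int = 0

    def __post_init__(self):
        for sid, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite embedding coordinate for {sid!r}")

    def array(self, sample_ids) -> np.ndarray:
        return np.asarray([self.coords[s] for s in sample_ids], dtype=np.float64)


@dataclass
class ClassificationResult:
    """Outcome of the k-nearest-annotated-neighbour vote for one query."""

    query_id: str
    neighbours: list  # (sample_id, mc, distance), ascending distance
    vote_counts: dict  # mc -> count
    called_mc: str
    called_sc: str
    k: int
    dnadeg_flag: bool = False

    @property
    def interpretable(self) -> bool:
        return not self.dnadeg_flag


def select_tdmp(reference: BetaMatrix, n_tdmp: int) -> np.ndarray:
    """Indices of the top differentially methylated probes (TDMP).

    Probes are ranked by per-probe standard deviation across reference
    samples (population formula, ddof = 0), descending; ties are broken by
    genomic (column) order so selection is deterministic.  Variance ranking
    drops non-informative probes — constant or neutral-filled columns have
    zero spread and rank last.
    """
    n_probes = reference.matrix.shape[1]
    if reference.n_samples < 2:
        raise ValueError("TDMP ranking needs >= 2 reference samples")
    if not (0 < n_tdmp <= n_probes):
        raise ValueError(f"n_tdmp {n_tdmp} outside (0, {n_probes}]")
    sd = reference.matrix.std(axis=0, ddof=0)
    # primary key: -sd descending; secondary: column index ascending
    order = np.lexsort((np.arange(n_probes), -sd))
    return order[:n_tdmp]


def _run_umap(data: np.ndarray, params: UmapParams) -> np.ndarray:
    import umap  # deferred: numba JIT makes this import expensive

    n = data.shape[0]
    n_neighbors = min(params.n_neighbors, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=params.min_dist,
            metric=params.metric,
            random_state=params.seed,
        )
        return np.asarray(reducer.fit_transform(data), dtype=np.float64)


def embed(
    reference: BetaMatrix,
    queries,
    params: UmapParams,
    min_covered: int = 1000,
    strict: bool = False,
) -> Embedding:
    """Jointly embed reference and query samples into two dimensions.

    Dense queries (:class:`BetaVector`) take the array path: TDMP columns are
    selected on the reference only, queries never perturb probe selection.
    A sparse query (:class:`SparseBetaVector`, nanopore path) defines the
    column subset itself; at most one sparse query per embedding, and a query
    covering fewer than ``min_covered`` probes warns (or raises when
    ``strict``).

    Reference rows are canonically re-ordered by sample id before UMAP so the
    embedding — hence every downstream call — is invariant to the order in
    which reference samples were assembled.
    """
    queries = list(queries)
    sparse = [q for q in queries if isinstance(q, SparseBetaVector)]
    dense = [q for q in queries if isinstance(q, BetaVector)]
    if sparse and dense:
        raise ValueError("cannot mix dense and sparse queries in one embedding")
    if len(sparse) > 1:
        raise ValueError("the nanopore path embeds one sparse query at a time")

    ref_order = np.argsort(np.asarray(reference.sample_ids, dtype=object))
    ref_ids = [reference.sample_ids[i] for i in ref_order]
    ref_mat = reference.matrix[ref_order]

    all_ids = list(ref_ids)
    if sparse:
        q = sparse[0]
        cols = q.indices
        if len(cols) < min_covered:
            msg = (
                f"query {q.sample_id!r} covers only {len(cols)} probes "
                f"(< {min_covered})"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        if len(cols) == 0:
            raise ValueError("sparse query covers no probes")
        qrow = np.asarray([q.entries[i] for i in cols], dtype=np.float64)
        data = np.vstack([ref_mat[:, cols], qrow])
        all_ids.append(q.sample_id)
    else:
        if params.n_tdmp is not None:
            cols = select_tdmp(
                BetaMatrix(ref_ids, ref_mat, reference.probeset), params.n_tdmp
            )
        else:
            cols = np.arange(ref_mat.shape[1])
        rows = [ref_mat[:, cols]]
        for q in dense:
            if len(q) != len(reference.probeset):
                raise ValueError(
                    f"query {q.sample_id!r} not aligned to the reference ProbeSet"
                )
            rows.append(q.values[cols][None, :])
            all_ids.append(q.sample_id)
        data = np.vstack(rows)

    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate sample ids between reference and queries")

    xy = _run_umap(data, params)
    coords = {sid: (float(x), float(y)) for sid, (x, y) in zip(all_ids, xy)}
    return Embedding(coords, params, n_features=data.shape[1])


def nearest_annotated(
    embedding: Embedding,
    query_id: str,
    annotations: AnnotationTable,
    k: int = DEFAULT_K,
) -> list:
    """The k annotated samples closest to the query in the 2-D plot.

    Euclidean distance in embedding space; unannotated samples and the query
    itself are skipped, not counted.  Returns ``(sample_id, mc, distance)``
    triples in ascending distance (ties broken by sample id).
    """
    if query_id not in embedding.coords:
        raise KeyError(f"query {query_id!r} is not embedded")
    qx, qy = embedding.coords[query_id]
    candidates = [
        sid
        for sid in embedding.coords
        if sid != query_id and annotations.is_annotated(sid)
    ]
    if len(candidates) < k:
        raise ValueError(
            f"only {len(candidates)} annotated samples in the embedding; "
            f"need {k} (deficit {k - len(candidates)})"
        )
    pts = embedding.array(candidates)
    d = np.hypot(pts[:, 0] - qx, pts[:, 1] - qy)
    order = sorted(range(len(candidates)), key=lambda i: (d[i], candidates[i]))[:k]
    return [(candidates[i], annotations.mc_of[candidates[i]], float(d[i])) for i in order]


def vote(
    neighbours: list,
    annotations: AnnotationTable,
    query_id: str = "",
) -> ClassificationResult:
    """Majority vote over the neighbour list.

    The called MC is the modal neighbour class; among tied classes the one
    containing the single nearest neighbour (smallest distance, i.e. the
    earliest-ranked member) wins.  The SC is looked up in the superclass map;
    an unmapped MC is its own SC.
    """
    if not neighbours:
        raise ValueError("empty neighbour list")
    counts: dict = {}
    first_rank: dict = {}
    for rank, (sid, mc, _dist) in enumerate(neighbours):
        counts[mc] = counts.get(mc, 0) + 1
        first_rank.setdefault(mc, rank)
    top = max(counts.values())
    tied = [mc for mc, c in counts.items() if c == top]
    called_mc = min(tied, key=lambda mc: first_rank[mc])
    called_sc = annotations.superclass(called_mc)
    return ClassificationResult(
        query_id=query_id,
        neighbours=list(neighbours),
        vote_counts=counts,
        called_mc=called_mc,
        called_sc=called_sc,
        k=len(neighbours),
    )


def qc_dnadeg(
    result: ClassificationResult, dnadeg_label: str = DNADEG_LABEL
) -> bool:
    """Flag a result whose neighbourhood is dominated by degraded-DNA cases.

    True iff the DNADEG class holds a strict majority (> k/2) of the
    neighbour votes.  The MC/SC calls are retained, but a flagged result
    should be excluded from interpretation.
    """
    flagged = result.vote_counts.get(dnadeg_label, 0) > result.k / 2
    result.dnadeg_flag = flagged
    return flagged


def classify_queries(
    reference: BetaMatrix,
    queries,
    annotations: AnnotationTable,
    params: UmapParams,
    k: int = DEFAULT_K,
    min_covered: int = 1000,
    strict: bool = False,
):
    """End-to-end pipeline: embed, find neighbours, vote, QC.

    Dense queries are embedded together in a single UMAP run; each sparse
    (nanopore) query gets its own embedding on its covered columns.  Returns
    ``(results, embedding)`` where ``embedding`` is the joint dense-path
    embedding (or the last sparse-path one).
    """
    queries = list(queries)
    dense = [q for q in queries if isinstance(q, BetaVector)]
    sparse = [q for q in queries if isinstance(q, SparseBetaVector)]

    results = []
    embedding = None
    if dense:
        embedding = embed(reference, dense, params)
        for q in dense:
            nb = nearest_annotated(embedding, q.sample_id, annotations, k=k)
            res = vote(nb, annotations, query_id=q.sample_id)
            qc_dnadeg(res)
            results.append(res)
    for q in sparse:
        embedding = embed(reference, [q], params, min_covered=min_covered, strict=strict)
        nb = nearest_annotated(embedding, q.sample_id, annotations, k=k)
        res = vote(nb, annotations, query_id=q.sample_id)
        qc_dnadeg(res)
        results.append(res)
    return results, embedding
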