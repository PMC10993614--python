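"""Scoring harness for UMAP-vote classification performance.

Compares classifier calls with reference diagnoses at two granularities:
fine methylation classes (MC) and clinically oriented superclasses (SC,
a coarsening of MCs).  Two experiments are supported:

* a **TDMP sweep** — repeat the classify-and-score cycle over a grid of
  probe-selection sizes (the default grid spans 50 to 75,000 probes, the
  range over which array-based classification is typically evaluated);
* **removal robustness** — randomly remove annotated reference samples,
  re-embed, re-classify and re-score, measuring stability of the match
  fraction as the reference thins out.

When the SC map is a genuine coarsening (every MC maps to one SC), the
SC-level match fraction can never fall below the MC-level fraction: a
correct MC call stays correct after translation, and an MC mismatch may
still translate to the same SC.  This monotonicity is asserted on every
sweep cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_K,
    AnnotationTable,
    UmapParams,
    classify_queries,
)
from .probe_store import BetaMatrix

__all__ = [
    "DEFAULT_TDMP_GRID",
    "BenchmarkResult",
    "match_fraction",
    "tdmp_sweep",
    "removal_robustness",
]

#: Default probe-count grid for the sweep.
DEFAULT_TDMP_GRID = (
    50, 100, 500, 1_000, 5_000, 10_000, 15_000, 20_000, 25_000, 50_000, 75_000,
)


@dataclass
class BenchmarkResult:
    """Long-format sweep cells plus removal-robustness records."""

    cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["n_tdmp", "level", "n_match", "n_total", "fraction", "failed"]
        )
    )
    removals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["n_removed", "seed", "fraction_mc", "fraction_sc"]
        )
    )

    def to_tsv(self, path):
        """Deterministic long-format TSV (sweep cells then removal rows)."""
        cells = self.cells.copy()
        cells["fraction"] = cells["fraction"].map(lambda v: f"{v:.6f}")
        with open(path, "w") as fh:
            cells.to_csv(fh, sep="\t", index=False)
            if len(self.removals):
                fh.write("#\n")
                rem = self.removals.copy()
                for col in ("fraction_mc", "fraction_sc"):
                    rem[col] = rem[col].map(lambda v: f"{v:.6f}")
                rem.to_csv(fh, sep="\t", index=False)


def match_fraction(calls, truths):
    """Exact-match agreement between calls and reference labels.

    ``calls`` are ``(sample_id, called_label)`` pairs; ``truths`` maps
    sample id to the reference label.  Every called sample must have a truth.
    Returns ``(n_match, n_total, fraction)``.
    """
    calls = list(calls)
    missing = [sid for sid, _l in calls if sid not in truths]
    if missing:
        raise KeyError(f"samples missing from truth table: {missing}")
    n_match = sum(1 for sid, label in calls if truths[sid] == label)
    n_total = len(calls)
    return n_match, n_total, (n_match / n_total if n_total else float("nan"))


def _score_both_levels(results, truths, annotations: AnnotationTable):
    mc_calls = [(r.query_id, r.called_mc) for r in results]
    sc_calls = [(r.query_id, r.called_sc) for r in results]
    sc_truths = {sid: annotations.superclass(mc) for sid, mc in truths.items()}
    mc = match_fraction(mc_calls, truths)
    sc = match_fraction(sc_calls, sc_truths)
    return mc, sc


def tdmp_sweep(
    reference: BetaMatrix,
    queries,
    truths,
    annotations: AnnotationTable,
    grid=DEFAULT_TDMP_GRID,
    params: UmapParams | None = None,
    k: int = DEFAULT_K,
) -> BenchmarkResult:
    """One classify-and-score cycle per TDMP grid value, at MC and SC level.

    Grid values exceeding the probe count are rejected up front.  A cell
    whose classification fails is recorded with ``failed=True`` and the sweep
    continues.  When ``sc_of`` is a coarsening, SC >= MC is asserted per cell.
    """
    if params is None:
        raise ValueError("params (with a seed) are required")
    n_probes = reference.matrix.shape[1]
    grid = list(grid)
    too_big = [g for g in grid if g > n_probes]
    if too_big:
        raise ValueError(f"grid values exceed probe count {n_probes}: {too_big}")

    coarsening = all(mc in annotations.sc_of for mc in annotations.mc_of.values())
    rows = []
    for n_tdmp in grid:
        try:
            results, _emb = classify_queries(
                reference, queries, annotations, params.replace(n_tdmp=n_tdmp), k=k
            )
            (mc_m, mc_t, mc_f), (sc_m, sc_t, sc_f) = _score_both_levels(
                results, truths, annotations
            )
        except Exception:  # noqa: BLE001 — cell failure must not kill the sweep
            rows.append((n_tdmp, "MC", 0, 0, float("nan"), True))
            rows.append((n_tdmp, "SC", 0, 0, float("nan"), True))
            continue
        if coarsening and sc_f < mc_f:
            raise AssertionError(
                f"SC fraction {sc_f} < MC fraction {mc_f} under a coarsening map"
            )
        rows.append((n_tdmp, "MC", mc_m, mc_t, mc_f, False))
        rows.append((n_tdmp, "SC", sc_m, sc_t, sc_f, False))
    cells = pd.DataFrame(
        rows, columns=["n_tdmp", "level", "n_match", "n_total", "fraction", "failed"]
    )
    return BenchmarkResult(cells=cells)


def removal_robustness(
    reference: BetaMatrix,
    annotations: AnnotationTable,
    queries,
    truths,
    removal_counts,
    seed: int,
    params: UmapParams | None = None,
    k: int = DEFAULT_K,
) -> pd.DataFrame:
    """Match fractions after random removal of annotated reference samples.

    For each count, that many annotated samples are removed uniformly at
    random (seeded, without replacement), the cohort is re-embedded and every
    query re-classified and re-scored.  Removal leaving fewer than k
    annotated samples is an error.
    """
    if params is None:
        raise ValueError("params (with a seed) are required")
    annotated_ids = sorted(
        sid for sid in reference.sample_ids if annotations.is_annotated(sid)
    )
    rows = []
    for n_removed in removal_counts:
        if len(annotated_ids) - n_removed < k:
            raise ValueError(
                f"removing {n_removed} leaves fewer than k={k} annotated samples"
            )
        rng = np.random.default_rng(seed + n_removed)
        removed = set(
            rng.choice(annotated_ids, size=n_removed, replace=False).tolist()
        )
        keep = [i for i, sid in enumerate(reference.sample_ids) if sid not in removed]
        sub = BetaMatrix(
            [reference.sample_ids[i] for i in keep],
            reference.matrix[keep],
            reference.probeset,
        )
        results, _emb = classify_queries(sub, queries, annotations, params, k=k)
        (_, _, mc_f), (_, _, sc_f) = _score_both_levels(results, truths, annotations)
        rows.append((n_removed, seed, mc_f, sc_f))
    return pd.DataFrame(rows, columns=["n_removed", "seed", "fraction_mc", "fraction_sc"])
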