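"""Report and plot generation: embedding scatter, vote pie, CNV profile.

Interactive exports are self-contained HTML files built around inline SVG;
each data point carries a native ``<title>`` element, so hovering reveals the
sample id and methylation class without any scripting dependency.  Static
figures use matplotlib.  The per-query diagnostic report bundles run
information, the neighbour zoom, the vote summary and (when reads are
supplied) the copy-number profile into one HTML document.
"""

from __future__ import annotations

import html
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import AnnotationTable, ClassificationResult, Embedding
from .cnv import BinnedCoverage

__all__ = [
    "embedding_to_tsv",
    "embedding_to_html",
    "classification_to_json",
    "plot_vote_pie",
    "plot_cnv_profile",
    "cnv_profile_to_html",
    "plot_benchmark",
    "write_report",
]


def embedding_to_tsv(embedding: Embedding, annotations: AnnotationTable, path):
    """TSV export: sample_id, x, y, mc ('' when unannotated)."""
    rows = [
        (sid, f"{x:.6f}", f"{y:.6f}", annotations.mc_of.get(sid, ""))
        for sid, (x, y) in sorted(embedding.coords.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "x", "y", "mc"]).to_csv(
        path, sep="\t", index=False
    )


def _scale(values, lo, hi, out_lo, out_hi):
    values = np.asarray(values, dtype=float)
    span = (hi - lo) or 1.0
    return out_lo + (values - lo) / span * (out_hi - out_lo)


def _class_colors(labels):
    cmap = plt.get_cmap("tab20")
    uniq = sorted({l for l in labels if l})
    colors = {l: matplotlib.colors.to_hex(cmap(i % 20)) for i, l in enumerate(uniq)}
    colors[""] = "#bbbbbb"
    return colors


def embedding_svg(
    embedding: Embedding,
    annotations: AnnotationTable,
    highlight=(),
    width: int = 720,
    height: int = 540,
) -> str:
    """Inline-SVG scatter of the embedding with hover annotations.

    Each point's ``<title>`` shows the sample id and its MC (or
    "unannotated"), the SVG equivalent of a pop-up-on-hover label.
    Samples in ``highlight`` are drawn as larger red-ringed markers.
    """
    ids = sorted(embedding.coords)
    xy = embedding.array(ids)
    pad = 30
    xs = _scale(xy[:, 0], xy[:, 0].min(), xy[:, 0].max(), pad, width - pad)
    ys = _scale(xy[:, 1], xy[:, 1].min(), xy[:, 1].max(), height - pad, pad)
    labels = [annotations.mc_of.get(s, "") for s in ids]
    colors = _class_colors(labels)
    highlight = set(highlight)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for sid, x, y, mc in zip(ids, xs, ys, labels):
        tip = html.escape(f"{sid} — {mc or 'unannotated'}")
        if sid in highlight:
            parts.append(
                f'<circle cx="{x:.1f}" cy="{y:.1f}" r="6" fill="{colors[mc]}" '
                f'stroke="red" stroke-width="2"><title>{tip}</title></circle>'
            )
        else:
            parts.append(
                f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3" fill="{colors[mc]}" '
                f'fill-opacity="0.8"><title>{tip}</title></circle>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def embedding_to_html(
    embedding: Embedding, annotations: AnnotationTable, path, highlight=(), title=""
):
    svg = embedding_svg(embedding, annotations, highlight=highlight)
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title or 'UMAP embedding')}</title></head><body>"
        f"<h2>{html.escape(title or 'UMAP embedding')}</h2>{svg}</body></html>"
    )
    Path(path).write_text(doc)


def classification_to_json(result: ClassificationResult, path=None):
    payload = {
        "query_id": result.query_id,
        "called_mc": result.called_mc,
        "called_sc": result.called_sc,
        "k": result.k,
        "dnadeg_flag": result.dnadeg_flag,
        "interpretable": result.interpretable,
        "vote_counts": result.vote_counts,
        "neighbours": [
            {"sample_id": s, "mc": mc, "distance": round(d, 6)}
            for s, mc, d in result.neighbours
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def plot_vote_pie(result: ClassificationResult, path):
    """Pie chart of the annotation counts among the nearest neighbours."""
    labels = sorted(result.vote_counts, key=result.vote_counts.get, reverse=True)
    counts = [result.vote_counts[l] for l in labels]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.pie(counts, labels=[f"{l} ({c})" for l, c in zip(labels, counts)])
    ax.set_title(f"{result.query_id}: {result.called_mc}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def _genome_axis(cov: BinnedCoverage):
    offsets, ticks = {}, []
    acc = 0
    for chrom, length in zip(cov.genome.chroms, cov.genome.lengths):
        offsets[chrom] = acc
        ticks.append((acc + length / 2, chrom.replace("chr", "")))
        acc += length
    return offsets, ticks, acc


def plot_cnv_profile(cov: BinnedCoverage, path, loci=None, title=""):
    """Static genome-wide log2 profile with optional locus annotations.

    ``loci`` is an iterable of ``(chrom, start, end, name)`` (e.g. parsed
    from a BED file of genes of interest); each is marked with a vertical
    line and label.
    """
    if not cov.log2:
        raise ValueError("normalize_bins must be applied before plotting")
    offsets, ticks, total = _genome_axis(cov)
    fig, ax = plt.subplots(figsize=(11, 3.2))
    for chrom in cov.genome.chroms:
        mids = [offsets[chrom] + (s + e) / 2 for s, e, _c in cov.bins[chrom]]
        ax.scatter(mids, cov.log2[chrom], s=8, color="#27548a")
        ax.axvline(offsets[chrom], color="#dddddd", lw=0.6, zorder=0)
    ax.axhline(0, color="black", lw=0.7)
    for chrom, start, end, name in loci or []:
        if chrom in offsets:
            x = offsets[chrom] + (start + end) / 2
            ax.axvline(x, color="#c23b22", lw=0.8, ls="--")
            ax.annotate(name, (x, ax.get_ylim()[1]), fontsize=7, color="#c23b22")
    ax.set_xticks([t for t, _l in ticks])
    ax.set_xticklabels([l for _t, l in ticks], fontsize=7)
    ax.set_xlim(0, total)
    ax.set_ylabel("log2 ratio")
    ax.set_title(title or f"Copy-number profile (bin {cov.bin_size // 1_000_000} Mb)")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def cnv_profile_svg(cov: BinnedCoverage, loci=None, width=960, height=280) -> str:
    """Inline-SVG CNV profile; each bin's hover shows its coordinates/ratio."""
    if not cov.log2:
        raise ValueError("normalize_bins must be applied before plotting")
    offsets, ticks, total = _genome_axis(cov)
    all_log2 = np.concatenate([cov.log2[c] for c in cov.genome.chroms])
    lo, hi = min(-1.5, all_log2.min()), max(1.5, all_log2.max())
    pad = 25
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    y0 = _scale([0.0], lo, hi, height - pad, pad)[0]
    parts.append(
        f'<line x1="{pad}" y1="{y0:.1f}" x2="{width - pad}" y2="{y0:.1f}" '
        'stroke="black" stroke-width="0.7"/>'
    )
    for chrom in cov.genome.chroms:
        for (s, e, c), l2 in zip(cov.bins[chrom], cov.log2[chrom]):
            gx = offsets[chrom] + (s + e) / 2
            x = _scale([gx], 0, total, pad, width - pad)[0]
            y = _scale([l2], lo, hi, height - pad, pad)[0]
            tip = html.escape(f"{chrom}:{s:,}-{e:,} n={c} log2={l2:.2f}")
            parts.append(
                f'<circle cx="{x:.1f}" cy="{y:.1f}" r="2.2" fill="#27548a">'
                f"<title>{tip}</title></circle>"
            )
    for chrom, start, end, name in loci or []:
        if chrom in offsets:
            gx = offsets[chrom] + (start + end) / 2
            x = _scale([gx], 0, total, pad, width - pad)[0]
            tip = html.escape(f"{name} {chrom}:{start:,}-{end:,}")
            parts.append(
                f'<line x1="{x:.1f}" y1="{pad}" x2="{x:.1f}" y2="{height - pad}" '
                f'stroke="#c23b22" stroke-dasharray="3"><title>{tip}</title></line>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def cnv_profile_to_html(cov: BinnedCoverage, path, loci=None, title=""):
    svg = cnv_profile_svg(cov, loci=loci)
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title or 'CNV profile')}</title></head><body>"
        f"<h2>{html.escape(title or 'CNV profile')}</h2>{svg}</body></html>"
    )
    Path(path).write_text(doc)


def plot_benchmark(result, path):
    """Match fraction versus TDMP count, one line per level."""
    cells = result.cells[~result.cells["failed"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    for level, marker in (("MC", "o"), ("SC", "s")):
        sub = cells[cells["level"] == level].sort_values("n_tdmp")
        ax.plot(sub["n_tdmp"], sub["fraction"], marker=marker, label=level)
    ax.set_xscale("log")
    ax.set_xlabel("TDMP count")
    ax.set_ylabel("match fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def write_report(
    result: ClassificationResult,
    embedding: Embedding,
    annotations: AnnotationTable,
    out_dir,
    run_info: dict | None = None,
    cov: BinnedCoverage | None = None,
    loci=None,
):
    """Assemble the per-query diagnostic report bundle.

    Writes ``<query>.json``, ``<query>_neighbours.tsv``, ``<query>_pie.png``,
    ``<query>_umap.html`` and a combined ``<query>_report.html`` with run
    information, neighbour zoom, vote counts and (optionally) the CNV
    profile.  A DNADEG-flagged query is prominently marked not interpretable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q = result.query_id

    classification_to_json(result, out_dir / f"{q}.json")
    pd.DataFrame(
        result.neighbours, columns=["sample_id", "mc", "distance"]
    ).to_csv(out_dir / f"{q}_neighbours.tsv", sep="\t", index=False)
    plot_vote_pie(result, out_dir / f"{q}_pie.png")
    highlight = [q] + [s for s, _mc, _d in result.neighbours]
    embedding_to_html(
        embedding, annotations, out_dir / f"{q}_umap.html",
        highlight=highlight, title=f"UMAP — {q}",
    )

    sections = []
    if result.dnadeg_flag:
        sections.append(
            "<p style='color:red;font-weight:bold'>NOT INTERPRETABLE: "
            "neighbourhood dominated by DNADEG (degraded DNA) reference "
            "cases — exclude from data interpretation.</p>"
        )
    info = {"query": q, "called_mc": result.called_mc, "called_sc": result.called_sc,
            "k": result.k, **(run_info or {})}
    rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in info.items()
    )
    sections.append(f"<h3>A. Run information</h3><table border='1'>{rows}</table>")
    sections.append(
        "<h3>B. Embedding (neighbour zoom)</h3>"
        + embedding_svg(embedding, annotations, highlight=highlight)
    )
    votes = "".join(
        f"<tr><td>{html.escape(mc)}</td><td>{c}</td></tr>"
        for mc, c in sorted(result.vote_counts.items(), key=lambda kv: -kv[1])
    )
    sections.append(
        "<h3>C. Annotation counts</h3>"
        f"<table border='1'><tr><th>MC</th><th>count</th></tr>{votes}</table>"
    )
    if cov is not None:
        sections.append("<h3>D. Copy-number profile</h3>" + cnv_profile_svg(cov, loci))
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>Report {html.escape(q)}</title></head><body>"
        f"<h2>Diagnostic report — {html.escape(q)}</h2>"
        + "".join(sections)
        + "</body></html>"
    )
    report_path = out_dir / f"{q}_report.html"
    report_path.write_text(doc)
    return report_path
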