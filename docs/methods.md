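# Methods

## The harmonized probe space

All platforms are reduced to a shared feature space of overlap CpGs: probes
present on every platform manifest supplied, minus a blacklist
(cross-reactive / polymorphic probes), minus everything on chrX/chrY.
Sex-chromosome depletion keeps the space free of sex-driven clustering;
the same convention is mirrored in the CNV module, which bins autosomes only
by default. The probe order is canonical — (chromosome order, position) —
and every beta vector/matrix is aligned to it. Chromosome names are
normalized to `chr1..chr22, chrX, chrY`; bare `1..22/X/Y` input names are
accepted. Manifest coordinates are 1-based; bedGraph input is 0-based
half-open and converted on ingestion (`start + 1` matches a probe position;
if strict matching captures fewer than half the records, the reverse-strand
offset is also tried, since CpG methylation is symmetric).

Per-sample betas are persisted as raw little-endian float32 payloads (4
bytes per probe, no embedded header) with a JSON sidecar carrying sample id,
probe-set version tag, and neutral-fill indices. The choice of float32 and
a headerless payload is this package's own convention: the layout is
trivially verifiable (file size = 4 × probe count) and loads at disk
bandwidth; beta values carry nowhere near 24 bits of information.

### The 0.49 neutral fill

Probes a platform did not cover receive exactly 0.49. The value is
deliberately just off the 0.5 midpoint: it is uninformative for
variance-based probe ranking (constant across samples filled the same way),
distinguishable from genuinely hemi-methylated sites on inspection, and
recorded in a fill mask so no downstream step needs to guess. The fill is
used on the array/panel paths only. The nanopore path never fills: a
shallow run covers a few thousand probes, and filling ~99% of the space
with a constant would swamp the signal — instead the reference matrix is
subset to exactly the query's covered columns before embedding.

## Harmonizing sequencing inputs

**Targeted panels (bedGraph).** The printed, rounded ratio column is
discarded and the methylation fraction recomputed at full precision as
#M / (#M + #N). Duplicate records at one position (strand-split dialects)
have their counts summed before the ratio (configurable to first-wins);
zero-total records stay neutral-filled. Records matching no probe are
counted in a load report, not fatal.

**Nanopore calls.** Per-site (or per-read) log-likelihood ratios are gated
at |LLR| ≥ 2.5 — the community convention for nanopolish/f5c call filtering
— and the per-probe beta is the fraction of methylated (LLR > 0) calls
among confident ones. How per-read calls are collapsed per site is not
standardized; this threshold-and-count rule is a documented package choice,
and betas are kept continuous (not binarized) before joining the array
references. A query covering fewer than 1,000 probes triggers a warning
(error in strict mode): below that, the joint embedding rests on too few
shared features to trust.

## Classification

1. **TDMP selection.** Probes are ranked by per-probe standard deviation
   across the *reference only* (population formula, ddof = 0; ties broken
   by genomic order so selection is deterministic). Queries never perturb
   probe selection in the default mode; recomputing TDMP with the query
   included is available behind a flag but off by default.
2. **Joint embedding.** Reference and queries are embedded together with
   UMAP (2 components, n_neighbors = 15, min_dist = 0.1, Euclidean metric,
   mandatory seed). The hyperparameters are package defaults chosen to
   match the k = 15 voting rule; there is no canonical published setting.
   Reference rows are canonically sorted by sample id before UMAP so
   classification is invariant to the order in which the reference was
   assembled (UMAP itself is not row-permutation invariant).
3. **Neighbour vote.** The k = 15 annotated samples nearest the query in
   the 2-D plot (Euclidean distance; unannotated samples and the query
   itself are skipped, not counted) vote with their MC. The modal class
   wins; among tied classes the one containing the single nearest
   neighbour wins. k = 15 matches typical per-entity reference sizes
   (≥ 8, usually > 20 cases per entity); with fewer reference cases per
   entity the pie chart must be read accordingly.
4. **Superclass translation.** MC → SC through a user-supplied map; an
   unmapped MC is its own superclass (warned). When the map is a genuine
   coarsening, SC-level agreement can never be below MC-level agreement —
   asserted on every benchmark sweep.
5. **DNADEG QC.** Degraded-DNA profiles form their own cluster; a query
   whose neighbourhood contains a *strict majority* (> k/2) of
   DNADEG-annotated neighbours is flagged not interpretable. "Majority" is
   the defensible reading of "mostly"; the threshold is configurable.

Neighbour search happens in the 2-D embedding, not in probe space: the
embedding is the diagnostic object the examiner sees, and the call should
agree with the plot being read.

## Copy-number profiling

Reads are reduced to (chromosome, 0-based start); assignment is by
alignment start (midpoint assignment differs negligibly at ≥ 1 Mb bins).
BAM input keeps primary alignments with MAPQ ≥ 20 (configurable). Bin width
adapts to the run: `round(total_genome_length × 30 / total_reads)`, clamped
to [1 Mb, 10 Mb]. The rounding-then-clamping rule is this package's
convention for realizing the 30-reads-per-bin target within the 1–10 Mb
working range. Normalization is against uniform expectation with a 0.5
pseudocount on both sides (empty bins stay finite); the truncated last bin
of each chromosome scales its expectation by true width. Output is the
log2 ratio per bin. Arm-level events (ratio 0.5 / 1.5) displace the mean
chromosome log2 by ≈ −0.74 / +0.36 after total-count renormalization —
comfortably beyond the ±0.2 detection threshold — whereas single-gene
events at 1–10 Mb bins are below resolution by design.

## The synthetic-data generator

Array betas are empirically bimodal, so class centroids are drawn from a
two-component beta mixture: "low" probes ~ Beta(2, 10), "high" probes
~ Beta(10, 2). A shared backbone covers 70% of probes; the remaining 30%
(the discriminative fraction) get an independent low/high state per class.
Samples are centroid + N(0, 0.05) noise, clipped to [0, 1]. The default
cohort is 8 classes × 20 samples × 2,000 probes — entity sizes matching
the k = 15 voting rule, with held-out queries drawn as fresh noise around
the same centroids. DNADEG profiles are uniform noise on [0.02, 0.98]:
no bimodality, no class structure, high per-probe spread — they cluster
with each other and apart from every class, as degraded profiles do.

Panel output draws per-site depth ~ Poisson(30) (≥ 1) and methylated counts
~ Binomial(depth, β); exactly `round(coverage × P)` probes are covered so
fill accounting is exact. Nanopore calls draw |LLR| above the confidence
gate for 90% of calls and below it otherwise, methylated with probability
β. CNV reads are sampled with density proportional to local copy ratio on
small synthetic genomes (3 × 50 Mb) so simulations run in seconds; with
1,500 reads the adaptive rule lands at 3 Mb bins, the middle of the
clamped range, mirroring a genome-scale shallow run at the same
reads-per-bin expectation.

What the generator does *not* model: read lengths and error profiles,
bisulfite conversion chemistry, probe-level measurement biases shared
between platforms, batch effects, tumour purity, or inter-class similarity
structure (classes are exchangeable). Passing tests therefore demonstrate
that the machinery is correct under clean class structure at stated noise
levels — not that real cohorts of these sizes achieve these accuracies.
Real methylation classes overlap, references are imbalanced, and tumour
content varies; the published behaviour of this approach on clinical data
is materially below the synthetic ceiling.

## Benchmarking

Match fractions are exact string equality after optional SC translation.
The TDMP sweep re-embeds per grid value (the default grid spans 50 to
75,000 probes; grid values above the probe count are rejected). Failed
cells are recorded, never silently dropped. Removal robustness removes
annotated reference samples uniformly at random (seeded, without
replacement), re-embeds and re-scores; the sampling frame is annotated
samples only, and the seed is recorded in the output.

## Numerical and operational choices

- All randomness flows through explicit seeds (`numpy.random.default_rng`);
  UMAP gets `random_state`, which forces single-threaded, reproducible
  layout. Fixed seed ⇒ byte-identical TSV/JSON outputs.
- Beta tables read missing cells as 0.49 + fill mask; unknown probe columns
  are counted and ignored; non-numeric cells fail naming row and column.
- Interactive exports are self-contained SVG-in-HTML with native `<title>`
  hover tooltips (sample id + MC per point) — no scripting dependency, and
  the files open anywhere, consistent with fully offline operation.
- Test and acceptance problem sizes (2,000-probe space, 160–320-sample
  references, 1,500-read CNV runs, 100 CNV replicates) are the package's
  chosen desk-scale study conditions; every rate reported by
  `scripts/acceptance.py` is recomputed from scratch at run time.

## Known limitations

- UMAP coordinates are platform-dependent at the bit level; determinism is
  guaranteed per platform, not across BLAS/numba versions.
- One-of-a-kind queries are pulled toward the best-matching cluster rather
  than placed apart — an inherent property of neighbour-based reading of a
  UMAP plot; no confidence score is provided, by design.
- The nanopore path embeds one sparse query at a time (its covered probes
  define the feature space); batching sparse queries with differing
  coverage is not defined.
- Copy-number output is descriptive (binned log2 ratios); no segmentation,
  focal-event calling, or purity correction.
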