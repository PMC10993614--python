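"""methylomap: harmonized DNA-methylation profiling for tumour diagnostics.

Harmonizes methylation measurements from microarrays, targeted methylation
sequencing and nanopore sequencing onto a shared overlap-CpG probe space,
classifies samples by joint UMAP embedding and majority vote over the nearest
annotated neighbours, profiles copy number from low-coverage read positions
by adaptive binning, and benchmarks classification agreement at methylation-
class and superclass level.
"""

from .probe_store import (
    FILL_VALUE,
    BetaMatrix,
    BetaVector,
    ProbeSet,
    build_probeset,
    load_betas,
    save_betas,
)
from .harmonize import (
    BedGraphRecord,
    SiteCall,
    SparseBetaVector,
    bedgraph_to_betas,
    nanopore_calls_to_betas,
    read_beta_table,
)
from .classify import (
    AnnotationTable,
    ClassificationResult,
    Embedding,
    UmapParams,
    classify_queries,
    embed,
    nearest_annotated,
    qc_dnadeg,
    select_tdmp,
    vote,
)
from .cnv import (
    BinnedCoverage,
    GenomeTable,
    ReadPosition,
    bin_reads,
    compute_bin_size,
    hg19_genome,
    normalize_bins,
)
from .benchmark import (
    BenchmarkResult,
    match_fraction,
    removal_robustness,
    tdmp_sweep,
)

__version__ = "0.1.0"
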