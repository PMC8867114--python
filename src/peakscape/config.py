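"""Pipeline-wide parameters.

A single :class:`PipelineConfig` instance carries every numeric convention
used downstream of read mapping and peak calling: the fragment extension
size, the depth-normalization target, bin widths, the annotation windows
around TSS/TES, the asymmetric replicate-consensus p-value thresholds and
the RNA-seq gene filters.  All windows are expressed in *stranded gene
coordinates*: 0 is the anchor (TSS or TES), positive offsets point in the
direction of transcription, and the windows are half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    #: fragment size each tag is extended to from its 5' end (MACS2 --extsize)
    extsize: int = 200
    #: depth-normalization target: tracks are scaled to this many mapped tags
    norm_target_reads: int = 10_000_000
    #: coverage-track bin width in bp
    track_bin: int = 10
    #: half-width of the TSS metaprofile window in bp
    metaprofile_flank: int = 2500
    #: half-width of summit-centered sequence windows for motif input
    summit_flank: int = 500
    #: peak p-value ceiling for the best replicate
    p_best: float = 0.01
    #: peak p-value ceiling for the other replicate(s)
    p_other: float = 0.05
    #: replicate support rule: a best-replicate peak must overlap peaks in
    #: every other replicate ("all") or in at least one ("any")
    consensus_mode: str = "all"
    #: annotation windows, stranded gene coordinates, half-open
    upstream_window: tuple[int, int] = (-5000, -1000)
    promoter_window: tuple[int, int] = (-1000, 500)
    tes_window: tuple[int, int] = (-500, 1000)
    downstream_window: tuple[int, int] = (1000, 5000)
    #: RNA-seq gene filters
    min_gene_length: int = 200
    excluded_chroms: frozenset[str] = frozenset({"chrY"})
    excluded_biotypes: frozenset[str] = frozenset({"rRNA"})
    #: flip metaprofile bins of minus-strand genes so bin index runs 5'->3'
    orient_metaprofile_by_strand: bool = True
    #: tag extension semantics: "extsize" replaces the read by an
    #: ``extsize`` bp fragment from its 5' end; "append" keeps the read and
    #: adds ``extsize`` bp past its 3' terminus
    extension_mode: str = "extsize"
    #: t-test options for expression stratification
    log_transform_fpkm: bool = True
    pooled_variance: bool = False
    #: binding definition: promoter-window overlap or annotation category
    binding_def: str = "promoter-overlap"
    #: library size for FPKM computed over post-filter genes (True) or the
    #: full input table (False)
    library_size_post_filter: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_best <= 1 and 0 < self.p_other <= 1):
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.consensus_mode not in ("all", "any"):
            raise ValueError("consensus_mode must be 'all' or 'any'")
        if self.extension_mode not in ("extsize", "append"):
            raise ValueError("extension_mode must be 'extsize' or 'append'")
        if self.binding_def not in ("promoter-overlap", "assigned-category"):
            raise ValueError(
                "binding_def must be 'promoter-overlap' or 'assigned-category'"
            )
        for name in ("extsize", "track_bin", "metaprofile_flank", "summit_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "upstream_window",
            "promoter_window",
            "tes_window",
            "downstream_window",
        ):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be an increasing (lo, hi) pair")


DEFAULT_CONFIG = PipelineConfig()
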