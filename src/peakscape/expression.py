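"""Linking promoter binding to expression level.

Genes are filtered (short genes, rRNA biotypes, chrY), per-replicate FPKM
is computed from fragment-count tables over union-exon lengths, replicate
FPKMs are averaged, genes are stratified by which factor binds their
promoter window, and group expression differences are tested with a
two-sided t test (Welch on log2(FPKM+1) by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .intervals import GeneModel, IntervalIndex, PeakSet, stranded_window
from .setops import shared_and_exclusive_genes

log = logging.getLogger(__name__)

GROUPS = ("nonbound", "dual", "A_only", "B_only")


@dataclass
class ExpressionRecord:
    gene_id: str
    counts: tuple[int, ...]
    union_exon_length: int
    fpkm_per_replicate: tuple[float, ...]
    fpkm_mean: float
    group: str = "nonbound"


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    degrees_of_freedom: float
    p_value: float


def filter_genes(
    genes: list[GeneModel], cfg: PipelineConfig
) -> tuple[list[GeneModel], dict[str, int]]:
    """Drop short genes, excluded biotypes and excluded chromosomes.

    A gene failing several criteria is attributed to the first matching
    rule (length, then biotype, then chromosome) in the removal counts.
    """
    kept: list[GeneModel] = []
    removed = {"short": 0, "biotype": 0, "chrom": 0}
    for g in genes:
        if g.union_exon_length < cfg.min_gene_length:
            removed["short"] += 1
        elif any(b in g.biotype for b in cfg.excluded_biotypes):
            removed["biotype"] += 1
        elif g.chrom in cfg.excluded_chroms:
            removed["chrom"] += 1
        else:
            kept.append(g)
    if any(removed.values()):
        log.info("gene filter removed %s", removed)
    return kept, removed


def read_counts_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-gene fragment-count TSV (gene_id + one column per
    replicate).  htseq-count summary rows (``__no_feature`` etc.) are
    dropped and logged."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    summary = df.index.astype(str).str.startswith("__")
    if summary.any():
        log.info("dropped %d htseq-count summary rows", int(summary.sum()))
        df = df.loc[~summary]
    return df


def fpkm(
    counts: pd.DataFrame,
    genes: list[GeneModel],
    cfg: PipelineConfig,
) -> list[ExpressionRecord]:
    """Per-replicate and replicate-averaged FPKM for every counted gene.

    For replicate r, ``FPKM_gr = counts_gr * 1e9 / (L_g * T_r)`` with
    ``L_g`` the union-exon length and ``T_r`` the replicate's total
    fragment count over the genes of the table (which, in the default
    pipeline, is the post-filter gene set).
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in counts.index if g not in by_id]
    if missing:
        raise KeyError(
            f"counts table contains genes absent from the gene models: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative fragment counts")
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        zero = [c for c, t in zip(counts.columns, totals) if t == 0]
        raise ValueError(f"replicate(s) with zero total fragments: {zero}")
    lengths = np.array([by_id[g].union_exon_length for g in counts.index], dtype=float)
    fpkm_mat = mat * 1e9 / (lengths[:, None] * totals[None, :])
    return [
        ExpressionRecord(
            gene_id=g,
            counts=tuple(int(c) for c in mat[i]),
            union_exon_length=int(lengths[i]),
            fpkm_per_replicate=tuple(float(x) for x in fpkm_mat[i]),
            fpkm_mean=float(fpkm_mat[i].mean()),
        )
        for i, g in enumerate(counts.index)
    ]


def bound_genes(
    final_peaks: PeakSet, genes: list[GeneModel], cfg: PipelineConfig
) -> set[str]:
    """Genes whose promoter window is touched (>=1 bp) by a final peak.

    The promoter window is ``cfg.promoter_window`` in stranded gene
    coordinates around the TSS.
    """
    index = IntervalIndex(final_peaks.intervals())
    bound: set[str] = set()
    for g in genes:
        win = stranded_window(g, g.tss, cfg.promoter_window)
        if win is not None and index.overlaps_any(win.chrom, win.start, win.end):
            bound.add(g.gene_id)
    return bound


def assign_groups(
    records: list[ExpressionRecord],
    bound_a: set[str],
    bound_b: set[str],
    filtered_gene_ids: Iterable[str],
) -> list[ExpressionRecord]:
    """Attach a binding group to each expression record.

    Genes absent from the filtered universe are labeled ``excluded``;
    the rest get dual / A_only / B_only / nonbound from promoter-binding
    membership.
    """
    universe = set(filtered_gene_ids)
    labels = shared_and_exclusive_genes(
        bound_a & universe,
        bound_b & universe,
        universe,
        labels=("A_only", "B_only", "dual", "nonbound"),
    )
    for r in records:
        r.group = labels.get(r.gene_id, "excluded")
    return records


def compare_groups(
    records: list[ExpressionRecord],
    groups: Sequence[str] = ("nonbound", "dual", "A_only"),
    cfg: Optional[PipelineConfig] = None,
) -> list[GroupComparison]:
    """Two-sided t test of expression between every pair of groups.

    Defaults to Welch's unequal-variance test on log2(FPKM_mean + 1);
    ``cfg.log_transform_fpkm=False`` tests raw FPKM and
    ``cfg.pooled_variance=True`` uses the pooled (Student) form.
    """
    cfg = cfg or PipelineConfig()
    by_group: dict[str, np.ndarray] = {}
    for g in groups:
        vals = np.array([r.fpkm_mean for r in records if r.group == g], dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {g!r} has {len(vals)} genes; need >=3")
        by_group[g] = np.log2(vals + 1.0) if cfg.log_transform_fpkm else vals
    out: list[GroupComparison] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a, b = by_group[ga], by_group[gb]
            res = stats.ttest_ind(a, b, equal_var=cfg.pooled_variance)
            out.append(
                GroupComparison(
                    group_a=ga,
                    group_b=gb,
                    n_a=len(a),
                    n_b=len(b),
                    statistic=float(res.statistic),
                    degrees_of_freedom=float(res.df),
                    p_value=float(res.pvalue),
                )
            )
    return out


def expression_table(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Long-format table (boxplot-ready): one row per gene with FPKMs and
    binding group."""
    n_reps = len(records[0].fpkm_per_replicate) if records else 0
    data = {
        "gene_id": [r.gene_id for r in records],
        "union_exon_length": [r.union_exon_length for r in records],
        **{
            f"counts_rep{i + 1}": [r.counts[i] for r in records]
            for i in range(n_reps)
        },
        **{
            f"fpkm_rep{i + 1}": [r.fpkm_per_replicate[i] for r in records]
            for i in range(n_reps)
        },
        "fpkm_mean": [r.fpkm_mean for r in records],
        "log2_fpkm_mean": [float(np.log2(r.fpkm_mean + 1.0)) for r in records],
        "group": [r.group for r in records],
    }
    return pd.DataFrame(data)
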