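"""End-to-end driver over a synthetic dataset.

Chains every stage — simulation, blacklist/threshold/consensus, nearest-TSS
annotation, Venn overlap of the two factors' final peak lists, normalized
TSS metaprofiles, and expression stratification with the group t test —
and optionally writes all outputs as plain-text files.  Exists so that the
whole analysis is reproducible from one seed, and is what the examples and
the acceptance script drive.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .annotation import annotation_table, genomic_distribution
from .config import PipelineConfig
from .consensus import consensus_pipeline
from .expression import (
    assign_groups,
    bound_genes,
    compare_groups,
    expression_table,
    filter_genes,
    fpkm,
)
from .io import write_narrowpeak
from .setops import venn_counts
from .signal import tss_metaprofile, write_bedgraph, track_from_tags
from .simulate import SimConfig, evaluate_consensus, simulate_dataset


def run_synthetic_analysis(
    sim_cfg: Optional[SimConfig] = None,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 7,
    outdir: Optional[Union[str, Path]] = None,
    include_signal: bool = True,
):
    """Simulate one dataset and run the full downstream analysis.

    Returns a dict of in-memory results; with ``outdir`` every artifact is
    also written as deterministic plain text (two runs with the same
    config and seed produce byte-identical trees).
    """
    sim_cfg = sim_cfg or SimConfig()
    cfg = cfg or PipelineConfig()
    ds = simulate_dataset(sim_cfg, seed=seed, with_tags=include_signal)
    out: dict = {"dataset": ds, "finals": {}, "reports": {}, "evaluation": {}}

    for factor in ("A", "B"):
        reps = ds.peaks[factor]
        final, report = consensus_pipeline(reps[0], reps[1:], ds.blacklist, cfg)
        out["finals"][factor] = final
        out["reports"][factor] = report
        out["evaluation"][factor] = evaluate_consensus(final, ds.truth, factor)

    genes = ds.annotation.genes
    out["distributions"] = {}
    out["annotations"] = {}
    for factor in ("A", "B"):
        dist, results = genomic_distribution(out["finals"][factor], genes, cfg)
        out["distributions"][factor] = dist
        out["annotations"][factor] = results

    out["venn"] = venn_counts(
        [out["finals"]["A"], out["finals"]["B"]]
    )

    if include_signal:
        lengths = ds.annotation.chrom_lengths
        out["metaprofile_chip"] = tss_metaprofile(ds.tags["A"][0], genes, lengths, cfg)
        out["metaprofile_input"] = tss_metaprofile(ds.input_tags, genes, lengths, cfg)

    filtered, removed = filter_genes(genes, cfg)
    universe = [g.gene_id for g in filtered]
    counts = ds.counts.loc[ds.counts.index.intersection(universe)]
    records = fpkm(counts, filtered, cfg)
    bound = {
        factor: bound_genes(out["finals"][factor], filtered, cfg)
        for factor in ("A", "B")
    }
    assign_groups(records, bound["A"], bound["B"], universe)
    out["records"] = records
    out["gene_filter_removed"] = removed
    out["comparisons"] = compare_groups(records, cfg=cfg)

    if outdir is not None:
        _write_outputs(Path(outdir), out, cfg)
    return out


def _write_outputs(outdir: Path, out: dict, cfg: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ds = out["dataset"]
    ds.write(outdir / "simulated")
    for factor in ("A", "B"):
        write_narrowpeak(out["finals"][factor], outdir / f"final_{factor}.narrowPeak")
        (outdir / f"consensus_report_{factor}.json").write_text(
            json.dumps(out["reports"][factor].as_dict(), indent=2) + "\n"
        )
        out["distributions"][factor].to_csv(
            outdir / f"distribution_{factor}.tsv", sep="\t", index=False
        )
        annotation_table(out["annotations"][factor]).to_csv(
            outdir / f"annotation_{factor}.tsv", sep="\t", index=False
        )
    (outdir / "venn.json").write_text(
        json.dumps(out["venn"].as_dict(), indent=2) + "\n"
    )
    if "metaprofile_chip" in out:
        chip, inp = out["metaprofile_chip"], out["metaprofile_input"]
        lines = ["bin_center_offset\tchip_mean\tinput_mean"]
        for off, c, i in zip(chip.bin_center_offsets, chip.values, inp.values):
            lines.append(f"{off:g}\t{c:.6g}\t{i:.6g}")
        (outdir / "metaprofile_A.tsv").write_text("\n".join(lines) + "\n")
        track = track_from_tags(
            ds.tags["A"][0], ds.annotation.chrom_lengths, cfg
        )
        write_bedgraph(track, outdir / "pileup_A_rep1.bedGraph")
    expression_table(out["records"]).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    (outdir / "comparisons.json").write_text(
        json.dumps([dataclasses.asdict(c) for c in out["comparisons"]], indent=2)
        + "\n"
    )
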