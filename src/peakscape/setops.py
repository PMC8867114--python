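"""Multi-set peak comparison (Venn-style membership counts).

Peaks from two or three sets are pooled and merged with >=1 bp overlap
chaining; each merged region's membership is the set of sources that
contributed at least one overlapping peak to it.  Counts are of merged
regions per membership combination — not of original peaks — so three-set
totals need not match any single input's peak count; the result carries
both numbers to avoid misreading.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping

from .intervals import IntervalIndex, PeakSet


@dataclass
class VennResult:
    set_names: tuple[str, ...]
    #: membership subset (tuple ordered like set_names) -> merged-region count
    counts: dict[tuple[str, ...], int]
    n_merged: int
    n_input: dict[str, int]

    def count(self, *names: str) -> int:
        key = tuple(n for n in self.set_names if n in names)
        return self.counts[key]

    def as_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "counts": {"&".join(k): v for k, v in self.counts.items()},
            "n_merged": self.n_merged,
            "n_input_peaks": self.n_input,
        }


def _subsets(names: tuple[str, ...]) -> list[tuple[str, ...]]:
    return list(
        chain.from_iterable(
            combinations(names, r) for r in range(1, len(names) + 1)
        )
    )


def venn_counts(sets: list[PeakSet]) -> VennResult:
    """Merged-region counts per membership combination of 2 or 3 peak sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn analysis takes 2 or 3 peak sets, got {len(sets)}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError("peak set names must be distinct")
    for s in sets:
        if len(s) == 0:
            raise ValueError(f"peak set {s.name!r} is empty")
    pooled = [iv for s in sets for iv in s.intervals()]
    index = IntervalIndex(pooled)  # merges on construction
    # membership[(chrom, region_idx)] = set of contributing source names
    membership: dict[tuple[str, int], set[str]] = {}
    for s in sets:
        for p in s:
            hit = index.which(p.chrom, p.start, p.end)
            # every peak lies inside exactly one merged region
            membership.setdefault((p.chrom, hit), set()).add(s.name)
    counts = {sub: 0 for sub in _subsets(names)}
    for members in membership.values():
        key = tuple(n for n in names if n in members)
        counts[key] += 1
    return VennResult(
        set_names=names,
        counts=counts,
        n_merged=len(membership),
        n_input={s.name: len(s) for s in sets},
    )


def shared_and_exclusive_genes(
    bound_a: Iterable[str],
    bound_b: Iterable[str],
    universe: Iterable[str],
    labels: tuple[str, str, str, str] = ("A_only", "B_only", "dual", "none"),
) -> dict[str, str]:
    """Label every gene of ``universe`` by its promoter-binding membership.

    ``bound_a``/``bound_b`` are the promoter-bound gene sets of two
    factors over the same gene universe; each gene gets exactly one of
    the four labels.
    """
    a, b, uni = set(bound_a), set(bound_b), set(universe)
    stray = (a | b) - uni
    if stray:
        raise ValueError(
            f"bound genes outside the shared gene universe: {sorted(stray)[:5]}"
        )
    a_only, b_only, dual, none = labels
    out: dict[str, str] = {}
    for g in uni:
        in_a, in_b = g in a, g in b
        out[g] = dual if (in_a and in_b) else a_only if in_a else b_only if in_b else none
    return out
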