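"""Overlap between peak sets: pairs, merged peaks, Venn counts, significance.

Two regions "overlap under maxgap g" iff at most g bases separate them
(``gap(a, b) <= g``); maxgap 0 therefore includes abutting intervals.
Merged peaks are connected components of the overlap graph across all input
sets, each spanned by the minimal covering interval.

Significance of the overlap between two sets is an upper-tail
hypergeometric test: with ``total_test`` potential peaks in the genome, n1
of which belong to set 1, drawing n2 for set 2 yields k or more shared
peaks with probability ``P(X >= k)``.  ``total_test`` is a user-supplied
universe size (e.g. the number of placeable binding sites), never estimated
from the data.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .errors import ValidationError
from .regions import GenomicRegion, RegionSet, gap


@dataclass(frozen=True)
class OverlapPair:
    """A pair of overlapping peaks from two sets plus their merged span."""

    peak1: GenomicRegion
    peak2: GenomicRegion
    merged: GenomicRegion  # [min start, max end], named "name1;name2"


@dataclass(frozen=True)
class Component:
    """One connected component of the cross-set overlap graph.

    ``members`` holds (set_index, region) pairs; ``pattern`` is a 0/1
    string, one character per input set, marking which sets contribute at
    least one region; ``span`` is the minimal interval covering every
    member.
    """

    members: tuple[tuple[int, GenomicRegion], ...]
    pattern: str
    span: GenomicRegion

    def involves(self, set_index: int) -> bool:
        return self.pattern[set_index] == "1"


@dataclass(frozen=True)
class PairwiseOverlap:
    """Hypergeometric overlap test between two sets (computed on them alone)."""

    label1: str
    label2: str
    n1: int          # components involving set 1
    n2: int          # components involving set 2
    k: int           # components involving both
    p_value: float


@dataclass(frozen=True)
class VennReport:
    labels: tuple[str, ...]
    cell_counts: dict[str, int]        # membership pattern -> count
    pairwise: tuple[PairwiseOverlap, ...]
    total_test: int


def find_overlapping_pairs(
    set1: RegionSet,
    set2: RegionSet,
    maxgap: int = 0,
    multiple: bool = True,
) -> list[OverlapPair]:
    """All (peak1, peak2) pairs with ``gap <= maxgap``, plus merged spans.

    With ``multiple=False`` each set-1 peak keeps only its closest partner
    (smallest gap; ties broken by leftmost set-2 start, then name).
    """
    if maxgap < 0:
        raise ValidationError(f"maxgap must be >= 0, got {maxgap}")
    pairs: list[OverlapPair] = []
    for chrom in set1.chromosomes():
        partners = set2.on_chromosome(chrom)
        if not partners:
            continue
        for p1 in set1.on_chromosome(chrom):
            hits = [p2 for p2 in partners if gap(p1, p2) <= maxgap]
            if not hits:
                continue
            if not multiple:
                hits = [min(hits, key=lambda p2: (gap(p1, p2), p2.start, p2.name))]
            for p2 in hits:
                merged = GenomicRegion(
                    chrom,
                    min(p1.start, p2.start),
                    max(p1.end, p2.end),
                    f"{p1.name};{p2.name}",
                )
                pairs.append(OverlapPair(p1, p2, merged))
    return pairs


def merge_connected(sets: Sequence[RegionSet], maxgap: int = 0) -> list[Component]:
    """Connected components of the overlap graph over all regions of all sets.

    Overlap is transitive through chains: regions A-B and B-C overlapping
    puts A, B, C in one component even if A and C are far apart.  Implemented
    as a per-chromosome sweep (intervals sorted by start; a region joins the
    open component while its start is within ``maxgap`` of the running
    maximum end), which is equivalent to union-find on the full pairwise
    gap matrix for interval graphs.
    """
    if len(sets) < 2:
        raise ValidationError("merge_connected needs at least 2 region sets")
    if maxgap < 0:
        raise ValidationError(f"maxgap must be >= 0, got {maxgap}")
    tagged = [
        (region, set_index)
        for set_index, regionset in enumerate(sets)
        for region in regionset
    ]
    by_chrom: dict[str, list[tuple[GenomicRegion, int]]] = {}
    for region, set_index in tagged:
        by_chrom.setdefault(region.chrom, []).append((region, set_index))

    components: list[Component] = []

    def close(chrom: str, members: list[tuple[int, GenomicRegion]]) -> None:
        start = min(r.start for _, r in members)
        end = max(r.end for _, r in members)
        pattern = "".join(
            "1" if any(i == s for i, _ in members) else "0"
            for s in range(len(sets))
        )
        name = ";".join(r.name for _, r in members)
        components.append(
            Component(tuple(members), pattern, GenomicRegion(chrom, start, end, name))
        )

    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end, t[0].name))
        open_members: list[tuple[int, GenomicRegion]] = []
        max_end = None
        for region, set_index in entries:
            if max_end is not None and region.start - max_end - 1 <= maxgap:
                open_members.append((set_index, region))
                max_end = max(max_end, region.end)
            else:
                if open_members:
                    close(chrom, open_members)
                open_members = [(set_index, region)]
                max_end = region.end
        if open_members:
            close(chrom, open_members)
    return components


def hypergeometric_overlap_pvalue(
    n1: int, n2: int, k: int, total_test: int
) -> float:
    """Upper-tail overlap p-value ``P(X >= k)``, X ~ Hypergeom(N, n1, n2).

    ``total_test`` is the universe size N (number of potential peaks), n1
    the number of marked peaks (set 1), n2 the number drawn (set 2) and k
    the observed overlap.  Preconditions are enforced, never clamped.
    """
    for name, value in (("n1", n1), ("n2", n2), ("k", k), ("total_test", total_test)):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    if k > min(n1, n2):
        raise ValidationError(f"k ({k}) exceeds min(n1, n2) = {min(n1, n2)}")
    if max(n1, n2) > total_test:
        raise ValidationError(
            f"set sizes ({n1}, {n2}) exceed total_test ({total_test})"
        )
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates the exact
    # sum with log-space internals, stable far into the tail
    p = float(hypergeom.sf(k - 1, total_test, n1, n2))
    return min(1.0, max(0.0, p))


def venn_report(
    sets: Sequence[RegionSet],
    maxgap: int = 0,
    total_test: int | None = None,
    count_mode: str = "component",
) -> VennReport:
    """Venn cell counts and pairwise overlap significance for 2-3 peak sets.

    Cell counts come from the membership patterns of the merged connected
    components; with ``count_mode="component"`` each component contributes
    1 to its pattern's cell, with ``count_mode="set1"`` it contributes the
    number of regions it holds from the lowest-indexed participating set.
    Pairwise tests are recomputed on each pair of sets alone, so a 3-set
    report agrees with its 2-set projections.
    """
    if not 2 <= len(sets) <= 3:
        raise ValidationError(
            f"venn_report supports 2 or 3 region sets, got {len(sets)}"
        )
    if count_mode not in ("component", "set1"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    if total_test is None:
        raise ValidationError("total_test (hypergeometric universe size) is required")
    if total_test < max(len(s) for s in sets):
        raise ValidationError(
            f"total_test ({total_test}) is smaller than the largest set "
            f"({max(len(s) for s in sets)})"
        )
    labels = tuple(s.label for s in sets)
    if len(set(labels)) != len(labels):
        raise ValidationError(f"set labels must be distinct, got {labels}")

    cell_counts: dict[str, int] = {}
    for comp in merge_connected(sets, maxgap=maxgap):
        if count_mode == "component":
            weight = 1
        else:
            first = comp.pattern.index("1")
            weight = sum(1 for i, _ in comp.members if i == first)
        cell_counts[comp.pattern] = cell_counts.get(comp.pattern, 0) + weight

    pairwise: list[PairwiseOverlap] = []
    for i, j in itertools.combinations(range(len(sets)), 2):
        comps = merge_connected([sets[i], sets[j]], maxgap=maxgap)
        n_i = sum(1 for c in comps if c.involves(0))
        n_j = sum(1 for c in comps if c.involves(1))
        k = sum(1 for c in comps if c.involves(0) and c.involves(1))
        if total_test < max(n_i, n_j):
            raise ValidationError(
                f"total_test ({total_test}) < number of merged peaks "
                f"({max(n_i, n_j)}) for pair ({labels[i]}, {labels[j]})"
            )
        p = hypergeometric_overlap_pvalue(n_i, n_j, k, total_test)
        pairwise.append(PairwiseOverlap(labels[i], labels[j], n_i, n_j, k, p))

    return VennReport(labels, cell_counts, tuple(pairwise), total_test)


# -- tabular output ---------------------------------------------------------

def write_merged_peaks_tsv(
    components: Iterable[Component], path: str | os.PathLike
) -> None:
    """One row per component: id, pattern, span, member names."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("component\tpattern\tchrom\tstart\tend\tmembers\n")
        for idx, comp in enumerate(components, 1):
            members = ";".join(r.name for _, r in comp.members)
            handle.write(
                f"component_{idx}\t{comp.pattern}\t{comp.span.chrom}\t"
                f"{comp.span.start}\t{comp.span.end}\t{members}\n"
            )


def write_venn_tsv(report: VennReport, path: str | os.PathLike) -> None:
    """Venn cell counts followed by the pairwise hypergeometric tests."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("# labels: " + "\t".join(report.labels) + "\n")
        handle.write(f"# total_test: {report.total_test}\n")
        handle.write("pattern\tcount\n")
        for pattern in sorted(report.cell_counts):
            handle.write(f"{pattern}\t{report.cell_counts[pattern]}\n")
        handle.write("label1\tlabel2\tn1\tn2\tk\tp_value\n")
        for pw in report.pairwise:
            handle.write(
                f"{pw.label1}\t{pw.label2}\t{pw.n1}\t{pw.n2}\t{pw.k}\t"
                f"{pw.p_value:.6g}\n"
            )
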