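"""Deterministic synthetic fixtures: genomes, gene models, peak sets, GO maps.

Everything derives from one integer seed through fixed per-generator
substreams (``numpy.random.SeedSequence(seed, spawn_key=(stream,))``), so
an identical :class:`FixtureSpec` reproduces byte-identical files and
adding a new generator never shifts the output of an existing one.

Peak placement modes:

* ``uniform`` — peaks dropped uniformly on the genome;
* ``planted_offset`` — each peak's start is placed exactly d bases 5' of a
  random gene's TSS (strand-aware), so nearest-TSS annotation must recover
  a signed distance of exactly -d;
* ``planted_overlap`` — a fixed fraction of peaks intersects a partner
  region set, the remainder is placed clear of it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .go import ASPECTS, GeneTermMap
from .io import write_bed, write_gff
from .regions import GenomicRegion, RegionSet, gap

# substream ids; order is append-only
_STREAM_GENOME = 0
_STREAM_GENES = 1
_STREAM_PEAKS = 2
_STREAM_GOMAP = 3

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset (see module docstring).

    Defaults sketch a compact genome: 2 chromosomes of 100 kb carrying 100
    single-interval genes of 0.5-2 kb and 50 peaks of 100-400 bp — sizes in
    the range peak callers report for yeast-scale experiments, small enough
    that brute-force oracles stay instant.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 100
    gene_length: tuple[int, int] = (500, 2000)
    forward_strand_prob: float = 0.5
    min_gene_gap: int = 1
    n_peaks: int = 50
    peak_width: tuple[int, int] = (100, 400)
    placement: str = "uniform"
    planted_offset_distance: int = 0
    planted_overlap_fraction: float = 0.8
    n_terms: int = 30
    annotation_prob: float = 0.1


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(stream,)))


def _chrom_names(spec: FixtureSpec) -> list[str]:
    return [f"chr{i + 1}" for i in range(spec.n_chroms)]


def make_genome(spec: FixtureSpec, path: str | os.PathLike | None = None,
                width: int = 60) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosomes; optionally written as FASTA."""
    if spec.chrom_length < 1 or spec.n_chroms < 1:
        raise ValidationError("n_chroms and chrom_length must be >= 1")
    rng = _rng(spec, _STREAM_GENOME)
    genome = {
        name: "".join(_BASES[rng.integers(0, 4, size=spec.chrom_length)])
        for name in _chrom_names(spec)
    }
    if path is not None:
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            for name, seq in genome.items():
                handle.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    handle.write(seq[i:i + width] + "\n")
    return genome


def make_gene_models(
    spec: FixtureSpec, path: str | os.PathLike | None = None
) -> RegionSet:
    """Non-overlapping stranded single-interval genes, ids g0001, g0002, ...

    Genes are distributed as evenly as possible across chromosomes; within
    a chromosome, inter-gene gaps (>= ``min_gene_gap``) are drawn uniformly
    from the leftover space.  Raises when the requested genes cannot fit.
    """
    lo, hi = spec.gene_length
    if not 1 <= lo <= hi:
        raise ValidationError(f"bad gene_length range {spec.gene_length}")
    rng = _rng(spec, _STREAM_GENES)
    chroms = _chrom_names(spec)
    per_chrom = [spec.n_genes // len(chroms)] * len(chroms)
    for i in range(spec.n_genes % len(chroms)):
        per_chrom[i] += 1
    regions: list[GenomicRegion] = []
    gene_id = 0
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=count)
        required = int(lengths.sum()) + spec.min_gene_gap * (count - 1)
        free = spec.chrom_length - required
        if free < 0:
            raise ValidationError(
                f"cannot pack {count} genes (total {required} bases incl. "
                f"gaps) into {chrom} of length {spec.chrom_length}"
            )
        extra = rng.multinomial(free, [1.0 / (count + 1)] * (count + 1))
        pos = 1
        for i in range(count):
            pos += int(extra[i]) + (spec.min_gene_gap if i > 0 else 0)
            gene_id += 1
            strand = "+" if rng.random() < spec.forward_strand_prob else "-"
            regions.append(
                GenomicRegion(chrom, pos, pos + int(lengths[i]) - 1,
                              f"g{gene_id:04d}", strand)
            )
            pos += int(lengths[i])
    genes = RegionSet("genes", regions)
    if path is not None:
        write_gff(genes, path)
    return genes


def make_peaks(
    spec: FixtureSpec,
    genes: RegionSet | None = None,
    partner: RegionSet | None = None,
    path: str | os.PathLike | None = None,
    label: str = "peaks",
) -> RegionSet:
    """Generate a peak set in the placement mode given by the spec."""
    lo, hi = spec.peak_width
    if not 1 <= lo <= hi:
        raise ValidationError(f"bad peak_width range {spec.peak_width}")
    rng = _rng(spec, _STREAM_PEAKS)
    chroms = _chrom_names(spec)
    regions: list[GenomicRegion] = []

    if spec.placement == "uniform":
        for i in range(spec.n_peaks):
            w = int(rng.integers(lo, hi + 1))
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(1, spec.chrom_length - w + 2))
            regions.append(GenomicRegion(chrom, start, start + w - 1,
                                         f"{label}_{i + 1}"))
    elif spec.placement == "planted_offset":
        if genes is None or len(genes) == 0:
            raise ValidationError("planted_offset placement requires gene models")
        d = spec.planted_offset_distance
        if d < 0:
            raise ValidationError(f"planted offset must be >= 0, got {d}")
        gene_list = list(genes)
        made = 0
        while made < spec.n_peaks:
            w = int(rng.integers(lo, hi + 1))
            g = gene_list[int(rng.integers(0, len(gene_list)))]
            tss = g.start if g.strand == "+" else g.end
            # signed distance -d means start = TSS - d on '+', TSS + d on '-'
            start = tss - d if g.strand == "+" else tss + d
            if start < 1 or start + w - 1 > spec.chrom_length:
                continue  # resample near a gene that leaves room
            made += 1
            regions.append(GenomicRegion(g.chrom, start, start + w - 1,
                                         f"{label}_{made}"))
    elif spec.placement == "planted_overlap":
        if partner is None or len(partner) == 0:
            raise ValidationError("planted_overlap placement requires a partner set")
        frac = spec.planted_overlap_fraction
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"overlap fraction must be in [0,1], got {frac}")
        n_hit = round(frac * spec.n_peaks)
        partner_list = list(partner)
        for i in range(n_hit):
            w = int(rng.integers(lo, hi + 1))
            target = partner_list[int(rng.integers(0, len(partner_list)))]
            low = max(1, target.start - w + 1)
            high = min(target.end, spec.chrom_length - w + 1)
            start = int(rng.integers(low, high + 1))
            regions.append(GenomicRegion(target.chrom, start, start + w - 1,
                                         f"{label}_{i + 1}"))
        made = n_hit
        while made < spec.n_peaks:
            w = int(rng.integers(lo, hi + 1))
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(1, spec.chrom_length - w + 2))
            candidate = GenomicRegion(chrom, start, start + w - 1, "tmp")
            near = [p for p in partner.on_chromosome(chrom)
                    if gap(candidate, p) < 1]
            if near:
                continue  # rejection-sample until clear of the partner set
            made += 1
            regions.append(GenomicRegion(chrom, start, start + w - 1,
                                         f"{label}_{made}"))
    else:
        raise ValidationError(
            f"unknown placement mode {spec.placement!r}; expected uniform, "
            "planted_offset or planted_overlap"
        )

    peaks = RegionSet(label, regions)
    if path is not None:
        write_bed(peaks, path)
    return peaks


def make_go_map(
    spec: FixtureSpec,
    genes: RegionSet | Sequence[str],
    path: str | os.PathLike | None = None,
) -> GeneTermMap:
    """Random gene->term map: each (gene, term) pair annotated independently
    with probability ``annotation_prob``; term aspects cycle BP/MF/CC."""
    if spec.n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if not 0.0 <= spec.annotation_prob <= 1.0:
        raise ValidationError("annotation_prob must be in [0, 1]")
    rng = _rng(spec, _STREAM_GOMAP)
    gene_ids = [g.name for g in genes] if isinstance(genes, RegionSet) else list(genes)
    terms = [(f"GO:{i + 1:07d}", ASPECTS[i % len(ASPECTS)])
             for i in range(spec.n_terms)]
    annotations: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}
    hits = rng.random((len(gene_ids), len(terms))) < spec.annotation_prob
    for gi, gene in enumerate(gene_ids):
        for ti, (term, aspect) in enumerate(terms):
            if hits[gi, ti]:
                annotations[aspect].setdefault(gene, set()).add(term)
    gene_map = GeneTermMap(
        {a: {g: frozenset(t) for g, t in genes_.items()}
         for a, genes_ in annotations.items() if genes_},
        term_names={term: f"synthetic term {term[3:]}" for term, _ in terms},
    )
    if path is not None:
        with open(path, "wt", encoding="utf-8", newline="\n") as handle:
            for aspect in ASPECTS:
                for gene in sorted(gene_map.annotations.get(aspect, {})):
                    for term in sorted(gene_map.annotations[aspect][gene]):
                        handle.write(f"{gene}\t{term}\t{aspect}\n")
    return gene_map


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    """Convenience: the same fixture shape under a different seed."""
    return replace(spec, seed=seed)
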