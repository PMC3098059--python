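"""Core genomic-interval model.

Coordinates are **1-based and closed on both ends** throughout the package,
the convention used by GFF and by most wet-lab coordinate lists.  BED input
(0-based, half-open) is converted at the parsing boundary, never inside the
analysis code.  A width-1 interval therefore has ``start == end`` and
``width == end - start + 1``.

Strand is one of ``+``, ``-`` or ``*`` (unstranded).  Numeric strand tokens
(``1``/``-1``) and the GFF placeholder ``.`` are accepted on input and
canonicalized; see :func:`canonical_strand`.

Chromosome names are matched by exact string equality — ``chr1`` and ``1``
are different chromosomes.  Silent aliasing hides input errors; callers who
need renaming apply it before construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import ValidationError

#: Canonical strand symbols: forward, reverse, unstranded.
STRANDS = ("+", "-", "*")

_STRAND_ALIASES = {
    "+": "+",
    "-": "-",
    "*": "*",
    ".": "*",
    "1": "+",
    "-1": "-",
}


def canonical_strand(token: str | int) -> str:
    """Map an input strand token to one of ``+ - *``.

    Accepts the biological symbols ``+``/``-``, the numeric convention
    ``1``/``-1``, and the "no strand" placeholders ``.`` and ``*``.
    Anything else raises :class:`ValidationError`.
    """
    tok = str(token).strip()
    try:
        return _STRAND_ALIASES[tok]
    except KeyError:
        raise ValidationError(
            f"unknown strand symbol {token!r}; expected one of + - . * 1 -1"
        ) from None


@dataclass(frozen=True)
class GenomicRegion:
    """One named genomic interval (a peak or an annotation feature).

    Parameters
    ----------
    chrom : str
        Chromosome (or contig) name; matched by exact string equality.
    start, end : int
        1-based closed coordinates, ``1 <= start <= end``.
    name : str
        Identifier, unique within a :class:`RegionSet`.
    strand : str
        ``+``, ``-`` or ``*`` (default: unstranded).
    score : float, optional
        Peak-caller score or similar; carried through I/O, never interpreted.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "*"
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not self.name:
            raise ValidationError("region name must be non-empty")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise ValidationError(
                f"coordinates of {self.name!r} must be integers, "
                f"got start={self.start!r} end={self.end!r}"
            )
        if self.start < 1:
            raise ValidationError(
                f"region {self.name!r}: start must be >= 1 (1-based closed), "
                f"got {self.start}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"region {self.name!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"region {self.name!r}: strand must be one of {STRANDS}, "
                f"got {self.strand!r}; use canonical_strand() on raw tokens"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def intersects(self, other: "GenomicRegion") -> bool:
        """True iff the two closed intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}={self.chrom}:{self.start}-{self.end}({self.strand})"


def gap(a: GenomicRegion, b: GenomicRegion) -> float:
    """Number of bases strictly between two regions.

    Returns ``math.inf`` for regions on different chromosomes, ``0`` for
    intersecting *or abutting* intervals, and otherwise the count of bases
    separating them (``right.start - left.end - 1`` for closed intervals).
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return math.inf
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end - 1)


class RegionSet:
    """A named, validated collection of :class:`GenomicRegion`.

    Region names must be unique within the set (annotation joins are keyed
    by name).  Iteration visits chromosomes in sorted order and regions
    within a chromosome sorted by ``(start, end, name)``, so per-chromosome
    starts are non-decreasing.
    """

    def __init__(self, label: str, regions: Iterable[GenomicRegion] = ()):
        if not label:
            raise ValidationError("RegionSet label must be non-empty")
        self.label = label
        self._by_name: dict[str, GenomicRegion] = {}
        by_chrom: dict[str, list[GenomicRegion]] = {}
        for region in regions:
            if region.name in self._by_name:
                raise ValidationError(
                    f"duplicate region name {region.name!r} in set {label!r}"
                )
            self._by_name[region.name] = region
            by_chrom.setdefault(region.chrom, []).append(region)
        self._by_chrom = {
            chrom: tuple(sorted(regs, key=lambda r: (r.start, r.end, r.name)))
            for chrom, regs in by_chrom.items()
        }

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self) -> Iterator[GenomicRegion]:
        for chrom in self.chromosomes():
            yield from self._by_chrom[chrom]

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> GenomicRegion:
        return self._by_name[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.label == other.label and list(self) == list(other)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({self.label!r}, n={len(self)})"

    # -- queries ------------------------------------------------------------

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_chrom))

    def on_chromosome(self, chrom: str) -> tuple[GenomicRegion, ...]:
        """All regions on one chromosome, sorted by (start, end, name)."""
        return self._by_chrom.get(chrom, ())

    def names(self) -> tuple[str, ...]:
        return tuple(self._by_name)
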