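"""Extract peak sequences with flanks from a FASTA genome, write FASTA.

Fetch regions are the peak interval extended by ``upstream`` bases to the
left and ``downstream`` to the right, silently clipped to the chromosome
(clipped peak names are logged at INFO).  Peaks are unstranded, so
sequences always come from the forward strand.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable

from pyfaidx import Fasta, FastaIndexingError, FastaNotFoundError

from .errors import ValidationError
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakSequence:
    """The retrieved sequence for one peak (after boundary clipping)."""

    name: str
    chrom: str
    fetch_start: int   # 1-based closed, >= 1
    fetch_end: int     # <= chromosome length
    sequence: str      # uppercase DNA, len == fetch_end - fetch_start + 1


class Genome:
    """A FASTA genome indexed by chromosome name (pyfaidx-backed)."""

    def __init__(self, path: str | os.PathLike):
        try:
            self._fasta = Fasta(str(path), duplicate_action="stop", rebuild=True)
        except FastaNotFoundError as exc:
            raise FileNotFoundError(str(exc)) from exc
        except FastaIndexingError as exc:
            raise ValidationError(f"cannot index FASTA {path}: {exc}") from exc
        except ValueError as exc:  # duplicate record ids
            raise ValidationError(f"bad FASTA {path}: {exc}") from exc
        self.lengths: dict[str, int] = {
            name: len(record) for name, record in self._fasta.items()
        }
        empty = [name for name, length in self.lengths.items() if length == 0]
        if empty:
            raise ValidationError(f"empty FASTA records in {path}: {empty}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand substring over 1-based closed [start, end]."""
        if chrom not in self.lengths:
            raise ValidationError(f"chromosome {chrom!r} not in genome")
        if start < 1 or end > self.lengths[chrom] or end < start:
            raise ValidationError(
                f"fetch {chrom}:{start}-{end} outside [1, {self.lengths[chrom]}]"
            )
        return str(self._fasta[chrom][start - 1:end])


def load_genome(path: str | os.PathLike) -> Genome:
    """Load a FASTA genome; record ids must be unique and non-empty."""
    return Genome(path)


def get_peak_sequences(
    peaks: RegionSet,
    upstream: int = 0,
    downstream: int = 0,
    genome: Genome | None = None,
) -> list[PeakSequence]:
    """Fetch each peak's sequence plus flanks, clipped to the chromosome.

    The fetch region is ``[start - upstream, end + downstream]`` clipped to
    ``[1, chromosome length]``.  Raises if any peak's chromosome is absent
    from the genome, listing the offending peaks.
    """
    if genome is None:
        raise ValidationError("a loaded genome is required")
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream and downstream must be >= 0")
    missing = [p.name for p in peaks if p.chrom not in genome]
    if missing:
        raise ValidationError(
            f"peak chromosomes not found in genome for peaks: {missing}"
        )
    out: list[PeakSequence] = []
    clipped: list[str] = []
    for peak in peaks:
        chrom_len = genome.lengths[peak.chrom]
        fetch_start = max(1, peak.start - upstream)
        fetch_end = min(chrom_len, peak.end + downstream)
        if fetch_start != peak.start - upstream or fetch_end != peak.end + downstream:
            clipped.append(peak.name)
        seq = genome.fetch(peak.chrom, fetch_start, fetch_end).upper()
        out.append(PeakSequence(peak.name, peak.chrom, fetch_start, fetch_end, seq))
    if clipped:
        logger.info("clipped fetch regions at chromosome boundaries for: %s",
                    ", ".join(clipped))
    return out


def write_fasta(
    seqs: Iterable[PeakSequence], path: str | os.PathLike, width: int = 50
) -> None:
    """Write peak sequences as wrapped FASTA.

    Headers are ``><name> <chrom>:<fetch_start>-<fetch_end>`` so the file
    is parseable by :func:`load_genome` (ids up to the first whitespace).
    Sequence lines are exactly ``width`` characters except the last.
    """
    if width < 1:
        raise ValidationError(f"width must be >= 1, got {width}")
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        for s in seqs:
            handle.write(f">{s.name} {s.chrom}:{s.fetch_start}-{s.fetch_end}\n")
            for i in range(0, len(s.sequence), width):
                handle.write(s.sequence[i:i + width] + "\n")
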