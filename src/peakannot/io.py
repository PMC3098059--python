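"""Readers and writers for BED, GFF/GTF and the package's TSV dialect.

Conversion rules applied at the boundary:

* BED is 0-based half-open: ``start = chromStart + 1``, ``end = chromEnd``.
* GFF/GTF is already 1-based closed and is taken verbatim.
* The TSV dialect is 1-based closed with header
  ``name chrom start end strand score`` and round-trips exactly.

Parsing is strict: malformed coordinates raise :class:`ParseError` naming
the file and line; duplicate names raise :class:`ValidationError` (from
:class:`RegionSet` construction).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError
from .regions import GenomicRegion, RegionSet, canonical_strand

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def _default_label(path: str | os.PathLike, label: str | None) -> str:
    return label if label is not None else Path(path).stem


def _parse_int(text: str, what: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", path, lineno) from None


def read_bed(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Read a BED file (>=3 columns) into a :class:`RegionSet`.

    Honors columns 1-6 (chrom, chromStart, chromEnd, name, score, strand);
    extra columns are ignored.  ``track``/``browser``/comment lines are
    skipped.  Missing names are auto-generated as ``peak_<k>`` counting data
    lines from 1.
    """
    regions: list[GenomicRegion] = []
    k = 0
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated columns, got {len(fields)}",
                    path, lineno,
                )
            chrom = fields[0]
            chrom_start = _parse_int(fields[1], "chromStart", path, lineno)
            chrom_end = _parse_int(fields[2], "chromEnd", path, lineno)
            if chrom_start < 0:
                raise ParseError(f"negative chromStart {chrom_start}", path, lineno)
            if chrom_end <= chrom_start:
                raise ParseError(
                    f"chromEnd ({chrom_end}) <= chromStart ({chrom_start})",
                    path, lineno,
                )
            k += 1
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{k}"
            score: float | None = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"non-numeric score {fields[4]!r}", path, lineno) from None
            strand = "*"
            if len(fields) > 5 and fields[5] != "":
                try:
                    strand = canonical_strand(fields[5])
                except ValidationError as exc:
                    raise ParseError(str(exc), path, lineno) from None
            regions.append(
                GenomicRegion(chrom, chrom_start + 1, chrom_end, name, strand, score)
            )
    return RegionSet(_default_label(path, label), regions)


def write_bed(regionset: RegionSet, path: str | os.PathLike) -> None:
    """Write a :class:`RegionSet` as 6-column BED (0-based half-open)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        for r in regionset:
            score = "." if r.score is None else format(r.score, "g")
            strand = "." if r.strand == "*" else r.strand
            handle.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\t{score}\t{strand}\n"
            )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    # Accepts both GFF3 "key=value;..." and GTF 'key "value"; ...' styles.
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
        else:
            bits = part.split(None, 1)
            if len(bits) != 2:
                continue
            key, value = bits
        out[key.strip()] = value.strip().strip('"')
    return out


def read_gff(
    path: str | os.PathLike,
    label: str | None = None,
    name_attribute: str | None = None,
) -> RegionSet:
    """Read a 9-column GFF/GTF file into a :class:`RegionSet`.

    Coordinates (columns 4-5) are 1-based closed and used verbatim.  The
    region name comes from attribute ``name_attribute`` when given, else
    ``ID``, else ``gene_id``, else ``Name``, else ``feature_<k>``.  Strand
    tokens ``+ - . 1 -1`` are accepted (``.`` becomes ``*``).
    """
    regions: list[GenomicRegion] = []
    k = 0
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"expected >=8 tab-separated GFF columns, got {len(fields)}",
                    path, lineno,
                )
            chrom = fields[0]
            start = _parse_int(fields[3], "start", path, lineno)
            end = _parse_int(fields[4], "end", path, lineno)
            if end < start:
                raise ParseError(f"end ({end}) < start ({start})", path, lineno)
            if start < 1:
                raise ParseError(f"start must be >= 1, got {start}", path, lineno)
            score: float | None = None
            if fields[5] not in ("", "."):
                try:
                    score = float(fields[5])
                except ValueError:
                    raise ParseError(f"non-numeric score {fields[5]!r}", path, lineno) from None
            try:
                strand = canonical_strand(fields[6])
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
            attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
            k += 1
            if name_attribute is not None:
                name = attrs.get(name_attribute)
                if name is None:
                    raise ParseError(
                        f"attribute {name_attribute!r} not found", path, lineno
                    )
            else:
                name = (
                    attrs.get("ID")
                    or attrs.get("gene_id")
                    or attrs.get("Name")
                    or f"feature_{k}"
                )
            regions.append(GenomicRegion(chrom, start, end, name, strand, score))
    return RegionSet(_default_label(path, label), regions)


def write_gff(
    regionset: RegionSet,
    path: str | os.PathLike,
    source: str = "peakannot",
    feature_type: str = "gene",
) -> None:
    """Write a :class:`RegionSet` as GFF3 (1-based closed, ``ID=`` names)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("##gff-version 3\n")
        for r in regionset:
            score = "." if r.score is None else format(r.score, "g")
            strand = "." if r.strand == "*" else r.strand
            handle.write(
                f"{r.chrom}\t{source}\t{feature_type}\t{r.start}\t{r.end}\t"
                f"{score}\t{strand}\t.\tID={r.name}\n"
            )


_TSV_HEADER = ("name", "chrom", "start", "end", "strand", "score")


def write_regions_tsv(regionset: RegionSet, path: str | os.PathLike) -> None:
    """Write the TSV dialect: header + one row per region, 1-based closed."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(_TSV_HEADER) + "\n")
        for r in regionset:
            score = "" if r.score is None else format(r.score, "g")
            handle.write(
                f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{score}\n"
            )


def read_regions_tsv(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Read the TSV dialect written by :func:`write_regions_tsv`."""
    regions: list[GenomicRegion] = []
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\r\n").split("\t")
        if tuple(header) != _TSV_HEADER:
            raise ParseError(
                f"bad TSV header {header!r}; expected {list(_TSV_HEADER)}", path, 1
            )
        for lineno, raw in enumerate(handle, 2):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_HEADER):
                raise ParseError(
                    f"expected {len(_TSV_HEADER)} columns, got {len(fields)}",
                    path, lineno,
                )
            name, chrom, start_s, end_s, strand_s, score_s = fields
            start = _parse_int(start_s, "start", path, lineno)
            end = _parse_int(end_s, "end", path, lineno)
            try:
                strand = canonical_strand(strand_s)
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
            score = None if score_s == "" else float(score_s)
            try:
                regions.append(GenomicRegion(chrom, start, end, name, strand, score))
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return RegionSet(_default_label(path, label), regions)


_READERS = {
    ".bed": read_bed,
    ".gff": read_gff,
    ".gff3": read_gff,
    ".gtf": read_gff,
    ".tsv": read_regions_tsv,
}


def read_regions(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Dispatch on file extension (.bed / .gff / .gff3 / .gtf / .tsv)."""
    suffix = Path(path).suffix.lower()
    reader = _READERS.get(suffix)
    if reader is None:
        raise ValidationError(
            f"cannot infer format of {path!r} from extension {suffix!r}; "
            f"expected one of {sorted(_READERS)}"
        )
    return reader(path, label=label)
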