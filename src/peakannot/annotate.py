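"""Annotate peaks with nearest-TSS and overlapping features.

The transcription start site (TSS) of a stranded feature is its 5' end:
``start`` on the forward strand, ``end`` on the reverse strand.  The signed
distance of a peak to a feature is measured from the **peak start** to the
TSS, oriented along the feature: negative means the peak start lies
upstream (5') of the TSS, positive downstream (3').  Peaks themselves are
treated as unstranded in every comparison.

Each peak/feature pair also gets a relative-position class
(``upstream``, ``downstream``, ``inside``, ``overlapStart``, ``overlapEnd``,
``includeFeature``) — mutually exclusive and exhaustive over all geometries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .regions import GenomicRegion, RegionSet, gap

NEAREST = "NearestStart"   # tag kept verbatim from the field's convention
OVERLAPPING = "Overlapping"

INSIDE_FEATURE_CLASSES = (
    "upstream",
    "downstream",
    "inside",
    "overlapStart",
    "overlapEnd",
    "includeFeature",
)

_OUTPUT_MODES = ("nearest", "overlapping", "both")


@dataclass(frozen=True)
class AnnotatedPeak:
    """One peak joined to one feature (or to nothing).

    ``feature`` is ``None`` when the peak had no candidate feature (no
    feature on its chromosome, or no overlap within ``maxgap``); the
    distance and class are then ``None`` as well.
    """

    peak: GenomicRegion
    feature: GenomicRegion | None
    distance_to_feature: int | None
    inside_feature: str | None
    from_overlapping_or_nearest: str


def _require_stranded(feature: GenomicRegion) -> None:
    if feature.strand not in ("+", "-"):
        raise ValidationError(
            f"feature {feature.name!r} is unstranded ('*'); TSS-based "
            "operations need stranded features — supply + or - strands"
        )


def feature_tss(feature: GenomicRegion) -> int:
    """1-based TSS coordinate of a stranded feature (5' boundary)."""
    _require_stranded(feature)
    return feature.start if feature.strand == "+" else feature.end


def signed_distance(peak: GenomicRegion, feature: GenomicRegion) -> int:
    """Signed peak-start-to-TSS distance, oriented along the feature.

    Negative: peak start is 5' (upstream) of the TSS; positive: 3'
    (downstream); zero: peak start coincides with the TSS.
    """
    tss = feature_tss(feature)
    if feature.strand == "+":
        return peak.start - tss
    return tss - peak.start


def classify_relative_position(peak: GenomicRegion, feature: GenomicRegion) -> str:
    """Relative-position class of a peak w.r.t. a stranded feature.

    The six classes partition all geometries: disjoint pairs are
    ``upstream``/``downstream`` in the feature's orientation; intersecting
    pairs are classified by which strand-aware boundaries (5' start, 3'
    end) the peak covers.
    """
    _require_stranded(feature)
    if feature.strand == "+":
        five_p, three_p = feature.start, feature.end
    else:
        five_p, three_p = feature.end, feature.start
    if not peak.intersects(feature):
        if peak.chrom != feature.chrom:
            raise ValidationError(
                f"peak {peak.name!r} and feature {feature.name!r} are on "
                "different chromosomes; relative position is undefined"
            )
        # Wholly on one side: decide 5' vs 3' in the feature's orientation.
        peak_is_left = peak.end < feature.start
        if feature.strand == "+":
            return "upstream" if peak_is_left else "downstream"
        return "downstream" if peak_is_left else "upstream"
    covers_5p = peak.start <= five_p <= peak.end
    covers_3p = peak.start <= three_p <= peak.end
    if covers_5p and covers_3p:
        return "includeFeature"
    if covers_5p:
        return "overlapStart"
    if covers_3p:
        return "overlapEnd"
    return "inside"


def _nearest_key(peak: GenomicRegion):
    def key(feature: GenomicRegion):
        d = signed_distance(peak, feature)
        # smallest |d|; ties upstream (d < 0) first, then by feature name
        return (abs(d), 0 if d < 0 else 1, feature.name)

    return key


def _feature_trees(features: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom in features.chromosomes():
        trees[chrom] = IntervalTree.from_tuples(
            (r.start, r.end + 1, r) for r in features.on_chromosome(chrom)
        )
    return trees


def _overlapping(
    trees: dict[str, IntervalTree], peak: GenomicRegion, maxgap: int
) -> list[GenomicRegion]:
    tree = trees.get(peak.chrom)
    if tree is None:
        return []
    # tree stores closed [start, end] as half-open [start, end+1); a feature
    # is within maxgap g iff f.start <= p.end + g + 1 and f.end >= p.start - g - 1
    hits = tree.overlap(peak.start - maxgap - 1, peak.end + maxgap + 2)
    return sorted((iv.data for iv in hits), key=lambda r: (r.start, r.end, r.name))


def _row(peak: GenomicRegion, feature: GenomicRegion | None, tag: str) -> AnnotatedPeak:
    if feature is None:
        return AnnotatedPeak(peak, None, None, None, tag)
    return AnnotatedPeak(
        peak,
        feature,
        signed_distance(peak, feature),
        classify_relative_position(peak, feature),
        tag,
    )


def annotate_peaks(
    peaks: RegionSet,
    features: RegionSet,
    output: str = "nearest",
    maxgap: int = 0,
    multiple: bool = False,
) -> list[AnnotatedPeak]:
    """Annotate every peak against a stranded feature set.

    Parameters
    ----------
    output : {"nearest", "overlapping", "both"}
        ``nearest``: one row per peak for the feature whose TSS minimizes
        the absolute signed distance.  ``overlapping``: rows for features
        within ``maxgap`` bases (``multiple=False`` keeps only the one with
        smallest absolute distance).  ``both``: the nearest rows plus those
        overlapping rows whose feature is not already the nearest one.
    maxgap : int
        Maximum number of bases allowed between peak and feature for them
        to count as overlapping; 0 includes abutting intervals.
    multiple : bool
        Whether a peak may report several overlapping features.

    Peaks with no candidate (no feature on the chromosome for
    nearest/both; no qualifying overlap for overlapping) yield a row with
    empty feature fields so every peak appears in the output.
    """
    if output not in _OUTPUT_MODES:
        raise ValidationError(
            f"unknown output mode {output!r}; expected one of {_OUTPUT_MODES}"
        )
    if maxgap < 0:
        raise ValidationError(f"maxgap must be >= 0, got {maxgap}")
    if len(peaks) == 0:
        raise ValidationError("peak set is empty")
    if len(features) == 0:
        raise ValidationError("feature set is empty")
    unstranded = [f.name for f in features if f.strand not in ("+", "-")]
    if unstranded:
        raise ValidationError(
            f"features must be stranded for TSS annotation; unstranded: "
            f"{unstranded[:5]}{'...' if len(unstranded) > 5 else ''}"
        )

    trees = _feature_trees(features)
    rows: list[AnnotatedPeak] = []
    for peak in peaks:
        candidates = features.on_chromosome(peak.chrom)
        nearest = min(candidates, key=_nearest_key(peak)) if candidates else None

        if output == "nearest":
            rows.append(_row(peak, nearest, NEAREST))
            continue

        overlapping = _overlapping(trees, peak, maxgap)
        if not multiple and overlapping:
            overlapping = [min(overlapping, key=_nearest_key(peak))]

        if output == "overlapping":
            if overlapping:
                rows.extend(_row(peak, f, OVERLAPPING) for f in overlapping)
            else:
                rows.append(_row(peak, None, OVERLAPPING))
        else:  # both
            rows.append(_row(peak, nearest, NEAREST))
            nearest_name = nearest.name if nearest is not None else None
            rows.extend(
                _row(peak, f, OVERLAPPING)
                for f in overlapping
                if f.name != nearest_name
            )
    return rows


@dataclass(frozen=True)
class DistanceHistogram:
    """Counts of nearest-TSS distances per half-open bin [edge_i, edge_{i+1}).

    Values below the first edge / at or above the last edge are reported in
    ``underflow`` / ``overflow``, not in ``counts``.
    """

    breaks: tuple[float, ...]
    counts: tuple[int, ...]
    underflow: int
    overflow: int

    @property
    def total(self) -> int:
        return sum(self.counts) + self.underflow + self.overflow


def distance_histogram(
    rows: Iterable[AnnotatedPeak], breaks: Sequence[float]
) -> DistanceHistogram:
    """Bin the nearest-TSS distances of an annotation result.

    Only rows tagged ``NearestStart`` with a defined distance contribute
    (the convention used when plotting distance-to-TSS histograms).  Bins
    are half-open on the right; out-of-range values go to the flanking
    underflow/overflow counters.
    """
    edges = np.asarray(list(breaks), dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValidationError("breaks must contain at least two edges")
    if not np.all(np.diff(edges) > 0):
        raise ValidationError("breaks must be strictly increasing")
    distances = [
        r.distance_to_feature
        for r in rows
        if r.from_overlapping_or_nearest == NEAREST and r.distance_to_feature is not None
    ]
    counts = [0] * (len(edges) - 1)
    underflow = overflow = 0
    for d in distances:
        idx = int(np.searchsorted(edges, d, side="right")) - 1
        if idx < 0:
            underflow += 1
        elif idx >= len(counts):
            overflow += 1
        else:
            counts[idx] += 1
    return DistanceHistogram(tuple(edges), tuple(counts), underflow, overflow)


def relative_position_counts(rows: Iterable[AnnotatedPeak]) -> dict[str, int]:
    """Tally relative-position classes, one contribution per kept row.

    Rows tagged ``Overlapping`` are always kept; ``NearestStart`` rows are
    kept only for peaks that have no ``Overlapping`` row — the convention
    used for relative-position pie charts, where an overlap is more
    informative than a possibly distant nearest gene.
    """
    rows = list(rows)
    overlapping_peaks = {
        r.peak.name for r in rows if r.from_overlapping_or_nearest == OVERLAPPING
        and r.feature is not None
    }
    counts: dict[str, int] = {}
    for r in rows:
        if r.feature is None:
            continue
        if r.from_overlapping_or_nearest == OVERLAPPING or (
            r.from_overlapping_or_nearest == NEAREST
            and r.peak.name not in overlapping_peaks
        ):
            counts[r.inside_feature] = counts.get(r.inside_feature, 0) + 1
    return counts


# -- tabular output ---------------------------------------------------------

_ANNOT_COLUMNS = (
    "peak", "chrom", "peak_start", "peak_end",
    "feature", "feature_start", "feature_end", "feature_strand",
    "insideFeature", "distancetoFeature", "fromOverlappingOrNearest",
)


def annotated_to_dataframe(rows: Iterable[AnnotatedPeak]) -> pd.DataFrame:
    records = []
    for r in rows:
        f = r.feature
        records.append({
            "peak": r.peak.name,
            "chrom": r.peak.chrom,
            "peak_start": r.peak.start,
            "peak_end": r.peak.end,
            "feature": f.name if f else "",
            "feature_start": f.start if f else pd.NA,
            "feature_end": f.end if f else pd.NA,
            "feature_strand": f.strand if f else "",
            "insideFeature": r.inside_feature or "",
            "distancetoFeature": r.distance_to_feature if f else pd.NA,
            "fromOverlappingOrNearest": r.from_overlapping_or_nearest,
        })
    return pd.DataFrame.from_records(records, columns=_ANNOT_COLUMNS)


def write_annotated_tsv(rows: Iterable[AnnotatedPeak], path: str | os.PathLike) -> None:
    """Write annotation rows as TSV with the columns listed above."""
    annotated_to_dataframe(rows).to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read back an annotated TSV (e.g. as input to GO enrichment)."""
    return pd.read_csv(path, sep="\t", dtype={"peak": str, "feature": str},
                       keep_default_na=False, na_values=[""])
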