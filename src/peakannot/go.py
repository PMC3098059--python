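"""Hypergeometric GO-term enrichment of peak-adjacent genes.

The test asks, per ontology aspect (BP/MF/CC): given a universe of N
annotated genes of which K carry a term, how surprising is it that k of
the n sampled (peak-adjacent) genes carry it?  p = P(X >= k) with
X ~ Hypergeom(N, K, n).  Terms annotated to fewer than ``min_go_term``
genes genome-wide are excluded *before* Benjamini-Hochberg adjustment
(the exclusion changes the number of tests m), and the ``max_p`` cutoff
applies to the adjusted p-value when adjustment is requested, else to the
raw one.

The gene->term map is aspect-partitioned; the universe of an aspect is
every gene with at least one annotation in that aspect.  Term propagation
along is_a edges is opt-in: supply parent edges and call
:func:`propagate_terms` first.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
_TERM_RE = re.compile(r"^GO:\d{7}$")
_ADJUST_METHODS = ("BH", "none")


def _check_term(term: str) -> str:
    if not _TERM_RE.match(term):
        raise ValidationError(
            f"malformed GO term id {term!r}; expected 'GO:' + 7 digits"
        )
    return term


@dataclass
class GeneTermMap:
    """Aspect-partitioned gene -> GO-term annotation.

    ``annotations[aspect][gene]`` is the (deduplicated) frozenset of term
    ids; ``term_names`` and ``parents`` (child -> set of is_a parents) are
    optional side tables.
    """

    annotations: dict[str, dict[str, frozenset[str]]]
    term_names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aspect in self.annotations:
            if aspect not in ASPECTS:
                raise ValidationError(
                    f"unknown GO aspect {aspect!r}; expected one of {ASPECTS}"
                )
            for gene, terms in self.annotations[aspect].items():
                for term in terms:
                    _check_term(term)

    def universe(self, aspect: str) -> set[str]:
        """Genes with at least one annotation in the aspect."""
        return set(self.annotations.get(aspect, {}))


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested GO term with its counts and p-values."""

    term: str
    name: str
    aspect: str
    universe_count: int   # K: universe genes annotated with the term
    sample_count: int     # k: sample genes annotated with the term
    universe_size: int    # N
    sample_size: int      # n
    p_raw: float
    p_adjusted: float


# -- readers ----------------------------------------------------------------

def read_gene_term_map(
    path: str | os.PathLike,
    term_names_path: str | os.PathLike | None = None,
    edges_path: str | os.PathLike | None = None,
) -> GeneTermMap:
    """Read a gene->term TSV (columns: gene, term[, aspect]; no header).

    A missing third column defaults the aspect to BP.  Optional side files:
    term names (term, name) and is_a edges (child, parent).
    """
    annotations: dict[str, dict[str, set[str]]] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"expected 2 or 3 columns (gene, term[, aspect]), got "
                    f"{len(fields)}", path, lineno,
                )
            gene, term = fields[0], fields[1]
            aspect = fields[2] if len(fields) == 3 else "BP"
            if aspect not in ASPECTS:
                raise ParseError(f"unknown aspect {aspect!r}", path, lineno)
            try:
                _check_term(term)
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
            annotations.setdefault(aspect, {}).setdefault(gene, set()).add(term)
    frozen = {
        aspect: {gene: frozenset(terms) for gene, terms in genes.items()}
        for aspect, genes in annotations.items()
    }
    term_names: dict[str, str] = {}
    if term_names_path is not None:
        with open(term_names_path, "rt", encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, 1):
                line = raw.rstrip("\r\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError("expected columns (term, name)",
                                     term_names_path, lineno)
                term_names[_check_term(fields[0])] = fields[1]
    parents: dict[str, set[str]] = {}
    if edges_path is not None:
        with open(edges_path, "rt", encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, 1):
                line = raw.rstrip("\r\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError("expected columns (child, parent)",
                                     edges_path, lineno)
                parents.setdefault(_check_term(fields[0]), set()).add(
                    _check_term(fields[1])
                )
    return GeneTermMap(
        frozen, term_names, {c: frozenset(p) for c, p in parents.items()}
    )


# -- operations -------------------------------------------------------------

def _ancestors(parents: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Transitive ancestor closure; raises on cycles."""
    cache: dict[str, frozenset[str]] = {}
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(term: str) -> frozenset[str]:
        state = color.get(term, WHITE)
        if state == BLACK:
            return cache[term]
        if state == GRAY:
            raise ValidationError(f"cycle in term hierarchy involving {term}")
        color[term] = GRAY
        result: set[str] = set()
        for parent in parents.get(term, ()):
            result.add(parent)
            result |= visit(parent)
        color[term] = BLACK
        cache[term] = frozenset(result)
        return cache[term]

    for term in list(parents):
        visit(term)
    return cache


def propagate_terms(gene_map: GeneTermMap) -> GeneTermMap:
    """Close every gene's term set under is_a ancestor edges (idempotent)."""
    ancestors = _ancestors(gene_map.parents)
    closed: dict[str, dict[str, frozenset[str]]] = {}
    for aspect, genes in gene_map.annotations.items():
        closed[aspect] = {}
        for gene, terms in genes.items():
            extended = set(terms)
            for term in terms:
                extended |= ancestors.get(term, frozenset())
            closed[aspect][gene] = frozenset(extended)
    return GeneTermMap(closed, dict(gene_map.term_names), dict(gene_map.parents))


def extract_gene_sample(rows: Iterable) -> set[str]:
    """Deduplicated feature (gene) ids from annotation rows.

    Accepts :class:`~peakannot.annotate.AnnotatedPeak` rows; rows with an
    empty feature are skipped.  Raises if nothing remains.
    """
    genes = {
        row.feature.name
        for row in rows
        if getattr(row, "feature", None) is not None
    }
    if not genes:
        raise ValidationError("no annotated genes to test (empty sample)")
    return genes


def enrich(
    sample: set[str],
    gene_map: GeneTermMap,
    max_p: float = 0.01,
    min_go_term: int = 1,
    adjust: str = "BH",
) -> dict[str, list[EnrichmentRow]]:
    """Hypergeometric GO enrichment of a gene sample, per aspect.

    Parameters
    ----------
    sample : set of gene ids
        Peak-adjacent genes; members absent from an aspect's universe are
        dropped from that aspect's n (and logged).
    max_p : float
        Significance cutoff, applied to the adjusted p under BH, to the
        raw p otherwise.
    min_go_term : int
        Minimum genome-wide annotation count K for a term to be tested;
        applied before adjustment.
    adjust : {"BH", "none"}
        Benjamini-Hochberg step-up FDR adjustment within each aspect.

    Returns a dict aspect -> rows sorted by (p_raw, term id).  Aspects with
    no sample genes in the universe yield no rows; if that happens for
    every aspect an error is raised.
    """
    if min_go_term < 1:
        raise ValidationError(f"min_go_term must be >= 1, got {min_go_term}")
    if adjust not in _ADJUST_METHODS:
        raise ValidationError(
            f"unknown adjustment {adjust!r}; expected one of {_ADJUST_METHODS}"
        )
    result: dict[str, list[EnrichmentRow]] = {}
    any_overlap = False
    for aspect in ASPECTS:
        result[aspect] = []
        genes = gene_map.annotations.get(aspect, {})
        if not genes:
            continue
        universe = set(genes)
        sample_in = sample & universe
        dropped = sample - universe
        if dropped:
            logger.info("%s: %d sample gene(s) absent from universe dropped",
                        aspect, len(dropped))
        if not sample_in:
            continue
        any_overlap = True
        N, n = len(universe), len(sample_in)
        term_universe_count: dict[str, int] = {}
        for terms in genes.values():
            for term in terms:
                term_universe_count[term] = term_universe_count.get(term, 0) + 1
        candidates = sorted(
            t for t, K in term_universe_count.items() if K >= min_go_term
        )
        if not candidates:
            continue
        term_sample_count = {t: 0 for t in candidates}
        for gene in sample_in:
            for term in genes[gene]:
                if term in term_sample_count:
                    term_sample_count[term] += 1
        p_raw = [
            float(hypergeom.sf(term_sample_count[t] - 1, N,
                               term_universe_count[t], n))
            for t in candidates
        ]
        if adjust == "BH":
            p_adj = list(multipletests(p_raw, method="fdr_bh")[1])
        else:
            p_adj = list(p_raw)
        rows = [
            EnrichmentRow(
                term=t,
                name=gene_map.term_names.get(t, ""),
                aspect=aspect,
                universe_count=term_universe_count[t],
                sample_count=term_sample_count[t],
                universe_size=N,
                sample_size=n,
                p_raw=min(1.0, pr),
                p_adjusted=min(1.0, pa),
            )
            for t, pr, pa in zip(candidates, p_raw, p_adj)
        ]
        cutoff_value = (lambda r: r.p_adjusted) if adjust == "BH" else (lambda r: r.p_raw)
        rows = [r for r in rows if cutoff_value(r) <= max_p]
        rows.sort(key=lambda r: (r.p_raw, r.term))
        result[aspect] = rows
    if not any_overlap:
        raise ValidationError(
            "no sample gene is present in any aspect's annotation universe"
        )
    return result


def enrichment_to_dataframe(result: dict[str, list[EnrichmentRow]]) -> pd.DataFrame:
    """Flatten enrichment results into the output table.

    Columns mirror the conventional report: GO ID, GO Term, Category plus
    the counts and both p-values (FDR = adjusted p).
    """
    records = [
        {
            "GO ID": r.term,
            "GO Term": r.name,
            "Category": r.aspect,
            "K": r.universe_count,
            "k": r.sample_count,
            "N": r.universe_size,
            "n": r.sample_size,
            "p_raw": r.p_raw,
            "FDR": r.p_adjusted,
        }
        for aspect in ASPECTS
        for r in result.get(aspect, [])
    ]
    return pd.DataFrame.from_records(
        records,
        columns=["GO ID", "GO Term", "Category", "K", "k", "N", "n", "p_raw", "FDR"],
    )


def write_enrichment_tsv(
    result: dict[str, list[EnrichmentRow]], path: str | os.PathLike
) -> None:
    enrichment_to_dataframe(result).to_csv(path, sep="\t", index=False)
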