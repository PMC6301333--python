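"""GO term enrichment of one annotation source against the pooled background.

For each GO term the contingency counts are

* A — cluster proteins annotated with the term,
* C — cluster (protein, term) annotation pairs to *other* terms,
* B, D — the same counts in the background (the union of all sources, so
  the cluster is contained in the background and B >= A always),

all restricted to one aspect (namespace) and deduplicated at the
(protein, term) level. The enrichment score is

    E = log10(A / C) - log10(B / D),

positive when the term is over-represented in the cluster. Candidate terms
are screened by a two-tailed Fisher exact test with Bonferroni correction
(family = terms tested per dataset/aspect) and by a minimum is_a distance
from the namespace root (defaults: cellular_component 3,
biological_process 3, molecular_function 4), keeping only high-level terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotation_model import (
    GO_NAMESPACES,
    CorpusError,
    DatasetCollection,
    GOAnnotation,
    GOOntology,
)

logger = logging.getLogger(__name__)

#: default max min-depth per aspect for reported terms
DEPTH_LIMITS = {
    "cellular_component": 3,
    "biological_process": 3,
    "molecular_function": 4,
}

#: relative tolerance when comparing point probabilities in the two-tailed sum
_TWO_TAILED_RELTOL = 1e-7


class EnrichmentError(CorpusError):
    pass


class ZeroCellError(EnrichmentError):
    """E is undefined when any of A, B, C, D is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """Term-vs-rest counts for one GO term in one cluster/background pair."""

    term_id: str
    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise EnrichmentError(f"negative count in table for {self.term_id}")
        if self.n == 0:
            raise EnrichmentError(f"empty table for {self.term_id}")

    @property
    def n(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    aspect: str
    A: int
    B: int
    C: int
    D: int
    E: float | None
    p: float
    p_adj: float
    min_depth: int
    passes_filters: bool


def min_depth(term_id: str, ontology: GOOntology) -> int:
    """Length of the shortest is_a path from the term to its namespace root."""
    if term_id not in ontology:
        raise EnrichmentError(f"unknown term {term_id}")
    ns = ontology.namespace(term_id)
    depths = ontology.depths(ns)
    if term_id not in depths:
        raise EnrichmentError(
            f"ontology integrity error: {term_id} cannot reach the "
            f"{ns} root via is_a"
        )
    return depths[term_id]


def _dedup_pairs(annotations: list[GOAnnotation], aspect: str) -> set[tuple[str, str]]:
    return {(a.accession, a.term_id) for a in annotations if a.aspect == aspect}


def build_contingency(
    term_id: str,
    cluster_annotations: list[GOAnnotation],
    background_annotations: list[GOAnnotation],
    aspect: str,
) -> ContingencyTable:
    """Build the (A, B, C, D) table for one term, aspect-restricted.

    Counting unit is the deduplicated (protein, term) pair; the background
    must contain the cluster's annotations (it is the union of all
    datasets), so a term present in the cluster but absent from the
    background is an error.
    """
    cluster = _dedup_pairs(cluster_annotations, aspect)
    background = _dedup_pairs(background_annotations, aspect)
    A = sum(1 for _, t in cluster if t == term_id)
    B = sum(1 for _, t in background if t == term_id)
    if A > 0 and B == 0:
        raise EnrichmentError(
            f"term {term_id} annotated in the cluster but absent from the "
            f"background; the background must be the union of all datasets"
        )
    return ContingencyTable(term_id, A, B, len(cluster) - A, len(background) - B)


def fisher_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p-value of the contingency table.

    The point probability of a table with the observed margins is the
    hypergeometric ``C(A+B, a) * C(C+D, c) / C(n, a+c)``; the two-tailed p
    sums the point probabilities of all tables with the same margins that
    are no more probable than the observed one (to within a relative
    tolerance of 1e-7). Computed in log space, so large counts neither
    overflow nor lose precision.
    """
    m = table.A + table.B          # total annotations of the term
    draws = table.A + table.C      # cluster annotation total
    n = table.n
    lo = max(0, m + draws - n)
    hi = min(m, draws)
    a = np.arange(lo, hi + 1)
    # log C(m, a) + log C(n - m, draws - a) - log C(n, draws)
    logpmf = (
        gammaln(m + 1) - gammaln(a + 1) - gammaln(m - a + 1)
        + gammaln(n - m + 1) - gammaln(draws - a + 1)
        - gammaln(n - m - draws + a + 1)
        - (gammaln(n + 1) - gammaln(draws + 1) - gammaln(n - draws + 1))
    )
    log_obs = logpmf[table.A - lo]
    keep = logpmf <= log_obs + math.log1p(_TWO_TAILED_RELTOL)
    return float(min(1.0, np.exp(logpmf[keep]).sum()))


def enrichment_E(table: ContingencyTable) -> float:
    """Enrichment score ``log10(A/C) - log10(B/D)``; requires all cells > 0."""
    if min(table.A, table.B, table.C, table.D) == 0:
        raise ZeroCellError(
            f"E undefined for {table.term_id}: zero cell in "
            f"(A={table.A}, B={table.B}, C={table.C}, D={table.D})"
        )
    return math.log10(table.A / table.C) - math.log10(table.B / table.D)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def enrichment_table(
    dataset: DatasetCollection,
    annotations: list[GOAnnotation],
    background_accessions: set[str],
    ontology: GOOntology,
    aspect: str,
    p_cutoff: float = 0.05,
    depth_limits: dict[str, int] | None = None,
    evidence_exclude: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Score every candidate term of *aspect* for one dataset.

    The family for Bonferroni correction is the number of terms tested for
    this (dataset, aspect) pair — every term with at least one background
    annotation. Terms with a zero cell keep their Fisher p but have
    ``E = None`` and never pass the filters. Evidence codes (including
    IEA) are kept unless listed in *evidence_exclude*.
    """
    if aspect not in GO_NAMESPACES:
        raise EnrichmentError(f"unknown aspect {aspect!r}")
    depth_limits = depth_limits or DEPTH_LIMITS
    if evidence_exclude:
        annotations = [a for a in annotations
                       if a.evidence_code not in evidence_exclude]
    cluster = [a for a in annotations if a.accession in dataset.proteins]
    background = [a for a in annotations
                  if a.accession in background_accessions]

    bg_pairs = _dedup_pairs(background, aspect)
    tested_terms = sorted({t for _, t in bg_pairs})
    m = len(tested_terms)
    if m == 0:
        return []

    results: list[EnrichmentResult] = []
    for term in tested_terms:
        if term not in ontology:
            raise EnrichmentError(f"annotated term {term} not in ontology")
        table = build_contingency(term, cluster, background, aspect)
        p = fisher_two_tailed(table)
        p_adj = bonferroni(p, m)
        depth = min_depth(term, ontology)
        try:
            e: float | None = enrichment_E(table)
        except ZeroCellError:
            e = None
            logger.debug("term %s excluded from E ranking (zero cell)", term)
        passes = (
            e is not None
            and p_adj < p_cutoff
            and depth <= depth_limits[aspect]
        )
        results.append(EnrichmentResult(
            term, ontology.name(term), aspect,
            table.A, table.B, table.C, table.D,
            e, p, p_adj, depth, passes,
        ))
    return results


def top_enriched_terms(
    dataset: DatasetCollection,
    annotations: list[GOAnnotation],
    background_accessions: set[str],
    ontology: GOOntology,
    aspect: str,
    k: int = 5,
    p_cutoff: float = 0.05,
    depth_limits: dict[str, int] | None = None,
    evidence_exclude: set[str] | None = None,
) -> list[EnrichmentResult]:
    """The k most enriched passing terms, ranked by E descending.

    Fewer than k (including none) are returned when fewer terms pass the
    Bonferroni and depth filters.
    """
    results = enrichment_table(
        dataset, annotations, background_accessions, ontology, aspect,
        p_cutoff=p_cutoff, depth_limits=depth_limits,
        evidence_exclude=evidence_exclude,
    )
    passing = [r for r in results if r.passes_filters]
    passing.sort(key=lambda r: (-r.E, r.term_id))
    return passing[:k]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [{
        "term_id": r.term_id, "name": r.name, "aspect": r.aspect,
        "A": r.A, "B": r.B, "C": r.C, "D": r.D,
        "E": np.nan if r.E is None else r.E,
        "p": r.p, "p_adj": r.p_adj, "min_depth": r.min_depth,
        "passes_filters": r.passes_filters,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "term_id", "name", "aspect", "A", "B", "C", "D", "E", "p",
        "p_adj", "min_depth", "passes_filters",
    ])
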