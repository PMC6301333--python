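"""Protein- and residue-level overlap between annotation sources, and
superkingdom taxonomy profiles.

Protein intersections are computed on accessions; residue overlap is
computed positionally, pairing regions only when they lie on the same
accession. Unique residues of a dataset are those covered by none of the
other datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .annotation_model import (
    SUPERKINGDOMS,
    CorpusError,
    DatasetCollection,
    ProteinRecord,
    residue_coverage,
)

TAXONOMY_CATEGORIES = SUPERKINGDOMS + ("Unknown",)


class OverlapError(CorpusError):
    pass


@dataclass
class IntersectionResult:
    """Venn cells plus pairwise intersection counts for protein sets."""

    #: cell key = frozenset of dataset names the cell's proteins belong to
    venn_cells: dict[frozenset, int]
    pairwise: pd.DataFrame
    union_size: int

    def cell(self, *names: str) -> int:
        return self.venn_cells.get(frozenset(names), 0)


def protein_intersections(
    datasets: list[DatasetCollection], subset: list[str] | None = None
) -> IntersectionResult:
    """Membership (Venn) cell counts and pairwise intersections.

    With *subset*, only the named datasets are considered; cells are keyed
    by the exact combination of datasets a protein belongs to, so the cell
    counts partition the union.
    """
    by_name = {d.name: d for d in datasets}
    if subset is None:
        subset = [d.name for d in datasets]
    unknown = [n for n in subset if n not in by_name]
    if unknown:
        raise OverlapError(f"unknown dataset name(s): {unknown}")
    if len(subset) < 2:
        raise OverlapError("need at least two datasets to intersect")

    chosen = [by_name[n] for n in subset]
    union: set[str] = set().union(*(d.proteins for d in chosen))
    cells: dict[frozenset, int] = {}
    for acc in union:
        key = frozenset(d.name for d in chosen if acc in d.proteins)
        cells[key] = cells.get(key, 0) + 1

    pairwise = pd.DataFrame(0, index=subset, columns=subset, dtype=int)
    for a in chosen:
        pairwise.loc[a.name, a.name] = len(a.proteins)
    for a, b in combinations(chosen, 2):
        n = len(a.proteins & b.proteins)
        pairwise.loc[a.name, b.name] = n
        pairwise.loc[b.name, a.name] = n
    return IntersectionResult(cells, pairwise, len(union))


@dataclass
class ResidueOverlapResult:
    """Pairwise shared ID residue counts and per-dataset unique residues."""

    shared: pd.DataFrame  # diagonal = dataset n_residues
    unique: pd.Series     # residues covered by no other dataset


def residue_overlap_matrix(
    datasets: list[DatasetCollection],
) -> ResidueOverlapResult:
    """Count positionally overlapping ID residues between every pair.

    The diagonal holds each dataset's total ID residues; ``unique[d]`` is
    the number of d's residues not covered by any other dataset.
    """
    names = [d.name for d in datasets]
    # coverage per (dataset, accession), computed once
    coverage: dict[str, dict[str, set[int]]] = {}
    for d in datasets:
        cov: dict[str, set[int]] = {}
        for acc in d.proteins:
            cov[acc] = residue_coverage(d, acc)
        coverage[d.name] = cov

    shared = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for d in datasets:
        shared.loc[d.name, d.name] = d.n_residues
    for a, b in combinations(datasets, 2):
        n = 0
        for acc in a.proteins & b.proteins:
            n += len(coverage[a.name][acc] & coverage[b.name][acc])
        shared.loc[a.name, b.name] = n
        shared.loc[b.name, a.name] = n

    unique = {}
    for d in datasets:
        covered_by_others = 0
        for acc, positions in coverage[d.name].items():
            others: set[int] = set()
            for o in datasets:
                if o.name != d.name and acc in coverage[o.name]:
                    others |= coverage[o.name][acc]
            covered_by_others += len(positions & others)
        unique[d.name] = d.n_residues - covered_by_others
    return ResidueOverlapResult(shared, pd.Series(unique, name="unique"))


def shared_fraction(
    a: DatasetCollection, b: DatasetCollection, level: str = "proteins"
) -> float:
    """Fraction of *a* shared with *b* (denominator is a; asymmetric).

    ``level`` is ``"proteins"`` (accession intersection) or ``"residues"``
    (positional residue intersection).
    """
    if level == "proteins":
        if not a.proteins:
            raise OverlapError(f"dataset {a.name} has no proteins")
        return len(a.proteins & b.proteins) / len(a.proteins)
    if level == "residues":
        if a.n_residues == 0:
            raise OverlapError(f"dataset {a.name} has no residues")
        shared = 0
        for acc in a.proteins & b.proteins:
            shared += len(residue_coverage(a, acc) & residue_coverage(b, acc))
        return shared / a.n_residues
    raise OverlapError(f"unknown level {level!r}; use 'proteins' or 'residues'")


def taxonomy_profile(
    dataset: DatasetCollection, proteins: dict[str, ProteinRecord]
) -> pd.Series:
    """Proportions over {Bacteria, Archaea, Eukaryota, Viruses, Unknown}.

    The superkingdom is the first lineage element when it names one of the
    four domains of life; anything else (including a missing lineage) is
    reported as Unknown rather than silently dropped.
    """
    if not dataset.proteins:
        raise OverlapError(f"dataset {dataset.name} is empty")
    counts = {k: 0 for k in TAXONOMY_CATEGORIES}
    for acc in dataset.proteins:
        rec = proteins.get(acc)
        kingdom = rec.superkingdom if rec is not None else "Unknown"
        counts[kingdom] += 1
    total = sum(counts.values())
    return pd.Series({k: counts[k] / total for k in TAXONOMY_CATEGORIES},
                     name=dataset.name)


def taxonomy_counts(
    dataset: DatasetCollection, proteins: dict[str, ProteinRecord]
) -> pd.Series:
    """Raw superkingdom counts (same categories as :func:`taxonomy_profile`)."""
    if not dataset.proteins:
        raise OverlapError(f"dataset {dataset.name} is empty")
    counts = {k: 0 for k in TAXONOMY_CATEGORIES}
    for acc in dataset.proteins:
        rec = proteins.get(acc)
        kingdom = rec.superkingdom if rec is not None else "Unknown"
        counts[kingdom] += 1
    return pd.Series(counts, name=dataset.name)
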