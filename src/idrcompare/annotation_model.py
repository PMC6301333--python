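"""Domain model and plain-text I/O for disorder-region corpora.

The unit of analysis is a *merged* intrinsically disordered region (IDR):
raw annotations from one source on one protein are flattened so that
overlapping or directly adjacent intervals coalesce into a single region.
All coordinates are 1-based inclusive, the convention of protein feature
annotations in DisProt/UniProt: the interval (start, end) covers
``end - start + 1`` residues, and ``(1, 4)`` followed by ``(5, 9)`` is a
single region ``(1, 9)``.

File dialects (all tab-separated, ``#`` comment lines allowed):

* region tables — accession, source, start, end, label
* taxonomy — accession, semicolon-joined lineage (root to species)
* GO annotations — accession, term_id, aspect, evidence_code
* ontology — OBO ``[Term]`` stanzas (id, name, namespace, is_a)
* sequences — FASTA, accession as record id
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota", "Viruses")
#: the 20 standard residues, alphabetical one-letter order used everywhere
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues excluded from composition and charge denominators
NONSTANDARD_RESIDUES = frozenset("XBZUO")

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


class CorpusError(Exception):
    """Base class for corpus construction/validation failures."""


class InvalidCoordinateError(CorpusError):
    """A region with start < 1 or start > end."""


class ParseError(CorpusError):
    """A malformed input line; message carries file and line number."""


class ValidationError(CorpusError):
    """An input that parses but violates a corpus invariant."""


def _superkingdom_from_lineage(lineage: Sequence[str] | None) -> str:
    if not lineage:
        return "Unknown"
    head = lineage[0].strip()
    return head if head in SUPERKINGDOMS else "Unknown"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein accession with optional sequence and taxonomy lineage."""

    accession: str
    sequence: str | None = None
    lineage: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if self.sequence is not None and len(self.sequence) < 1:
            raise ValidationError(
                f"protein {self.accession}: sequence present but empty"
            )

    @property
    def superkingdom(self) -> str:
        """First lineage element if it names a superkingdom, else 'Unknown'."""
        return _superkingdom_from_lineage(self.lineage)


@dataclass(frozen=True)
class RegionAnnotation:
    """One raw disorder annotation: (protein, source, start, end, label)."""

    accession: str
    source: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise InvalidCoordinateError(
                f"invalid coordinates for {self.accession}/{self.source}: "
                f"start={self.start}, end={self.end} (1-based inclusive, "
                f"1 <= start <= end required)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MergedRegion:
    """A flattened region; the unit of all per-region statistics.

    Within one (accession, source) pair merged regions are pairwise
    disjoint and separated by at least one uncovered residue.
    """

    accession: str
    source: str
    start: int
    end: int
    n_source_annotations: int = 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise InvalidCoordinateError(
                f"invalid merged region {self.accession}/{self.source}: "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        """Covered 1-based positions."""
        return range(self.start, self.end + 1)


@dataclass
class DatasetCollection:
    """A named annotation source owning proteins and merged regions."""

    name: str
    proteins: set[str] = field(default_factory=set)
    regions: list[MergedRegion] = field(default_factory=list)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_residues(self) -> int:
        return sum(r.length for r in self.regions)

    def regions_of(self, accession: str) -> list[MergedRegion]:
        return [r for r in self.regions if r.accession == accession]

    def validate(self) -> None:
        for r in self.regions:
            if r.accession not in self.proteins:
                raise ValidationError(
                    f"dataset {self.name}: region on {r.accession} but the "
                    f"accession is not in the protein set"
                )


@dataclass(frozen=True)
class GOAnnotation:
    """A protein-to-term assignment with aspect and evidence code."""

    accession: str
    term_id: str
    aspect: str
    evidence_code: str = "IEA"


class GOOntology:
    """An is_a DAG of GO terms with one root per namespace.

    Thin wrapper over a networkx MultiDiGraph (edges point child -> parent,
    as produced by :func:`obonet.read_obo`); only ``is_a`` edges are used
    for depth and reachability.
    """

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph
        self._roots: dict[str, str] = {}
        self._depths: dict[str, dict[str, int]] = {}
        for node, data in graph.nodes(data=True):
            ns = data.get("namespace")
            if ns is None:
                raise ValidationError(f"ontology term {node} has no namespace")
            if not self.parents(node):
                if ns in self._roots:
                    raise ValidationError(
                        f"namespace {ns} has multiple roots: "
                        f"{self._roots[ns]} and {node}"
                    )
                self._roots[ns] = node
        isa = self._isa_graph()
        if not nx.is_directed_acyclic_graph(isa):
            raise ValidationError("ontology is_a edges contain a cycle")

    def _isa_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for child, parent, key in self.graph.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        return g

    @classmethod
    def from_obo(cls, path: str | Path) -> "GOOntology":
        return cls(obonet.read_obo(str(path)))

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.graph.nodes)
        return [
            n for n, d in self.graph.nodes(data=True)
            if d.get("namespace") == namespace
        ]

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id]["namespace"]

    def parents(self, term_id: str) -> list[str]:
        return [
            p for _, p, key in self.graph.out_edges(term_id, keys=True)
            if key == "is_a"
        ]

    def root(self, namespace: str) -> str:
        try:
            return self._roots[namespace]
        except KeyError:
            raise ValidationError(f"no root term for namespace {namespace}")

    def depths(self, namespace: str) -> dict[str, int]:
        """Min is_a distance from the namespace root for every term in it."""
        if namespace not in self._depths:
            root = self.root(namespace)
            rev = self._isa_graph().reverse(copy=False)
            self._depths[namespace] = dict(
                nx.single_source_shortest_path_length(rev, root)
            )
        return self._depths[namespace]


@dataclass
class Corpus:
    """Everything the pipeline reads: datasets plus shared protein context."""

    datasets: list[DatasetCollection]
    proteins: dict[str, ProteinRecord]
    ontology: GOOntology | None = None
    go_annotations: list[GOAnnotation] = field(default_factory=list)
    lc_masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def dataset(self, name: str) -> DatasetCollection:
        for d in self.datasets:
            if d.name == name:
                return d
        raise KeyError(f"unknown dataset: {name}")

    @property
    def dataset_names(self) -> list[str]:
        return [d.name for d in self.datasets]


# ---------------------------------------------------------------------------
# merging and coverage primitives
# ---------------------------------------------------------------------------

def merge_regions(annotations: Iterable[RegionAnnotation]) -> list[MergedRegion]:
    """Flatten raw annotations of one (accession, source) into merged regions.

    Overlapping intervals and directly adjacent intervals (``end + 1 ==
    next start``) coalesce; output is sorted by start, pairwise disjoint,
    and separated by gaps of at least one residue.
    """
    annotations = list(annotations)
    if not annotations:
        return []
    accessions = {a.accession for a in annotations}
    sources = {a.source for a in annotations}
    if len(accessions) > 1 or len(sources) > 1:
        raise ValidationError(
            f"merge_regions expects one accession and one source, got "
            f"accessions={sorted(accessions)} sources={sorted(sources)}"
        )
    acc, src = annotations[0].accession, annotations[0].source
    merged: list[MergedRegion] = []
    cur_start = cur_end = None
    cur_n = 0
    for a in sorted(annotations, key=lambda a: (a.start, a.end)):
        if cur_start is None:
            cur_start, cur_end, cur_n = a.start, a.end, 1
        elif a.start <= cur_end + 1:  # overlap or zero-gap adjacency
            cur_end = max(cur_end, a.end)
            cur_n += 1
        else:
            merged.append(MergedRegion(acc, src, cur_start, cur_end, cur_n))
            cur_start, cur_end, cur_n = a.start, a.end, 1
    merged.append(MergedRegion(acc, src, cur_start, cur_end, cur_n))
    return merged


def residue_coverage(dataset: DatasetCollection, accession: str) -> set[int]:
    """1-based residue positions of *accession* covered by the dataset."""
    cov: set[int] = set()
    for r in dataset.regions:
        if r.accession == accession:
            cov.update(r.positions())
    return cov


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_region_table(path: str | Path) -> list[RegionAnnotation]:
    """Read a region table: accession, source, start, end[, label]."""
    path = Path(path)
    out: list[RegionAnnotation] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(
                f"{path}:{lineno}: expected >= 4 tab-separated columns "
                f"(accession, source, start, end[, label]), got {len(parts)}"
            )
        acc, src = parts[0], parts[1]
        try:
            start, end = int(parts[2]), int(parts[3])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: start/end must be integers, got "
                f"{parts[2]!r}, {parts[3]!r}"
            )
        label = parts[4] if len(parts) > 4 else ""
        try:
            out.append(RegionAnnotation(acc, src, start, end, label))
        except InvalidCoordinateError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    path = Path(path)
    out: dict[str, tuple[str, ...]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected accession<TAB>lineage, "
                f"got {len(parts)} columns"
            )
        out[parts[0]] = tuple(t.strip() for t in parts[1].split(";") if t.strip())
    return out


def read_go_annotations(path: str | Path) -> list[GOAnnotation]:
    path = Path(path)
    out: list[GOAnnotation] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: expected accession, term_id, aspect"
                f"[, evidence_code], got {len(parts)} columns"
            )
        aspect = parts[2]
        if aspect not in GO_NAMESPACES:
            raise ParseError(
                f"{path}:{lineno}: unknown GO aspect {aspect!r}"
            )
        evidence = parts[3] if len(parts) > 3 else "IEA"
        out.append(GOAnnotation(parts[0], parts[1], aspect, evidence))
    return out


def read_lc_masks(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read low-complexity masks (region-table dialect) into merged intervals."""
    raw = read_region_table(path)
    by_acc: dict[str, list[RegionAnnotation]] = {}
    for a in raw:
        by_acc.setdefault(a.accession, []).append(a)
    out: dict[str, list[tuple[int, int]]] = {}
    for acc, anns in by_acc.items():
        # masks may come from several source tags; merge positionally
        flat = [RegionAnnotation(acc, "lc", a.start, a.end) for a in anns]
        out[acc] = [(m.start, m.end) for m in merge_regions(flat)]
    return out


def read_corpus(
    region_paths: Sequence[str | Path] | str | Path,
    fasta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    go_path: str | Path | None = None,
    obo_path: str | Path | None = None,
    lc_path: str | Path | None = None,
) -> Corpus:
    """Assemble a validated :class:`Corpus` from plain-text inputs.

    Region annotations are merged per (accession, source); GO/taxonomy
    rows for accessions absent from every region table are reported and
    skipped.
    """
    if isinstance(region_paths, (str, Path)):
        region_paths = [region_paths]
    annotations: list[RegionAnnotation] = []
    for p in region_paths:
        annotations.extend(read_region_table(p))

    sequences = read_fasta(fasta_path) if fasta_path else {}
    lineages = read_taxonomy(taxonomy_path) if taxonomy_path else {}

    known = {a.accession for a in annotations}
    proteins: dict[str, ProteinRecord] = {}
    for acc in sorted(known):
        seq = sequences.get(acc)
        proteins[acc] = ProteinRecord(acc, seq, lineages.get(acc))

    # validate coordinates against known sequence lengths
    for a in annotations:
        seq = sequences.get(a.accession)
        if seq is not None and a.end > len(seq):
            raise ValidationError(
                f"region {a.accession}/{a.source} ({a.start}, {a.end}) "
                f"extends beyond the sequence (length {len(seq)})"
            )

    by_key: dict[tuple[str, str], list[RegionAnnotation]] = {}
    source_order: list[str] = []
    for a in annotations:
        if a.source not in source_order:
            source_order.append(a.source)
        by_key.setdefault((a.source, a.accession), []).append(a)

    datasets: list[DatasetCollection] = []
    for src in source_order:
        ds = DatasetCollection(src)
        for (s, acc), anns in sorted(by_key.items()):
            if s != src:
                continue
            ds.proteins.add(acc)
            ds.regions.extend(merge_regions(anns))
        ds.regions.sort(key=lambda r: (r.accession, r.start))
        ds.validate()
        datasets.append(ds)

    ontology = GOOntology.from_obo(obo_path) if obo_path else None
    go_annotations: list[GOAnnotation] = []
    if go_path:
        for ann in read_go_annotations(go_path):
            if ann.accession not in known:
                logger.warning(
                    "GO annotation for unknown accession %s skipped",
                    ann.accession,
                )
                continue
            if ontology is not None:
                if ann.term_id not in ontology:
                    raise ValidationError(
                        f"GO annotation refers to unknown term {ann.term_id}"
                    )
                if ontology.namespace(ann.term_id) != ann.aspect:
                    raise ValidationError(
                        f"GO annotation aspect {ann.aspect} does not match "
                        f"namespace of {ann.term_id}"
                    )
            go_annotations.append(ann)

    lc_masks: dict[str, list[tuple[int, int]]] = {}
    if lc_path:
        for acc, ivals in read_lc_masks(lc_path).items():
            if acc not in known:
                logger.warning("LC mask for unknown accession %s skipped", acc)
                continue
            lc_masks[acc] = ivals

    return Corpus(datasets, proteins, ontology, go_annotations, lc_masks)


STANDARD_FILES = {
    "regions": "regions.tsv",
    "fasta": "sequences.fasta",
    "taxonomy": "taxonomy.tsv",
    "go": "go_annotations.tsv",
    "obo": "ontology.obo",
    "lc": "lc_masks.tsv",
}


def read_corpus_dir(directory: str | Path) -> Corpus:
    """Read a corpus from a directory laid out with the standard file names."""
    d = Path(directory)
    regions = d / STANDARD_FILES["regions"]
    if not regions.exists():
        raise CorpusError(f"no region table at {regions}")

    def opt(key: str) -> Path | None:
        p = d / STANDARD_FILES[key]
        return p if p.exists() else None

    return read_corpus(
        regions,
        fasta_path=opt("fasta"),
        taxonomy_path=opt("taxonomy"),
        go_path=opt("go"),
        obo_path=opt("obo"),
        lc_path=opt("lc"),
    )


def write_corpus(
    corpus: Corpus,
    directory: str | Path,
    raw_annotations: Sequence[RegionAnnotation] | None = None,
) -> None:
    """Write a corpus back to the standard plain-text dialects.

    If *raw_annotations* is omitted the merged regions are written (the
    round trip through :func:`read_corpus_dir` is then the identity, since
    merging is idempotent).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    with open(d / STANDARD_FILES["regions"], "w") as fh:
        fh.write("# accession\tsource\tstart\tend\tlabel"
                 "  (1-based inclusive coordinates)\n")
        if raw_annotations is not None:
            rows = [(a.accession, a.source, a.start, a.end, a.label)
                    for a in raw_annotations]
        else:
            rows = [(r.accession, r.source, r.start, r.end, "")
                    for ds in corpus.datasets for r in ds.regions]
        for acc, src, start, end, label in sorted(rows):
            fh.write(f"{acc}\t{src}\t{start}\t{end}\t{label}\n")

    if any(p.sequence for p in corpus.proteins.values()):
        records = [
            SeqRecord(Seq(p.sequence), id=p.accession, description="")
            for p in sorted(corpus.proteins.values(), key=lambda p: p.accession)
            if p.sequence
        ]
        SeqIO.write(records, str(d / STANDARD_FILES["fasta"]), "fasta")

    if any(p.lineage for p in corpus.proteins.values()):
        with open(d / STANDARD_FILES["taxonomy"], "w") as fh:
            fh.write("# accession\tlineage (semicolon-joined, root first)\n")
            for acc in sorted(corpus.proteins):
                lin = corpus.proteins[acc].lineage
                if lin:
                    fh.write(f"{acc}\t{';'.join(lin)}\n")

    if corpus.go_annotations:
        with open(d / STANDARD_FILES["go"], "w") as fh:
            fh.write("# accession\tterm_id\taspect\tevidence_code\n")
            for a in sorted(corpus.go_annotations,
                            key=lambda a: (a.accession, a.term_id)):
                fh.write(f"{a.accession}\t{a.term_id}\t{a.aspect}\t"
                         f"{a.evidence_code}\n")

    if corpus.ontology is not None:
        write_obo(corpus.ontology, d / STANDARD_FILES["obo"])

    if corpus.lc_masks:
        with open(d / STANDARD_FILES["lc"], "w") as fh:
            fh.write("# accession\tsource\tstart\tend\tlabel"
                     "  (low-complexity mask, 1-based inclusive)\n")
            for acc in sorted(corpus.lc_masks):
                for start, end in corpus.lc_masks[acc]:
                    fh.write(f"{acc}\tlc\t{start}\t{end}\t\n")


def write_obo(ontology: GOOntology, path: str | Path) -> None:
    """Write the ontology as minimal OBO [Term] stanzas."""
    g = ontology.graph
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(g.nodes):
            data = g.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {data['namespace']}\n")
            for parent in sorted(ontology.parents(term)):
                fh.write(f"is_a: {parent} ! {g.nodes[parent].get('name', parent)}\n")
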