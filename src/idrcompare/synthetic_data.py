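"""Synthetic multi-source disorder corpora with known, recoverable structure.

The generator emits exactly the plain-text dialects the readers in
:mod:`idrcompare.annotation_model` consume (region TSV, FASTA, taxonomy
TSV, GO TSV, OBO, LC-mask TSV) plus a JSON provenance file recording the
configuration, the seed, and the realized ground truth. Planted structure:

* per-dataset protein counts from sampling weights, with exact pairwise
  protein overlaps built from disjoint per-pair blocks;
* per-dataset superkingdom proportions assigned by largest-remainder
  quotas (shared proteins resolved by a deterministic greedy);
* log-normal merged-region lengths, truncated below at 5 residues;
* per-region Das–Pappu charge classes realized through exact integer
  charged-residue counts, so downstream classification recovers the
  planted class mix region for region;
* low-complexity runs written simultaneously into the sequence and the
  mask file — the generator, not a SEG implementation, is the source of
  truth for masks;
* a synthetic is_a DAG per GO namespace with planted term enrichments
  realized by oversampling a term in one dataset by a fold factor.

A single integer seed drives independent sub-streams (keyed by purpose
and dataset name), so adding a dataset leaves the others' draws unchanged.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_model import (
    AMINO_ACIDS,
    GO_NAMESPACES,
    SUPERKINGDOMS,
    Corpus,
    CorpusError,
    DatasetCollection,
    GOAnnotation,
    GOOntology,
    MergedRegion,
    ProteinRecord,
    RegionAnnotation,
    merge_regions,
    write_corpus,
)
from .sequence_features import das_pappu_class

import networkx as nx


class ConfigError(CorpusError):
    """An invalid or infeasible generator configuration."""


_NEUTRAL_RESIDUES = [aa for aa in AMINO_ACIDS if aa not in "KRDE"]
_LC_RUN_RESIDUES = "SGQNTAP"  # candidate letters for planted low-entropy runs
_EVIDENCE_CODES = ["IEA", "IDA", "IMP", "TAS"]
_EVIDENCE_WEIGHTS = [0.6, 0.2, 0.1, 0.1]


def normalized_profile(weights: Mapping[str, float]) -> dict[str, float]:
    """Normalize a letter->weight mapping into a 20-residue simplex point."""
    missing = [aa for aa in AMINO_ACIDS if aa not in weights]
    if missing:
        raise ConfigError(f"composition profile missing residues: {missing}")
    vals = np.array([float(weights[aa]) for aa in AMINO_ACIDS])
    if np.any(vals < 0) or vals.sum() <= 0:
        raise ConfigError("composition profile weights must be non-negative "
                          "with a positive sum")
    vals = vals / vals.sum()
    return dict(zip(AMINO_ACIDS, vals))


#: generic disorder-like composition (polar/charged-enriched, aromatic- and
#: hydrophobic-depleted); normalized at import
DEFAULT_DISORDER_PROFILE = normalized_profile({
    "A": 0.065, "C": 0.008, "D": 0.055, "E": 0.092, "F": 0.018,
    "G": 0.072, "H": 0.020, "I": 0.022, "K": 0.078, "L": 0.042,
    "M": 0.015, "N": 0.042, "P": 0.092, "Q": 0.052, "R": 0.045,
    "S": 0.105, "T": 0.052, "V": 0.036, "W": 0.005, "Y": 0.013,
})

#: filler used for inter-region linkers (never counted by region statistics)
_LINKER_PROFILE = normalized_profile({aa: 1.0 for aa in AMINO_ACIDS})


def _check_simplex(name: str, values: Sequence[float]) -> None:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"{name} must be a probability vector summing to 1 (got sum "
            f"{arr.sum():.12f})"
        )


@dataclass
class DatasetSpec:
    """Per-dataset generation settings.

    ``weight`` scales the protein universe: the dataset gets
    ``round(weight * n_proteins)`` proteins. ``charge_class_mix`` gives the
    target proportions of Das–Pappu classes 1–5 among the dataset's
    regions; ``superkingdom_proportions`` the target proportions over
    {Bacteria, Archaea, Eukaryota, Viruses}.
    """

    name: str
    weight: float
    mean_regions_per_protein: float = 1.3
    region_length_median: float = 30.0
    region_length_sigma: float = 0.7
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISORDER_PROFILE))
    charge_class_mix: tuple[float, ...] = (0.60, 0.28, 0.04, 0.04, 0.04)
    lc_run_rate: float = 0.10
    superkingdom_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"Bacteria": 0.05, "Archaea": 0.01,
                                 "Eukaryota": 0.84, "Viruses": 0.10})

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("dataset_specs: name must be non-empty")
        if self.weight <= 0:
            raise ConfigError(f"dataset {self.name}: weight must be > 0")
        if self.mean_regions_per_protein < 1:
            raise ConfigError(
                f"dataset {self.name}: mean_regions_per_protein must be >= 1"
            )
        if self.region_length_median < 5:
            raise ConfigError(
                f"dataset {self.name}: region_length_median must be >= 5"
            )
        if self.region_length_sigma <= 0:
            raise ConfigError(
                f"dataset {self.name}: region_length_sigma must be > 0"
            )
        if not 0 <= self.lc_run_rate <= 1:
            raise ConfigError(
                f"dataset {self.name}: lc_run_rate must be in [0, 1]"
            )
        _check_simplex(f"dataset {self.name}: composition",
                       [normalized_profile(self.composition)[aa]
                        for aa in AMINO_ACIDS])
        if len(self.charge_class_mix) != 5:
            raise ConfigError(
                f"dataset {self.name}: charge_class_mix needs 5 entries"
            )
        _check_simplex(f"dataset {self.name}: charge_class_mix",
                       self.charge_class_mix)
        extra = set(self.superkingdom_proportions) - set(SUPERKINGDOMS)
        if extra:
            raise ConfigError(
                f"dataset {self.name}: unknown superkingdoms {sorted(extra)}"
            )
        _check_simplex(f"dataset {self.name}: superkingdom_proportions",
                       list(self.superkingdom_proportions.values()))


@dataclass
class OntologySpec:
    """Shape of the synthetic is_a DAG: a rooted tree per namespace (with
    occasional extra is_a parents) of the given depth and branching."""

    depth: Mapping[str, int] | int = 3
    branching: Mapping[str, int] | int = 3
    extra_parent_rate: float = 0.1

    def depth_of(self, namespace: str) -> int:
        return self.depth[namespace] if isinstance(self.depth, Mapping) \
            else self.depth

    def branching_of(self, namespace: str) -> int:
        return self.branching[namespace] if isinstance(self.branching, Mapping) \
            else self.branching

    def validate(self) -> None:
        for ns in GO_NAMESPACES:
            if self.depth_of(ns) < 1:
                raise ConfigError(f"ontology_spec: depth for {ns} must be >= 1")
            if self.branching_of(ns) < 1:
                raise ConfigError(
                    f"ontology_spec: branching for {ns} must be >= 1"
                )
        if not 0 <= self.extra_parent_rate <= 1:
            raise ConfigError("ontology_spec: extra_parent_rate in [0, 1]")


@dataclass
class PlantedEnrichment:
    """Oversample *term_id* (or, if None, a depth-1 term of *aspect*
    chosen deterministically) in *dataset* by *fold*."""

    dataset: str
    fold: float
    aspect: str = "molecular_function"
    term_id: str | None = None

    def validate(self) -> None:
        if self.fold < 1:
            raise ConfigError("planted_enrichments: fold must be >= 1")
        if self.aspect not in GO_NAMESPACES:
            raise ConfigError(
                f"planted_enrichments: unknown aspect {self.aspect!r}"
            )


@dataclass
class CorpusConfig:
    n_proteins: int
    dataset_specs: list[DatasetSpec]
    pairwise_overlap: float = 0.1
    ontology_spec: OntologySpec = field(default_factory=OntologySpec)
    planted_enrichments: list[PlantedEnrichment] = field(default_factory=list)
    go_terms_per_protein: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not self.dataset_specs:
            raise ConfigError("dataset_specs must not be empty")
        names = [s.name for s in self.dataset_specs]
        if len(set(names)) != len(names):
            raise ConfigError("dataset_specs: names must be unique")
        for s in self.dataset_specs:
            s.validate()
        if not 0 <= self.pairwise_overlap < 1:
            raise ConfigError("pairwise_overlap must be in [0, 1)")
        self.ontology_spec.validate()
        for p in self.planted_enrichments:
            p.validate()
            if p.dataset not in names:
                raise ConfigError(
                    f"planted_enrichments: unknown dataset {p.dataset!r}"
                )
        if self.go_terms_per_protein < 0:
            raise ConfigError("go_terms_per_protein must be >= 0")


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def _freq_vector(freqs) -> np.ndarray:
    if isinstance(freqs, Mapping):
        arr = np.array([float(freqs[aa]) for aa in AMINO_ACIDS])
    else:
        arr = np.asarray(freqs, dtype=float)
    if arr.shape != (20,):
        raise ConfigError("frequency vector must have 20 entries")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigError("frequencies must be a simplex point")
    return arr


def sample_sequence(length: int, freqs, rng: np.random.Generator) -> str:
    """Draw an i.i.d. amino-acid string of *length* from a 20-simplex."""
    if length < 1:
        raise ConfigError(f"sequence length must be >= 1, got {length}")
    arr = _freq_vector(freqs)
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=arr)
    return "".join(letters)


def sample_charged_region(
    length: int,
    target_fplus: float,
    target_fminus: float,
    rng: np.random.Generator,
    neutral_profile: Mapping[str, float] | None = None,
) -> str:
    """A region realizing charge-fraction targets to the nearest residue.

    Charged counts are ``round(target * length)``, so the realized f+ and
    f- are within 1/length of the targets; charged positions are placed
    uniformly at random, K/R and D/E chosen per residue, and the remaining
    positions drawn from the neutral part of *neutral_profile*.
    """
    if length < 1:
        raise ConfigError(f"region length must be >= 1, got {length}")
    if target_fplus < 0 or target_fminus < 0 or \
            target_fplus + target_fminus > 1 + 1e-12:
        raise ConfigError(
            f"infeasible charge targets f+={target_fplus}, f-={target_fminus}"
        )
    n_pos = round(target_fplus * length)
    n_neg = round(target_fminus * length)
    if n_pos + n_neg > length:
        raise ConfigError("charge targets round to more residues than fit")
    profile = normalized_profile(neutral_profile or DEFAULT_DISORDER_PROFILE)
    return _assemble_region(length, n_pos, n_neg, 0, "S", profile, rng)[0]


def _neutral_weights(profile: Mapping[str, float]) -> np.ndarray:
    w = np.array([profile[aa] for aa in _NEUTRAL_RESIDUES])
    if w.sum() <= 0:
        raise ConfigError("composition profile has no mass on neutral residues")
    return w / w.sum()


def _assemble_region(
    length: int, n_pos: int, n_neg: int, lc_len: int, lc_residue: str,
    profile: Mapping[str, float], rng: np.random.Generator,
) -> tuple[str, tuple[int, int] | None, dict[str, float]]:
    """Build a region string and return (sequence, lc_span, expected_counts).

    ``lc_span`` is the 1-based (start, end) of the planted run within the
    region, or None. ``expected_counts`` is the exact expectation of each
    letter's count given the realized charged/LC plan.
    """
    letters = np.empty(length, dtype="<U1")
    free = np.ones(length, dtype=bool)
    lc_span = None
    if lc_len > 0:
        offset = int(rng.integers(0, length - lc_len + 1))
        letters[offset:offset + lc_len] = lc_residue
        free[offset:offset + lc_len] = False
        lc_span = (offset + 1, offset + lc_len)
    free_idx = np.flatnonzero(free)
    if n_pos + n_neg > free_idx.size:
        raise ConfigError("charged residues do not fit outside the LC run")
    charged_idx = rng.choice(free_idx, size=n_pos + n_neg, replace=False)
    p_k = profile["K"] / (profile["K"] + profile["R"]) \
        if profile["K"] + profile["R"] > 0 else 0.5
    p_d = profile["D"] / (profile["D"] + profile["E"]) \
        if profile["D"] + profile["E"] > 0 else 0.5
    for i in charged_idx[:n_pos]:
        letters[i] = "K" if rng.random() < p_k else "R"
    for i in charged_idx[n_pos:]:
        letters[i] = "D" if rng.random() < p_d else "E"
    neutral_idx = np.setdiff1d(free_idx, charged_idx, assume_unique=True)
    if neutral_idx.size:
        nw = _neutral_weights(profile)
        letters[neutral_idx] = rng.choice(_NEUTRAL_RESIDUES,
                                          size=neutral_idx.size, p=nw)
    expected: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
    expected[lc_residue] += lc_len
    expected["K"] += n_pos * p_k
    expected["R"] += n_pos * (1 - p_k)
    expected["D"] += n_neg * p_d
    expected["E"] += n_neg * (1 - p_d)
    if neutral_idx.size:
        nw = _neutral_weights(profile)
        for aa, w in zip(_NEUTRAL_RESIDUES, nw):
            expected[aa] += neutral_idx.size * w
    return "".join(letters), lc_span, expected


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def build_synthetic_ontology(
    spec: OntologySpec, rng: np.random.Generator
) -> GOOntology:
    """A rooted is_a DAG per namespace with the requested depth/branching."""
    spec.validate()
    graph = nx.MultiDiGraph()
    counter = 1
    for ns in GO_NAMESPACES:
        depth = spec.depth_of(ns)
        branching = spec.branching_of(ns)
        root = f"GO:{counter:07d}"
        counter += 1
        graph.add_node(root, name=f"{ns} root", namespace=ns)
        levels = [[root]]
        for d in range(1, depth + 1):
            level = []
            for parent in levels[-1]:
                for _ in range(branching):
                    term = f"GO:{counter:07d}"
                    counter += 1
                    graph.add_node(
                        term, name=f"synthetic {ns} term {counter}",
                        namespace=ns,
                    )
                    graph.add_edge(term, parent, key="is_a")
                    level.append(term)
            # a few extra parents at the level above keep it a true DAG
            if d >= 2 and spec.extra_parent_rate > 0:
                for term in level:
                    if rng.random() < spec.extra_parent_rate:
                        extra = levels[-1][int(rng.integers(len(levels[-1])))]
                        if not graph.has_edge(term, extra, key="is_a"):
                            graph.add_edge(term, extra, key="is_a")
            levels.append(level)
    return GOOntology(graph)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Integer quotas summing to *total*, by the largest-remainder method."""
    props = np.asarray(proportions, dtype=float)
    raw = props * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def _stream(seed: int, *key_parts) -> np.random.Generator:
    """Independent deterministic sub-stream keyed by purpose strings."""
    key = [zlib.crc32(str(p).encode()) for p in key_parts]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *key]))


def _charged_counts(
    cls: int, length: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Integer (n+, n-) whose fractions classify exactly as *cls*."""
    for _ in range(40):
        if cls == 1:
            fp, fm = rng.uniform(0.0, 0.18), rng.uniform(0.0, 0.18)
        elif cls == 2:
            hi = rng.uniform(0.26, 0.34)
            lo = rng.uniform(0.0, 0.34)
            fp, fm = (hi, lo) if rng.random() < 0.5 else (lo, hi)
        elif cls == 3:
            fp, fm = rng.uniform(0.37, 0.47), rng.uniform(0.37, 0.47)
        elif cls == 4:
            fp, fm = rng.uniform(0.0, 0.30), rng.uniform(0.37, 0.55)
        elif cls == 5:
            fp, fm = rng.uniform(0.37, 0.55), rng.uniform(0.0, 0.30)
        else:
            raise ConfigError(f"unknown charge class {cls}")
        n_pos, n_neg = round(fp * length), round(fm * length)
        if n_pos + n_neg <= length and \
                das_pappu_class(n_pos / length, n_neg / length) == cls:
            return n_pos, n_neg
    # deterministic fallbacks on the class anchors
    if cls == 1:
        return 0, 0
    if cls == 2:
        n = math.ceil(0.25 * length)
        if n / length > 0.35:
            raise ConfigError(
                f"class 2 unrealizable at region length {length}"
            )
        return n, 0
    strong = math.floor(0.35 * length) + 1
    if cls == 3:
        return strong, strong
    if cls == 4:
        return 0, strong
    return strong, 0


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _plan_membership(config: CorpusConfig):
    """Exact protein membership: per-pair shared blocks plus private pools.

    The pairwise overlap target is read as the shared fraction of the
    smaller dataset of each pair; each pair gets a dedicated block of that
    many proteins, so realized pairwise intersections equal the targets
    exactly and all higher-order intersections are empty.
    """
    specs = config.dataset_specs
    sizes = {s.name: max(1, round(s.weight * config.n_proteins))
             for s in specs}
    names = [s.name for s in specs]
    pair_counts: dict[tuple[str, str], int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair_counts[(a, b)] = round(
                config.pairwise_overlap * min(sizes[a], sizes[b])
            )
    shared_per_dataset = {n: 0 for n in names}
    for (a, b), n in pair_counts.items():
        shared_per_dataset[a] += n
        shared_per_dataset[b] += n
    for n in names:
        if shared_per_dataset[n] > sizes[n]:
            raise ConfigError(
                f"infeasible overlap: dataset {n} would need "
                f"{shared_per_dataset[n]} shared proteins but has only "
                f"{sizes[n]}"
            )
    needed = sum(pair_counts.values()) + sum(
        sizes[n] - shared_per_dataset[n] for n in names
    )
    if needed > config.n_proteins:
        raise ConfigError(
            f"infeasible overlap: {needed} distinct proteins needed but "
            f"n_proteins = {config.n_proteins}"
        )

    membership: dict[str, tuple[str, ...]] = {}
    idx = 0

    def next_acc() -> str:
        nonlocal idx
        idx += 1
        return f"SP{idx:06d}"

    for (a, b), n in pair_counts.items():
        for _ in range(n):
            membership[next_acc()] = (a, b)
    for name in names:
        for _ in range(sizes[name] - shared_per_dataset[name]):
            membership[next_acc()] = (name,)
    return sizes, pair_counts, membership


def _assign_superkingdoms(config: CorpusConfig,
                          membership: dict[str, tuple[str, ...]]):
    """Largest-remainder quotas per dataset; shared proteins resolved by a
    deterministic greedy that maximizes the summed remaining deficit."""
    specs = {s.name: s for s in config.dataset_specs}
    sizes = {n: sum(1 for m in membership.values() if n in m) for n in specs}
    categories = list(SUPERKINGDOMS)
    quota = {}
    for name, spec in specs.items():
        props = [spec.superkingdom_proportions.get(c, 0.0) for c in categories]
        quota[name] = dict(zip(categories,
                               _largest_remainder(props, sizes[name])))
    assigned = {n: {c: 0 for c in categories} for n in specs}
    kingdom_of: dict[str, str] = {}
    for acc, members in membership.items():  # insertion order: shared first
        best_c, best_score = categories[0], -math.inf
        for c in categories:
            score = sum(quota[d][c] - assigned[d][c] for d in members)
            if score > best_score:
                best_c, best_score = c, score
        kingdom_of[acc] = best_c
        for d in members:
            assigned[d][best_c] += 1
    return kingdom_of, assigned, quota


def generate_corpus(
    config: CorpusConfig, out_dir: str | Path | None = None
) -> tuple[Corpus, dict]:
    """Generate a corpus; optionally write it (plus provenance) to disk.

    Returns the in-memory :class:`Corpus` and the provenance dictionary
    holding the realized ground truth per dataset (superkingdom counts,
    charge-class counts, exact expected residue frequencies, mean LC
    fraction, region/residue totals) and the resolved planted enrichments.
    """
    config.validate()
    seed = config.seed
    sizes, pair_counts, membership = _plan_membership(config)
    names = [s.name for s in config.dataset_specs]
    specs = {s.name: s for s in config.dataset_specs}
    kingdom_of, kingdom_counts, kingdom_quota = _assign_superkingdoms(
        config, membership)

    proteins_of: dict[str, list[str]] = {n: [] for n in names}
    for acc, members in membership.items():
        for d in members:
            proteins_of[d].append(acc)

    # ---- ontology and GO annotations -------------------------------------
    onto_rng = _stream(seed, "ontology")
    ontology = build_synthetic_ontology(config.ontology_spec, onto_rng)
    aspect_terms = {
        ns: sorted(t for t in ontology.terms(ns) if t != ontology.root(ns))
        for ns in GO_NAMESPACES
    }

    planted_resolved: list[dict] = []
    used_terms: set[str] = set()
    for p in config.planted_enrichments:
        term = p.term_id
        if term is None:
            depths = ontology.depths(p.aspect)
            candidates = [t for t in aspect_terms[p.aspect]
                          if depths[t] == 1 and t not in used_terms]
            if not candidates:
                raise ConfigError(
                    f"no free depth-1 term left to plant in {p.aspect}"
                )
            term = candidates[0]
        elif term not in ontology:
            raise ConfigError(f"planted term {term} not in the ontology")
        used_terms.add(term)
        planted_resolved.append({
            "dataset": p.dataset, "aspect": p.aspect,
            "term_id": term, "fold": p.fold,
        })

    go_rng = _stream(seed, "go")
    go_pairs: set[tuple[str, str, str]] = set()  # (acc, term, aspect)
    accessions = list(membership)
    for acc in accessions:
        for ns in GO_NAMESPACES:
            terms = aspect_terms[ns]
            if not terms:
                continue
            k = min(int(go_rng.poisson(config.go_terms_per_protein)),
                    len(terms))
            if k > 0:
                chosen = go_rng.choice(len(terms), size=k, replace=False)
                for i in chosen:
                    go_pairs.add((acc, terms[i], ns))
    for planted in planted_resolved:
        ds, term, aspect = planted["dataset"], planted["term_id"], planted["aspect"]
        n_terms = len(aspect_terms[aspect])
        p0 = min(1.0, config.go_terms_per_protein / n_terms)
        p_extra = min(1.0, (planted["fold"] - 1.0) * p0)
        for acc in proteins_of[ds]:
            if go_rng.random() < p_extra:
                go_pairs.add((acc, term, aspect))
    go_annotations = []
    for acc, term, aspect in sorted(go_pairs):
        ev = go_rng.choice(_EVIDENCE_CODES, p=_EVIDENCE_WEIGHTS)
        go_annotations.append(GOAnnotation(acc, term, aspect, str(ev)))

    # ---- regions: lengths, classes, charged counts, LC runs --------------
    # planned[acc] -> list of per-region dicts (dataset order preserved)
    planned: dict[str, list[dict]] = {acc: [] for acc in membership}
    dataset_truth: dict[str, dict] = {}

    for name in names:
        spec = specs[name]
        rng = _stream(seed, "regions", name)
        regions: list[dict] = []
        for acc in proteins_of[name]:
            n_reg = 1 + int(rng.poisson(spec.mean_regions_per_protein - 1.0))
            for _ in range(n_reg):
                length = max(5, int(round(rng.lognormal(
                    math.log(spec.region_length_median),
                    spec.region_length_sigma))))
                regions.append({"accession": acc, "length": length})
        n_regions = len(regions)
        class_counts = _largest_remainder(spec.charge_class_mix, n_regions)
        order = rng.permutation(n_regions)
        # class 2 cannot be realized at length 5: give it length>=6 regions
        class2_slots = [i for i in order if regions[i]["length"] >= 6]
        if len(class2_slots) < class_counts[1]:
            # extend just enough length-5 regions to 6 (rare, tiny corpora)
            for i in order:
                if regions[i]["length"] == 5:
                    regions[i]["length"] = 6
                    class2_slots.append(i)
                    if len(class2_slots) >= class_counts[1]:
                        break
        taken = set(class2_slots[:class_counts[1]])
        for i in taken:
            regions[i]["class"] = 2
        rest = [i for i in order if i not in taken]
        pos = 0
        for cls, cnt in ((1, class_counts[0]), (3, class_counts[2]),
                         (4, class_counts[3]), (5, class_counts[4])):
            for i in rest[pos:pos + cnt]:
                regions[i]["class"] = cls
            pos += cnt

        profile = normalized_profile(spec.composition)
        expected_counts = {aa: 0.0 for aa in AMINO_ACIDS}
        total_residues = 0
        lc_total_fraction = 0.0
        realized_class_counts = [0] * 5
        for reg in regions:
            L = reg["length"]
            cls = reg["class"]
            n_pos, n_neg = _charged_counts(cls, L, rng)
            lc_len = 0
            lc_residue = "S"
            capacity = L - n_pos - n_neg
            if spec.lc_run_rate > 0 and rng.random() < spec.lc_run_rate \
                    and capacity >= 4:
                lc_len = min(capacity,
                             max(4, int(round(rng.uniform(0.2, 0.6) * L))))
                lc_residue = _LC_RUN_RESIDUES[
                    int(rng.integers(len(_LC_RUN_RESIDUES)))]
            seq, lc_span, exp = _assemble_region(
                L, n_pos, n_neg, lc_len, lc_residue, profile, rng)
            reg.update(sequence=seq, lc_span=lc_span, dataset=name)
            realized_class_counts[cls - 1] += 1
            total_residues += L
            lc_total_fraction += lc_len / L
            for aa, v in exp.items():
                expected_counts[aa] += v
            planned[reg["accession"]].append(reg)

        dataset_truth[name] = {
            "size": sizes[name],
            "n_regions": n_regions,
            "total_region_residues": total_residues,
            "class_counts": realized_class_counts,
            "kingdom_counts": kingdom_counts[name],
            "kingdom_quota": kingdom_quota[name],
            "expected_residue_frequencies": {
                aa: expected_counts[aa] / total_residues
                for aa in AMINO_ACIDS
            },
            "mean_lc_fraction": lc_total_fraction / n_regions,
            "region_length_median_config": spec.region_length_median,
        }

    # ---- protein layout: place regions, fill linkers, emit raw rows ------
    raw_annotations: list[RegionAnnotation] = []
    merged_by_dataset: dict[str, list[MergedRegion]] = {n: [] for n in names}
    lc_masks: dict[str, list[tuple[int, int]]] = {}
    protein_records: dict[str, ProteinRecord] = {}

    for acc in membership:
        rng = _stream(seed, "layout", acc)
        regs = planned[acc]
        cursor = int(rng.integers(0, 6))
        chunks: list[str] = []
        if cursor:
            chunks.append(sample_sequence(cursor, _LINKER_PROFILE, rng))
        for j, reg in enumerate(regs):
            if j > 0:
                gap = int(rng.integers(1, 11))
                chunks.append(sample_sequence(gap, _LINKER_PROFILE, rng))
                cursor += gap
            start = cursor + 1
            end = cursor + reg["length"]
            cursor = end
            chunks.append(reg["sequence"])
            reg["start"], reg["end"] = start, end
            merged_by_dataset[reg["dataset"]].append(
                MergedRegion(acc, reg["dataset"], start, end, 1))
            if reg["lc_span"] is not None:
                s, e = reg["lc_span"]
                lc_masks.setdefault(acc, []).append(
                    (start + s - 1, start + e - 1))
            # sometimes emit the region as two raw rows to exercise merging
            if reg["length"] >= 4 and rng.random() < 0.35:
                m = int(rng.integers(start + 1, end - 1))
                if rng.random() < 0.5:  # adjacent split
                    rows = [(start, m), (m + 1, end)]
                else:                   # overlapping split
                    rows = [(start, m + 1), (m, end)]
                for s_, e_ in rows:
                    raw_annotations.append(RegionAnnotation(
                        acc, reg["dataset"], s_, e_, "synthetic"))
            else:
                raw_annotations.append(RegionAnnotation(
                    acc, reg["dataset"], start, end, "synthetic"))
        tail = int(rng.integers(0, 6))
        if tail:
            chunks.append(sample_sequence(tail, _LINKER_PROFILE, rng))
            cursor += tail
        sequence = "".join(chunks)
        kingdom = kingdom_of[acc]
        lineage = (kingdom,
                   f"{kingdom}_clade{zlib.crc32(acc.encode()) % 7}",
                   f"synthspecies_{acc}")
        protein_records[acc] = ProteinRecord(acc, sequence, lineage)

    # canonical mask form: merged, sorted
    for acc in list(lc_masks):
        flat = [RegionAnnotation(acc, "lc", s, e) for s, e in lc_masks[acc]]
        lc_masks[acc] = [(m.start, m.end) for m in merge_regions(flat)]

    datasets = []
    for name in names:
        regions = sorted(merged_by_dataset[name],
                         key=lambda r: (r.accession, r.start))
        ds = DatasetCollection(name, set(proteins_of[name]), regions)
        ds.validate()
        datasets.append(ds)

    corpus = Corpus(datasets, protein_records, ontology, go_annotations,
                    lc_masks)

    provenance = {
        "generator": "idrcompare.synthetic_data",
        "seed": seed,
        "n_proteins": config.n_proteins,
        "pairwise_overlap": config.pairwise_overlap,
        "pair_overlap_counts": {f"{a}|{b}": n
                                for (a, b), n in pair_counts.items()},
        "planted_enrichments": planted_resolved,
        "datasets": dataset_truth,
        "config": config_to_dict(config),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus(corpus, out, raw_annotations=raw_annotations)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return corpus, provenance


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def config_to_dict(config: CorpusConfig) -> dict:
    d = asdict(config)
    d["ontology_spec"]["depth"] = config.ontology_spec.depth \
        if not isinstance(config.ontology_spec.depth, Mapping) \
        else dict(config.ontology_spec.depth)
    return d


def config_from_dict(data: Mapping) -> CorpusConfig:
    """Build and validate a CorpusConfig from parsed JSON, with errors
    naming the offending field."""
    def require(key):
        if key not in data:
            raise ConfigError(f"config missing required field {key!r}")
        return data[key]

    try:
        specs = [DatasetSpec(**{**s, "charge_class_mix":
                                 tuple(s.get("charge_class_mix",
                                             (0.60, 0.28, 0.04, 0.04, 0.04)))})
                 for s in require("dataset_specs")]
    except TypeError as exc:
        raise ConfigError(f"dataset_specs: {exc}") from exc
    onto = data.get("ontology_spec", {})
    planted = [PlantedEnrichment(**p)
               for p in data.get("planted_enrichments", [])]
    config = CorpusConfig(
        n_proteins=require("n_proteins"),
        dataset_specs=specs,
        pairwise_overlap=data.get("pairwise_overlap", 0.1),
        ontology_spec=OntologySpec(**onto) if not isinstance(onto, OntologySpec)
        else onto,
        planted_enrichments=planted,
        go_terms_per_protein=data.get("go_terms_per_protein", 3.0),
        seed=data.get("seed", 0),
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# the study conditions: a seven-source corpus echoing the curated databases
# ---------------------------------------------------------------------------

def _tweak(profile: Mapping[str, float], **mult: float) -> dict[str, float]:
    w = {aa: profile[aa] for aa in AMINO_ACIDS}
    for aa, m in mult.items():
        w[aa] *= m
    return normalized_profile(w)


def study_corpus_config(seed: int = 0) -> CorpusConfig:
    """Seven pseudo-datasets emulating the character of the curated ID
    databases: a short-motif source, binding-site sources, a fuzzy-complex
    source, and one source with a strongly divergent taxonomy profile
    (``mfib_like``). One 3-fold molecular-function enrichment is planted
    in ``ideal_like``.
    """
    base = DEFAULT_DISORDER_PROFILE
    common_kingdoms = {"Bacteria": 0.05, "Archaea": 0.02,
                       "Eukaryota": 0.80, "Viruses": 0.13}
    divergent_kingdoms = {"Bacteria": 0.55, "Archaea": 0.05,
                          "Eukaryota": 0.35, "Viruses": 0.05}
    broad_mix = (0.55, 0.30, 0.05, 0.05, 0.05)
    compact_mix = (0.30, 0.62, 0.02, 0.04, 0.02)
    specs = [
        DatasetSpec("disprot_like", weight=0.14,
                    mean_regions_per_protein=1.5, region_length_median=35,
                    region_length_sigma=0.9, composition=base,
                    charge_class_mix=broad_mix, lc_run_rate=0.25,
                    superkingdom_proportions=common_kingdoms),
        DatasetSpec("elm_like", weight=0.32,
                    mean_regions_per_protein=1.4, region_length_median=9,
                    region_length_sigma=0.35,
                    composition=_tweak(base, P=1.6, W=3.0, A=0.6, G=0.6),
                    charge_class_mix=broad_mix, lc_run_rate=0.02,
                    superkingdom_proportions=common_kingdoms),
        DatasetSpec("ideal_like", weight=0.14,
                    mean_regions_per_protein=1.8, region_length_median=25,
                    region_length_sigma=0.8,
                    composition=_tweak(base, R=0.7),
                    charge_class_mix=broad_mix, lc_run_rate=0.10,
                    superkingdom_proportions=common_kingdoms),
        DatasetSpec("dibs_like", weight=0.09,
                    mean_regions_per_protein=1.1, region_length_median=15,
                    region_length_sigma=0.5, composition=base,
                    charge_class_mix=broad_mix, lc_run_rate=0.03,
                    superkingdom_proportions=common_kingdoms),
        DatasetSpec("mfib_like", weight=0.09,
                    mean_regions_per_protein=1.05, region_length_median=55,
                    region_length_sigma=0.6,
                    composition=_tweak(base, K=1.2, E=1.2),
                    charge_class_mix=compact_mix, lc_run_rate=0.08,
                    superkingdom_proportions=divergent_kingdoms),
        DatasetSpec("fuzdb_like", weight=0.09,
                    mean_regions_per_protein=1.4, region_length_median=35,
                    region_length_sigma=0.8,
                    composition=_tweak(base, Q=1.8, N=1.8, R=0.7),
                    charge_class_mix=broad_mix, lc_run_rate=0.25,
                    superkingdom_proportions=common_kingdoms),
        DatasetSpec("uniprot_like", weight=0.09,
                    mean_regions_per_protein=1.05, region_length_median=60,
                    region_length_sigma=0.7,
                    composition=_tweak(base, C=3.0, W=0.5, Y=0.5, H=0.5),
                    charge_class_mix=compact_mix, lc_run_rate=0.10,
                    superkingdom_proportions={"Bacteria": 0.03,
                                              "Archaea": 0.01,
                                              "Eukaryota": 0.66,
                                              "Viruses": 0.30}),
    ]
    return CorpusConfig(
        n_proteins=6000,
        dataset_specs=specs,
        pairwise_overlap=0.08,
        ontology_spec=OntologySpec(
            depth={"molecular_function": 3, "biological_process": 4,
                   "cellular_component": 4},
            branching=3, extra_parent_rate=0.1),
        planted_enrichments=[
            PlantedEnrichment("ideal_like", fold=3.0,
                              aspect="molecular_function"),
        ],
        go_terms_per_protein=3.0,
        seed=seed,
    )


#: the dataset with the divergent superkingdom profile in the study corpus
STUDY_DIVERGENT_TAXA_DATASET = "mfib_like"
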