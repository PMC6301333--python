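"""Per-region and per-dataset sequence features of disordered regions.

Covers region length summaries, amino-acid composition and its enrichment
over a background proteome, hierarchical clustering of enrichment profiles
by variance-standardized Euclidean distance, Das–Pappu charge-state
classification, and low-complexity (LC) content given precomputed masks.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .annotation_model import (
    AMINO_ACIDS,
    NONSTANDARD_RESIDUES,
    CorpusError,
    DatasetCollection,
    MergedRegion,
)

logger = logging.getLogger(__name__)

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")

#: Das–Pappu diagram-of-states class labels
CHARGE_CLASSES = (1, 2, 3, 4, 5)


class FeatureError(CorpusError):
    """A feature was requested on inputs that cannot support it."""


# ---------------------------------------------------------------------------
# composition and enrichment
# ---------------------------------------------------------------------------

def region_sequence(region: MergedRegion, sequences: dict[str, str]) -> str:
    seq = sequences.get(region.accession)
    if seq is None:
        raise FeatureError(
            f"no sequence for accession {region.accession}; composition and "
            f"charge statistics require sequences"
        )
    if region.end > len(seq):
        raise FeatureError(
            f"region {region.accession} ({region.start}, {region.end}) "
            f"extends beyond sequence of length {len(seq)}"
        )
    return seq[region.start - 1: region.end]


def aa_frequencies(
    dataset: DatasetCollection, sequences: dict[str, str]
) -> pd.Series:
    """Amino-acid frequencies over the dataset's merged-region residues.

    Counts are restricted to region residues; non-standard letters
    (X, B, Z, U, O) are excluded from numerator and denominator, with the
    excluded count logged.
    """
    counts = {aa: 0 for aa in AMINO_ACIDS}
    excluded = 0
    for region in dataset.regions:
        for aa in region_sequence(region, sequences):
            if aa in counts:
                counts[aa] += 1
            elif aa in NONSTANDARD_RESIDUES:
                excluded += 1
            else:
                raise FeatureError(
                    f"unexpected residue {aa!r} in {region.accession}"
                )
    total = sum(counts.values())
    if total == 0:
        raise FeatureError(f"dataset {dataset.name}: no standard residues")
    if excluded:
        logger.info(
            "dataset %s: excluded %d non-standard residues from composition",
            dataset.name, excluded,
        )
    return pd.Series(
        {aa: counts[aa] / total for aa in AMINO_ACIDS}, name=dataset.name
    )


def enrichment(freqs: pd.Series, background: pd.Series) -> pd.Series:
    """Fold change vs background: ``(f_i - b_i) / b_i`` per amino acid."""
    background = background.reindex(freqs.index)
    if background.isna().any() or (background <= 0).any():
        bad = background.index[background.isna() | (background <= 0)].tolist()
        raise FeatureError(
            f"background frequencies must be strictly positive for every "
            f"computed amino acid; offending entries: {bad}"
        )
    return (freqs - background) / background


def load_background(path: str | Path | None = None) -> pd.Series:
    """Load a background amino-acid frequency table (aa<TAB>frequency).

    With no path, loads the packaged default — an approximate snapshot of
    the UniProtKB average amino-acid distribution, normalized on load.
    Supply the TrEMBL release table matching your corpus for real analyses.
    """
    if path is None:
        ref = importlib.resources.files("idrcompare") / "data" / "background_frequencies.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    freqs: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        freqs[aa] = float(value)
    s = pd.Series(freqs).reindex(list(AMINO_ACIDS))
    if s.isna().any():
        raise FeatureError("background table must cover all 20 amino acids")
    return s / s.sum()


# ---------------------------------------------------------------------------
# clustering of composition / enrichment profiles
# ---------------------------------------------------------------------------

def seuclidean_distance(u, v, variance) -> float:
    """Variance-standardized Euclidean distance.

    ``d = sqrt(sum_i (u_i - v_i)^2 / V_i)``; symmetric, zero iff u == v.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if u.shape != v.shape or u.shape != variance.shape:
        raise FeatureError("u, v and variance must have equal lengths")
    if np.any(variance <= 0):
        raise FeatureError("variance vector must be strictly positive")
    return float(np.sqrt(np.sum((u - v) ** 2 / variance)))


@dataclass
class ClusterResult:
    """Agglomerative clustering of dataset profiles."""

    labels: list[str]
    linkage_matrix: np.ndarray
    distance_matrix: pd.DataFrame
    variance: pd.Series

    @property
    def leaf_order(self) -> list[str]:
        tree = to_tree(self.linkage_matrix)
        return [self.labels[i] for i in tree.pre_order(lambda n: n.id)]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def cluster_profiles(
    profiles: pd.DataFrame, variance: pd.Series | None = None,
    method: str = "average",
) -> ClusterResult:
    """Cluster dataset profiles (rows) by standardized Euclidean distance.

    *variance* defaults to the per-column variance across datasets
    (ddof=1), the standardization used for the profile heat map.
    """
    if len(profiles) < 2:
        raise FeatureError("clustering needs at least two profiles")
    if variance is None:
        variance = profiles.var(axis=0, ddof=1)
    variance = variance.reindex(profiles.columns)
    if (variance <= 0).any() or variance.isna().any():
        raise FeatureError(
            "per-column variance must be strictly positive; drop constant "
            "columns or supply an explicit variance vector"
        )
    condensed = pdist(profiles.to_numpy(float), metric="seuclidean",
                      V=variance.to_numpy(float))
    z = linkage(condensed, method=method)
    dm = pd.DataFrame(squareform(condensed), index=profiles.index,
                      columns=profiles.index)
    return ClusterResult(list(profiles.index), z, dm, variance)


# ---------------------------------------------------------------------------
# charge classification (Das–Pappu diagram of states)
# ---------------------------------------------------------------------------

def charge_fractions(sequence: str) -> tuple[float, float]:
    """(f+, f-): fractions of K/R and D/E residues.

    Histidine counts as neutral; non-standard letters are excluded from
    the denominator.
    """
    n_pos = n_neg = n_std = 0
    for aa in sequence:
        if aa in NONSTANDARD_RESIDUES:
            continue
        n_std += 1
        if aa in POSITIVE_RESIDUES:
            n_pos += 1
        elif aa in NEGATIVE_RESIDUES:
            n_neg += 1
    if n_std == 0:
        raise FeatureError("charge fractions of an empty sequence are undefined")
    return n_pos / n_std, n_neg / n_std


def das_pappu_class(f_plus: float, f_minus: float) -> int:
    """Das–Pappu diagram-of-states class from charge fractions.

    1 — weak polyampholytes/polyelectrolytes (f+ < 0.25 and f- < 0.25);
    2 — Janus/boundary sequences (both <= 0.35, not class 1);
    3 — strong polyampholytes (both > 0.35);
    4 — strong negative polyelectrolytes (f- > 0.35, f+ <= 0.35);
    5 — strong positive polyelectrolytes (f+ > 0.35, f- <= 0.35).
    """
    if f_plus < 0 or f_minus < 0:
        raise FeatureError("charge fractions must be non-negative")
    if f_plus + f_minus > 1 + 1e-12:
        raise FeatureError(
            f"f+ + f- = {f_plus + f_minus:.4f} exceeds 1"
        )
    if f_plus < 0.25 and f_minus < 0.25:
        return 1
    if f_plus <= 0.35 and f_minus <= 0.35:
        return 2
    if f_plus > 0.35 and f_minus > 0.35:
        return 3
    if f_minus > 0.35:
        return 4
    return 5


@dataclass(frozen=True)
class ChargeProfile:
    """Charge state of one merged region."""

    accession: str
    source: str
    start: int
    end: int
    f_plus: float
    f_minus: float
    das_pappu_class: int


def charge_profiles(
    dataset: DatasetCollection, sequences: dict[str, str]
) -> list[ChargeProfile]:
    out = []
    for region in dataset.regions:
        fp, fm = charge_fractions(region_sequence(region, sequences))
        out.append(ChargeProfile(region.accession, region.source,
                                 region.start, region.end, fp, fm,
                                 das_pappu_class(fp, fm)))
    return out


def class_histogram(
    dataset: DatasetCollection, sequences: dict[str, str]
) -> pd.DataFrame:
    """Counts and proportions of regions per Das–Pappu class (1–5)."""
    if not dataset.regions:
        raise FeatureError(f"dataset {dataset.name} has no regions")
    counts = {c: 0 for c in CHARGE_CLASSES}
    for p in charge_profiles(dataset, sequences):
        counts[p.das_pappu_class] += 1
    n = sum(counts.values())
    return pd.DataFrame({
        "count": pd.Series(counts),
        "proportion": pd.Series({c: counts[c] / n for c in CHARGE_CLASSES}),
    })


# ---------------------------------------------------------------------------
# low-complexity content
# ---------------------------------------------------------------------------

def lc_fraction(
    region: MergedRegion, masks: list[tuple[int, int]]
) -> float:
    """Fraction of the region's residues inside low-complexity mask intervals."""
    covered = 0
    for start, end in masks:
        if start < 1 or start > end:
            raise FeatureError(f"invalid mask interval ({start}, {end})")
        lo = max(region.start, start)
        hi = min(region.end, end)
        if lo <= hi:
            covered += hi - lo + 1
    return covered / region.length


def lc_fractions(
    dataset: DatasetCollection, lc_masks: dict[str, list[tuple[int, int]]]
) -> pd.DataFrame:
    """Per-region LC fraction for every merged region in the dataset."""
    rows = []
    for region in dataset.regions:
        rows.append({
            "accession": region.accession,
            "start": region.start,
            "end": region.end,
            "length": region.length,
            "lc_fraction": lc_fraction(region,
                                       lc_masks.get(region.accession, [])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# region lengths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthSummary:
    """Five-number-plus-mean summary of merged-region lengths."""

    dataset: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: int
    max: int


def region_lengths(dataset: DatasetCollection) -> np.ndarray:
    return np.array([r.length for r in dataset.regions], dtype=float)


def length_summary(dataset: DatasetCollection) -> LengthSummary:
    """Length summary; quantiles by linear interpolation."""
    lengths = region_lengths(dataset)
    if lengths.size == 0:
        raise FeatureError(f"dataset {dataset.name} has no regions")
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return LengthSummary(
        dataset=dataset.name,
        n=int(lengths.size),
        mean=float(lengths.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=int(lengths.min()),
        max=int(lengths.max()),
    )
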