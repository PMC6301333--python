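"""Published summary tables of the 2018 curated-database snapshot.

The accession-level datasets behind the published comparison were never
deposited, but the per-dataset counts and a few pairwise intersections
were printed and are shipped here as inputs for the summary arithmetic
(totals, means, regions per protein, shared fractions).
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

import pandas as pd


def _load(name: str) -> str:
    return (importlib.resources.files("idrcompare") / "data" / name).read_text()


def published_dataset_counts() -> pd.DataFrame:
    """Per-dataset proteins/regions/residues of the published snapshot."""
    df = pd.read_csv(
        StringIO(_load("published_dataset_counts.tsv")),
        sep="\t", comment="#",
        names=["dataset", "proteins", "regions", "residues"],
    )
    return df.set_index("dataset")


def published_pairwise_intersections() -> pd.DataFrame:
    """Published pairwise shared-protein counts (one row per pair)."""
    return pd.read_csv(
        StringIO(_load("published_pairwise_intersections.tsv")),
        sep="\t", comment="#",
        names=["dataset_a", "dataset_b", "shared_proteins"],
    )
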