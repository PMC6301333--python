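"""Shared fixtures: handcrafted micro-corpora, the full study corpus, and
independent brute-force oracles used to cross-check the statistics."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from idrcompare.annotation_model import (
    Corpus,
    DatasetCollection,
    MergedRegion,
    ProteinRecord,
    read_corpus_dir,
)
from idrcompare.synthetic_data import generate_corpus, study_corpus_config

#: one fixed seed for every seeded test in the suite
SUITE_SEED = 20180935


def make_dataset(name, regions, proteins=None):
    """DatasetCollection from (accession, start, end) triples."""
    regs = [MergedRegion(acc, name, s, e) for acc, s, e in regions]
    prots = set(proteins) if proteins else {r.accession for r in regs}
    return DatasetCollection(name, prots, regs)


@pytest.fixture
def two_protein_corpus():
    """Two datasets over two sequenced proteins with hand-set regions.

    p1 = 'KKKK' + 'AAAA' + 'DDDD' + 'WWWW' (regions avoid the W tail so
    composition restricted to regions is checkable by eye); p2 all serine.
    """
    p1 = ProteinRecord("p1", "KKKKAAAADDDDWWWW", ("Eukaryota", "x", "y"))
    p2 = ProteinRecord("p2", "S" * 12, ("Bacteria", "x", "y"))
    ds_a = make_dataset("A", [("p1", 1, 8), ("p2", 1, 6)])
    ds_b = make_dataset("B", [("p1", 5, 12)])
    return Corpus([ds_a, ds_b], {"p1": p1, "p2": p2})


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """The seven-source study corpus written to disk and read back, so the
    fixture exercises the full file round trip; returns (corpus, provenance).
    """
    out = tmp_path_factory.mktemp("study_corpus")
    config = study_corpus_config(seed=SUITE_SEED)
    _, provenance = generate_corpus(config, out_dir=out)
    corpus = read_corpus_dir(out)
    return corpus, provenance


@pytest.fixture(scope="session")
def fisher_oracle():
    """Exact two-tailed Fisher p by exhaustive enumeration in rational
    arithmetic — independent of the package's log-space implementation."""

    def oracle(A: int, B: int, C: int, D: int) -> float:
        m, draws, n = A + B, A + C, A + B + C + D

        def point(a: int) -> Fraction:
            return Fraction(comb(m, a) * comb(n - m, draws - a),
                            comb(n, draws))

        observed = point(A)
        lo, hi = max(0, m + draws - n), min(m, draws)
        total = sum((p for a in range(lo, hi + 1)
                     if (p := point(a)) <= observed), Fraction(0))
        return float(min(Fraction(1), total))

    return oracle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SUITE_SEED)
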