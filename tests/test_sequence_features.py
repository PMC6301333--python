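"""Composition, enrichment, clustering distance, charge classes, LC, lengths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from idrcompare.annotation_model import AMINO_ACIDS, MergedRegion
from idrcompare.sequence_features import (
    FeatureError,
    aa_frequencies,
    charge_fractions,
    class_histogram,
    cluster_profiles,
    das_pappu_class,
    enrichment,
    lc_fraction,
    length_summary,
    load_background,
    seuclidean_distance,
)
from conftest import make_dataset


class TestComposition:
    def test_single_region_pure(self):
        ds = make_dataset("d", [("p", 1, 4)])
        freqs = aa_frequencies(ds, {"p": "AAAA"})
        assert freqs["A"] == 1.0 and freqs.sum() == 1.0

    def test_pooling_across_regions(self):
        ds = make_dataset("d", [("p", 1, 2), ("q", 1, 2)])
        freqs = aa_frequencies(ds, {"p": "AC", "q": "DE"})
        assert all(freqs[aa] == 0.25 for aa in "ACDE")

    def test_restricted_to_region_residues(self):
        # residues outside the region are W; they must not be counted
        ds = make_dataset("d", [("p", 5, 8)])
        freqs = aa_frequencies(ds, {"p": "WWWWAAAAWWWW"})
        assert freqs["W"] == 0.0 and freqs["A"] == 1.0

    def test_nonstandard_residues_excluded_from_denominator(self):
        ds = make_dataset("d", [("p", 1, 5)])
        freqs = aa_frequencies(ds, {"p": "AAXXA"})
        assert freqs["A"] == 1.0

    def test_missing_sequence_names_accession(self):
        ds = make_dataset("d", [("p", 1, 4)])
        with pytest.raises(FeatureError, match="p"):
            aa_frequencies(ds, {})


class TestEnrichment:
    def test_fold_change_identities(self):
        f = pd.Series(0.05, index=list(AMINO_ACIDS))
        assert (enrichment(f, f) == 0).all()
        b = pd.Series(0.05, index=list(AMINO_ACIDS))
        e = enrichment(pd.Series(0.10, index=list(AMINO_ACIDS)), b)
        assert np.allclose(e, 1.0)
        z = enrichment(pd.Series(0.0, index=list(AMINO_ACIDS)), b)
        assert np.allclose(z, -1.0)

    def test_zero_background_rejected(self):
        f = pd.Series(0.05, index=list(AMINO_ACIDS))
        b = f.copy()
        b["W"] = 0.0
        with pytest.raises(FeatureError, match="W"):
            enrichment(f, b)

    def test_frequency_reconstruction_duality(self, rng):
        b = pd.Series(rng.dirichlet(np.ones(20)), index=list(AMINO_ACIDS))
        f = pd.Series(rng.dirichlet(np.ones(20)), index=list(AMINO_ACIDS))
        e = enrichment(f, b)
        assert np.allclose((e * b + b), f, atol=1e-12)

    def test_packaged_background_is_a_simplex(self):
        bg = load_background()
        assert abs(bg.sum() - 1) < 1e-12 and (bg > 0).all()


class TestSeuclidean:
    def test_zero_iff_equal_and_known_value(self):
        assert seuclidean_distance([1, 2], [1, 2], [1, 1]) == 0.0
        assert seuclidean_distance([1, 0], [0, 1], [1, 1]) == pytest.approx(
            np.sqrt(2), abs=1e-15)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(50):
            u, v = rng.normal(size=20), rng.normal(size=20)
            var = rng.uniform(0.1, 2.0, size=20)
            direct = np.sqrt(np.sum((u - v) ** 2 / var))
            assert seuclidean_distance(u, v, var) == pytest.approx(
                direct, abs=1e-12)

    def test_invalid_variance_rejected(self):
        with pytest.raises(FeatureError):
            seuclidean_distance([1, 2], [1, 2], [1, 0])


class TestClustering:
    def test_identical_pair_merges_first(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [5.0, 5.0, 5.0]],
            index=["a", "b", "far"], columns=["x", "y", "z"])
        res = cluster_profiles(profiles,
                               variance=pd.Series(1.0, index=["x", "y", "z"]))
        first = res.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_two_profiles_single_merge_at_their_distance(self):
        profiles = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        var = pd.Series(1.0, index=profiles.columns)
        res = cluster_profiles(profiles, variance=var)
        assert res.linkage_matrix.shape[0] == 1
        assert res.linkage_matrix[0, 2] == pytest.approx(5.0)
        assert "a" in res.to_newick() and res.to_newick().endswith(";")

    def test_average_linkage_heights_non_decreasing(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(6, 8)))
        res = cluster_profiles(profiles,
                               variance=pd.Series(1.0, index=range(8)))
        heights = res.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestChargeClassification:
    def test_charge_fraction_examples(self):
        assert charge_fractions("KKDD") == (0.5, 0.5)
        assert charge_fractions("AAAA") == (0.0, 0.0)
        assert charge_fractions("KRDEAAAAAA") == (0.2, 0.2)
        with pytest.raises(FeatureError):
            charge_fractions("")

    @pytest.mark.parametrize("fp, fm, expected", [
        (0.0, 0.0, 1), (0.24, 0.24, 1),
        (0.30, 0.10, 2), (0.35, 0.35, 2), (0.25, 0.0, 2),
        (0.40, 0.40, 3), (0.36, 0.36, 3),
        (0.0, 0.40, 4), (0.20, 0.36, 4),
        (0.40, 0.0, 5), (0.36, 0.20, 5),
    ])
    def test_rule_table(self, fp, fm, expected):
        assert das_pappu_class(fp, fm) == expected

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(FeatureError):
            das_pappu_class(0.7, 0.7)
        with pytest.raises(FeatureError):
            das_pappu_class(-0.1, 0.0)

    def test_grid_partition_every_point_gets_one_class(self):
        """Every (f+, f-) on the 0.01 grid with f+ + f- <= 1 is assigned
        exactly one class, and class regions are contiguous with the rules."""
        seen = set()
        for i in range(101):
            for j in range(101 - i):
                cls = das_pappu_class(i / 100, j / 100)
                assert cls in (1, 2, 3, 4, 5)
                seen.add(cls)
        assert seen == {1, 2, 3, 4, 5}

    def test_class_histogram_neutral_corpus(self):
        ds = make_dataset("d", [("p", 1, 4), ("q", 1, 4)])
        hist = class_histogram(ds, {"p": "AAAA", "q": "GGGG"})
        assert hist.loc[1, "proportion"] == 1.0
        assert hist["proportion"].sum() == pytest.approx(1.0)

    def test_class_histogram_empty_dataset_errors(self):
        ds = make_dataset("d", [])
        ds.proteins = set()
        with pytest.raises(FeatureError):
            class_histogram(ds, {})


class TestLowComplexity:
    def test_fraction_examples(self):
        region = MergedRegion("p", "d", 1, 10)
        assert lc_fraction(region, [(1, 10)]) == 1.0
        assert lc_fraction(region, []) == 0.0
        assert lc_fraction(region, [(6, 10)]) == 0.5
        assert lc_fraction(region, [(6, 25)]) == 0.5  # clipped to region
        assert lc_fraction(region, [(1, 2), (9, 10)]) == 0.4


class TestLengthSummary:
    def test_single_region(self):
        summary = length_summary(make_dataset("d", [("p", 1, 5)]))
        assert (summary.n, summary.mean, summary.median, summary.min,
                summary.max) == (1, 5.0, 5.0, 5, 5)

    def test_interpolated_median(self):
        ds = make_dataset("d", [("p", 1, k) for k in range(1, 101)])
        assert length_summary(ds).median == pytest.approx(50.5)

    def test_empty_dataset_errors(self):
        with pytest.raises(FeatureError):
            length_summary(make_dataset("d", []))

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_quantile_ordering_invariant(self, lengths):
        ds = make_dataset("d", [("p", 1, n) for n in lengths])
        s = length_summary(ds)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
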