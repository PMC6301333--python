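"""Generator: elementary samplers, ontology shape, corpus-level guarantees."""

import json

import numpy as np
import pytest

from idrcompare.annotation_model import AMINO_ACIDS, read_corpus_dir
from idrcompare.go_enrichment import min_depth
from idrcompare.overlap_stats import protein_intersections
from idrcompare.sequence_features import charge_fractions, das_pappu_class
from idrcompare.synthetic_data import (
    ConfigError,
    CorpusConfig,
    DatasetSpec,
    OntologySpec,
    build_synthetic_ontology,
    config_from_dict,
    config_to_dict,
    generate_corpus,
    sample_charged_region,
    sample_sequence,
    study_corpus_config,
)
from conftest import SUITE_SEED


class TestSampleSequence:
    def test_degenerate_profile(self, rng):
        freqs = {aa: (1.0 if aa == "A" else 0.0) for aa in AMINO_ACIDS}
        assert sample_sequence(5, freqs, rng) == "AAAAA"

    def test_zero_length_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_sequence(0, {aa: 0.05 for aa in AMINO_ACIDS}, rng)

    def test_uniform_frequencies_within_binomial_error(self):
        """100k draws at p = 0.05 per letter: each realized frequency within
        4 sigma of the binomial standard error sqrt(p(1-p)/n)."""
        rng = np.random.default_rng(SUITE_SEED)
        n = 100_000
        seq = sample_sequence(n, {aa: 0.05 for aa in AMINO_ACIDS}, rng)
        sigma = np.sqrt(0.05 * 0.95 / n)
        for aa in AMINO_ACIDS:
            assert abs(seq.count(aa) / n - 0.05) < 4 * sigma


class TestSampleChargedRegion:
    def test_exact_counts(self, rng):
        seq = sample_charged_region(10, 0.5, 0.0, rng)
        assert sum(seq.count(x) for x in "KR") == 5
        assert sum(seq.count(x) for x in "DE") == 0

    def test_no_charges(self, rng):
        seq = sample_charged_region(10, 0.0, 0.0, rng)
        assert not set(seq) & set("KRDE")

    def test_balanced_strong_targets_classify_class_3(self, rng):
        seq = sample_charged_region(20, 0.4, 0.4, rng)
        assert das_pappu_class(*charge_fractions(seq)) == 3

    def test_realized_fractions_within_one_residue(self, rng):
        for target in (0.13, 0.27, 0.41):
            seq = sample_charged_region(37, target, 0.1, rng)
            fp, _ = charge_fractions(seq)
            assert abs(fp - target) <= 1 / 37 + 1e-12

    def test_infeasible_targets_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_charged_region(10, 0.7, 0.5, rng)


class TestSyntheticOntology:
    def test_depth_one_branching_three(self, rng):
        onto = build_synthetic_ontology(
            OntologySpec(depth=1, branching=3, extra_parent_rate=0.0), rng)
        for ns in ("molecular_function", "biological_process",
                   "cellular_component"):
            children = [t for t in onto.terms(ns) if t != onto.root(ns)]
            assert len(children) == 3
            assert all(onto.parents(t) == [onto.root(ns)] for t in children)

    def test_all_min_depths_realized(self, rng):
        onto = build_synthetic_ontology(OntologySpec(depth=4, branching=2),
                                        rng)
        depths = {min_depth(t, onto) for t in
                  onto.terms("biological_process")}
        assert depths == {0, 1, 2, 3, 4}

    def test_extra_parents_keep_dag(self, rng):
        import networkx as nx
        onto = build_synthetic_ontology(
            OntologySpec(depth=3, branching=3, extra_parent_rate=0.5), rng)
        # GOOntology.__init__ already validates acyclicity; double-check
        g = nx.DiGraph((u, v) for u, v, k in onto.graph.edges(keys=True)
                       if k == "is_a")
        assert nx.is_directed_acyclic_graph(g)


def small_config(seed=0, overlap=0.2):
    specs = [
        DatasetSpec("alpha", weight=0.3, region_length_median=20,
                    region_length_sigma=0.5),
        DatasetSpec("beta", weight=0.2, region_length_median=12,
                    region_length_sigma=0.4),
    ]
    return CorpusConfig(n_proteins=200, dataset_specs=specs,
                        pairwise_overlap=overlap,
                        ontology_spec=OntologySpec(depth=2, branching=2,
                                                   extra_parent_rate=0.0),
                        seed=seed)


class TestGenerateCorpus:
    def test_same_seed_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(small_config(seed=7), out_dir=d1)
        generate_corpus(small_config(seed=7), out_dir=d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(small_config(seed=7), out_dir=d1)
        generate_corpus(small_config(seed=8), out_dir=d2)
        assert (d1 / "sequences.fasta").read_bytes() != \
               (d2 / "sequences.fasta").read_bytes()

    def test_zero_overlap_gives_disjoint_datasets(self):
        corpus, _ = generate_corpus(small_config(overlap=0.0))
        res = protein_intersections(corpus.datasets)
        assert res.pairwise.loc["alpha", "beta"] == 0

    def test_pairwise_overlap_realized_exactly(self):
        corpus, prov = generate_corpus(small_config(overlap=0.2))
        res = protein_intersections(corpus.datasets)
        expected = prov["pair_overlap_counts"]["alpha|beta"]
        assert expected == round(0.2 * min(len(corpus.dataset("alpha").proteins),
                                           len(corpus.dataset("beta").proteins)))
        assert res.pairwise.loc["alpha", "beta"] == expected

    def test_infeasible_overlap_rejected_before_generation(self):
        cfg = small_config()
        cfg.n_proteins = 20
        cfg.dataset_specs[0].weight = 3.0  # 60 proteins from a universe of 20
        with pytest.raises(ConfigError, match="infeasible"):
            generate_corpus(cfg)

    def test_regions_fit_sequences_and_masks_match_runs(self, tmp_path):
        out = tmp_path / "c"
        generate_corpus(small_config(seed=3), out_dir=out)
        corpus = read_corpus_dir(out)  # read_corpus validates coordinates
        for acc, ivals in corpus.lc_masks.items():
            seq = corpus.proteins[acc].sequence
            for s, e in ivals:
                run = seq[s - 1:e]
                assert len(set(run)) == 1  # planted homopolymer stretch

    def test_provenance_round_trips_through_json_and_config(self, tmp_path):
        out = tmp_path / "c"
        _, prov = generate_corpus(small_config(seed=3), out_dir=out)
        on_disk = json.loads((out / "provenance.json").read_text())
        assert on_disk["seed"] == 3
        rebuilt = config_from_dict(on_disk["config"])
        assert config_to_dict(rebuilt) == prov["config"]

    def test_study_config_validates(self):
        study_corpus_config(seed=1).validate()


class TestParameterRecoveryAggregates:
    """Generator truth recorded in provenance matches what the pipeline
    recovers; the full checks at study scale live in the acceptance suite."""

    def test_truth_totals_match_corpus(self, study_corpus):
        corpus, prov = study_corpus
        for d in corpus.datasets:
            truth = prov["datasets"][d.name]
            assert d.n_proteins == truth["size"]
            assert d.n_regions == truth["n_regions"]
            assert d.n_residues == truth["total_region_residues"]
            assert sum(truth["class_counts"]) == truth["n_regions"]
            freqs = truth["expected_residue_frequencies"]
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
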