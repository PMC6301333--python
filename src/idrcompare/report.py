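"""Analysis orchestration: run every pipeline stage over a corpus, write
the tabular outputs, and roll them up into a single Markdown report.

Used by the command-line interface; importable directly for scripted runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation_model import Corpus, GO_NAMESPACES
from .compare_stats import FEATURES, significance_matrix, CompareError
from .go_enrichment import top_enriched_terms, results_to_frame
from .overlap_stats import (
    protein_intersections,
    residue_overlap_matrix,
    taxonomy_profile,
)
from .sequence_features import (
    FeatureError,
    aa_frequencies,
    class_histogram,
    cluster_profiles,
    enrichment,
    lc_fractions,
    length_summary,
    load_background,
)

logger = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path, header_note: str,
               index_label: str = "dataset") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def summarize_counts(counts: pd.DataFrame) -> dict:
    """Derived arithmetic over a per-dataset counts table.

    *counts* has columns ``proteins``, ``regions``, ``residues`` indexed by
    dataset name; returns totals, the mean dataset size, and per-dataset
    regions-per-protein ratios.
    """
    for col in ("proteins", "regions", "residues"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    return {
        "total_proteins": int(counts["proteins"].sum()),
        "total_regions": int(counts["regions"].sum()),
        "total_residues": int(counts["residues"].sum()),
        "mean_proteins_per_dataset": float(counts["proteins"].mean()),
        "regions_per_protein": {
            name: float(row["regions"] / row["proteins"])
            for name, row in counts.iterrows()
        },
    }


def counts_table(corpus: Corpus) -> pd.DataFrame:
    rows = {
        d.name: {"proteins": d.n_proteins, "regions": d.n_regions,
                 "residues": d.n_residues}
        for d in corpus.datasets
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def analyze_corpus(
    corpus: Corpus, out_dir: str | Path,
    background: pd.Series | None = None,
) -> dict:
    """Run all analysis stages and write every output table under *out_dir*.

    Stages that require inputs the corpus lacks (sequences, GO files, LC
    masks) are skipped with a logged warning rather than failing the run.
    Returns a manifest of written files and skipped stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"written": [], "skipped": {}}

    def wrote(name: str) -> Path:
        manifest["written"].append(name)
        return out / name

    sequences = {a: p.sequence for a, p in corpus.proteins.items()
                 if p.sequence}
    have_sequences = all(
        r.accession in sequences
        for d in corpus.datasets for r in d.regions
    )

    # --- dataset counts ----------------------------------------------------
    counts = counts_table(corpus)
    _write_tsv(counts, wrote("table1_counts.tsv"),
               "per-dataset counts: annotated proteins, merged regions, "
               "disordered residues")

    # --- protein-level and residue-level overlap ---------------------------
    if len(corpus.datasets) >= 2:
        inter = protein_intersections(corpus.datasets)
        cells = pd.DataFrame(
            [{"datasets": "&".join(sorted(k)), "count": v}
             for k, v in sorted(inter.venn_cells.items(),
                                key=lambda kv: "&".join(sorted(kv[0])))]
        )
        _write_tsv(cells.set_index("datasets"), wrote("venn_cells.tsv"),
                   f"membership (Venn) cells over protein accessions; "
                   f"cells partition the union of {inter.union_size}",
                   index_label="datasets")
        _write_tsv(inter.pairwise, wrote("pairwise_proteins.tsv"),
                   "pairwise shared protein accessions; diagonal = dataset "
                   "size")
        res = residue_overlap_matrix(corpus.datasets)
        _write_tsv(res.shared, wrote("residue_overlap.tsv"),
                   "pairwise positionally shared disordered residues; "
                   "diagonal = dataset residue total")
        _write_tsv(res.unique.to_frame(), wrote("unique_residues.tsv"),
                   "residues covered by no other dataset")
    else:
        manifest["skipped"]["overlap"] = "fewer than two datasets"

    # --- taxonomy -----------------------------------------------------------
    if any(p.lineage for p in corpus.proteins.values()):
        tax = pd.DataFrame({d.name: taxonomy_profile(d, corpus.proteins)
                            for d in corpus.datasets}).T
        _write_tsv(tax, wrote("taxonomy.tsv"),
                   "superkingdom proportions per dataset (first lineage "
                   "element; Unknown = unparseable or missing lineage)")
    else:
        manifest["skipped"]["taxonomy"] = "no lineages in corpus"

    # --- lengths ------------------------------------------------------------
    lengths = pd.DataFrame([vars(length_summary(d))
                            for d in corpus.datasets]).set_index("dataset")
    _write_tsv(lengths, wrote("lengths.tsv"),
               "merged-region length summaries (residues; quartiles by "
               "linear interpolation)")

    # --- composition, enrichment, clustering, charge ------------------------
    if have_sequences:
        bg = background if background is not None else load_background()
        freqs = pd.DataFrame({d.name: aa_frequencies(d, sequences)
                              for d in corpus.datasets}).T
        enr = pd.DataFrame({name: enrichment(freqs.loc[name], bg)
                            for name in freqs.index}).T
        comp = pd.concat(
            [freqs.add_prefix("freq_"), enr.add_prefix("enrich_")], axis=1)
        _write_tsv(comp, wrote("composition.tsv"),
                   "amino-acid frequencies over region residues and fold "
                   "change (f-b)/b vs the background table")
        if len(corpus.datasets) >= 3:
            try:
                clust = cluster_profiles(enr)
                path = wrote("dendrogram.nwk")
                path.write_text(clust.to_newick() + "\n")
            except FeatureError as exc:
                manifest["skipped"]["clustering"] = str(exc)
        hist = pd.DataFrame({
            d.name: class_histogram(d, sequences)["proportion"]
            for d in corpus.datasets
        }).T
        hist.columns = [f"class_{c}" for c in hist.columns]
        _write_tsv(hist, wrote("charge_classes.tsv"),
                   "Das-Pappu diagram-of-states class proportions per "
                   "dataset (classes 1-5; f+ = K,R; f- = D,E)")
    else:
        manifest["skipped"]["composition"] = \
            "sequences missing for some annotated proteins"

    # --- low complexity ------------------------------------------------------
    if corpus.lc_masks:
        lc_rows = []
        for d in corpus.datasets:
            frac = lc_fractions(d, corpus.lc_masks)["lc_fraction"]
            lc_rows.append({
                "dataset": d.name, "n_regions": len(frac),
                "mean_lc_fraction": frac.mean(),
                "median_lc_fraction": frac.median(),
            })
        _write_tsv(pd.DataFrame(lc_rows).set_index("dataset"),
                   wrote("lc_content.tsv"),
                   "fraction of region residues inside low-complexity "
                   "masks, per dataset")
    else:
        manifest["skipped"]["lc"] = "no low-complexity masks in corpus"

    # --- GO enrichment -------------------------------------------------------
    if corpus.ontology is not None and corpus.go_annotations:
        union = set().union(*(d.proteins for d in corpus.datasets))
        frames = []
        for d in corpus.datasets:
            for aspect in GO_NAMESPACES:
                top = top_enriched_terms(
                    d, corpus.go_annotations, union, corpus.ontology, aspect)
                if top:
                    df = results_to_frame(top)
                    df.insert(0, "dataset", d.name)
                    df["rank"] = range(1, len(df) + 1)
                    frames.append(df)
        enr_df = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["dataset", "term_id"]))
        _write_tsv(enr_df, wrote("enrichment.tsv"),
                   "top enriched GO terms per dataset and aspect "
                   "(background = union of all datasets; Bonferroni "
                   "p_adj < 0.05; depth limits CC 3 / BP 3 / MF 4)",
                   index_label="row")
    else:
        manifest["skipped"]["go_enrichment"] = \
            "no ontology or GO annotations in corpus"

    # --- significance matrices ----------------------------------------------
    if len(corpus.datasets) >= 2:
        for feature in FEATURES:
            if feature in ("composition", "enrichment", "charge_class") \
                    and not have_sequences:
                manifest["skipped"][f"significance_{feature}"] = \
                    "requires sequences"
                continue
            if feature == "lc" and not corpus.lc_masks:
                manifest["skipped"]["significance_lc"] = "requires LC masks"
                continue
            if feature == "taxa" and not any(
                    p.lineage for p in corpus.proteins.values()):
                manifest["skipped"]["significance_taxa"] = "requires lineages"
                continue
            try:
                sig = significance_matrix(corpus, feature,
                                          background=background)
            except (CompareError, FeatureError) as exc:
                manifest["skipped"][f"significance_{feature}"] = str(exc)
                continue
            _write_tsv(sig.p_values, wrote(f"significance_{feature}_p.tsv"),
                       f"all-vs-all p-values for feature '{feature}' "
                       f"(diagonal fixed at 1)")
            _write_tsv(sig.statistics,
                       wrote(f"significance_{feature}_stat.tsv"),
                       f"all-vs-all test statistics for feature '{feature}'")

    for stage, reason in manifest["skipped"].items():
        logger.warning("stage %s skipped: %s", stage, reason)

    manifest["written"].sort()
    run_log = {
        "tool": "idrcompare",
        "version": __version__,
        "datasets": corpus.dataset_names,
        "manifest": manifest,
        "inputs_hash": _corpus_hash(corpus),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for d in corpus.datasets:
        h.update(d.name.encode())
        for r in d.regions:
            h.update(f"{r.accession}:{r.start}-{r.end};".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# roll-up report
# ---------------------------------------------------------------------------

def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def render_report(analysis_dir: str | Path) -> str:
    """One Markdown document summarizing a finished analysis directory."""
    d = Path(analysis_dir)
    counts_path = d / "table1_counts.tsv"
    if not counts_path.exists():
        raise FileNotFoundError(
            f"{d} does not look like an analysis directory "
            f"(no table1_counts.tsv)"
        )
    lines: list[str] = ["# Disorder-source comparison report", ""]
    missing: list[str] = []

    counts = _read_tsv(counts_path)
    summary = summarize_counts(counts)
    lines += ["## Dataset composition", "",
              "| dataset | proteins | regions | residues | regions/protein |",
              "|---|---|---|---|---|"]
    for name, row in counts.iterrows():
        rpp = summary["regions_per_protein"][name]
        lines.append(f"| {name} | {row['proteins']} | {row['regions']} | "
                     f"{row['residues']} | {rpp:.2f} |")
    lines += ["",
              f"Raw sum of proteins across datasets: "
              f"{summary['total_proteins']} "
              f"(mean {summary['mean_proteins_per_dataset']:.1f} per "
              f"dataset).", ""]

    def section(fname: str, title: str, render) -> None:
        path = d / fname
        lines.append(f"## {title}")
        lines.append("")
        if not path.exists():
            missing.append(fname)
            lines.append("*not computed*")
            lines.append("")
            return
        render(_read_tsv(path))
        lines.append("")

    def md_table(df: pd.DataFrame, fmt: str = "{}") -> None:
        lines.append("| | " + " | ".join(str(c) for c in df.columns) + " |")
        lines.append("|" + "---|" * (len(df.columns) + 1))
        for idx, row in df.iterrows():
            cells = " | ".join(fmt.format(v) for v in row)
            lines.append(f"| {idx} | {cells} |")

    section("pairwise_proteins.tsv", "Pairwise shared proteins",
            lambda df: md_table(df))
    section("residue_overlap.tsv", "Pairwise shared disordered residues",
            lambda df: md_table(df))
    section("taxonomy.tsv", "Superkingdom proportions",
            lambda df: md_table(df, "{:.3f}"))
    section("charge_classes.tsv", "Das-Pappu class proportions",
            lambda df: md_table(df, "{:.3f}"))
    section("lengths.tsv", "Region length summaries",
            lambda df: md_table(df))
    section("lc_content.tsv", "Low-complexity content",
            lambda df: md_table(df, "{:.3f}"))

    path = d / "enrichment.tsv"
    lines += ["## Top enriched GO terms", ""]
    if path.exists():
        enr = pd.read_csv(path, sep="\t", comment="#")
        if len(enr) and "term_id" in enr.columns:
            lines += ["| dataset | aspect | term | E | p_adj | rank |",
                      "|---|---|---|---|---|---|"]
            for _, r in enr.iterrows():
                lines.append(
                    f"| {r['dataset']} | {r['aspect']} | {r['term_id']} "
                    f"({r['name']}) | {r['E']:.3f} | {r['p_adj']:.3g} | "
                    f"{int(r['rank'])} |")
        else:
            lines.append("No term passed the Bonferroni and depth filters.")
    else:
        missing.append("enrichment.tsv")
        lines.append("*not computed*")
    lines.append("")

    if missing:
        lines += ["## Not computed", ""]
        lines += [f"- {m}" for m in missing]
        lines.append("")
    return "\n".join(lines) + "\n"
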