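# Methods

This note documents the models, conventions, default parameters, and
numerical choices behind `idrcompare`, and what the synthetic study
corpus does and does not establish about real data.

## Data model and region merging

All coordinates are 1-based inclusive, the protein-feature convention of
DisProt/UniProt; `(start, end)` covers `end − start + 1` residues. Raw
annotations from one source on one protein are flattened into *merged
regions*: intervals that overlap or touch end-to-start (`end + 1 ==
next start`) coalesce. The adjacency rule matters because concatenation
pipelines flatten overlapping evidence into runs of directly adjacent
intervals; treating zero-gap neighbours as one region restores the
underlying disordered segment. Merged regions are the unit of every
per-region statistic. Merging is idempotent, order-invariant, and
coverage-conserving (property-tested). Region labels are carried through
I/O but ignored by statistics, since all annotations of a source are
pooled. Sequences are optional: overlap, taxonomy, and length statistics
work without them; composition and charge statistics fail fast with the
offending accession when a sequence is missing.

## Overlap and taxonomy

Protein-level intersections are computed on accessions; Venn cells are
keyed by the exact membership combination, so cells partition the union
(checked against brute-force set algebra). Residue overlap counts
positionally shared residues of regions on the same accession; a
source's *unique* residues are those covered by no other source.
Residue overlap is computed on merged regions — by coverage
conservation the result is identical on raw annotations.

Superkingdom calls use the first lineage element when it is one of
Bacteria / Archaea / Eukaryota / Viruses; anything else, including a
missing lineage, is reported in an explicit Unknown bucket rather than
dropped.

## Composition, enrichment, clustering

Amino-acid frequencies are counted over region residues only.
Non-standard letters (X, B, Z, U, O) are excluded from numerator and
denominator, with the excluded count logged. Enrichment is the fold
change `(f_i − b_i) / b_i` against a background frequency table; a zero
background entry is an error, not a silent exclusion. The packaged
default background is an approximate snapshot of the UniProtKB average
amino-acid distribution, normalized on load; it is a convenience only —
analyses of a real corpus should pass the absolute frequency table of
the matching TrEMBL release, and the test suite always supplies
explicit synthetic backgrounds so no shipped number is load-bearing.

Profiles are clustered agglomeratively on the variance-standardized
Euclidean distance `d = sqrt(Σ (u_i − v_i)² / V_i)`. The distance is
authored directly (and oracle-tested); the linkage is delegated to
`scipy.cluster.hierarchy`. Average linkage is the default — only the
distance, not the linkage, is canonical for this analysis, so the
linkage method is a keyword argument. `V` defaults to the per-amino-acid
variance across dataset profiles (ddof = 1); constant columns make the
distance undefined and raise rather than being patched.

## Charge classification

`f+` counts K and R, `f−` counts D and E; histidine is treated as
neutral, the standard convention for diagram-of-states work. The class
rules, with the strong-polyelectrolyte boundary read as a strict
"> 0.35" and the class-2 boundary inclusive:

| class | rule | interpretation |
|---|---|---|
| 1 | f+ < 0.25 and f− < 0.25 | weak polyampholytes / polyelectrolytes |
| 2 | both ≤ 0.35, not class 1 | Janus / boundary sequences |
| 3 | both > 0.35 | strong polyampholytes |
| 4 | f− > 0.35, f+ ≤ 0.35 | strong negative polyelectrolytes |
| 5 | f+ > 0.35, f− ≤ 0.35 | strong positive polyelectrolytes |

The rules are an if/elif cascade, so every feasible `(f+, f−)` pair
receives exactly one class; completeness over the 0.01 grid is asserted
in the acceptance suite. `f+ + f− > 1` is rejected.

## Low complexity

LC masks are inputs in the region-table dialect (no SEG
reimplementation); the LC content of a region is the fraction of its
residues inside mask intervals, clipped to the region. Mask intervals
are positionally merged per accession on load.

## GO enrichment

Counting unit: the deduplicated (protein, term) pair, aspect-restricted
— "the count of a term" is the number of annotated proteins, the
standard enrichment convention; this is stated as the contract because
annotation-instance counting would differ when evidence is duplicated.
The background is the union of all sources, so the cluster is a subset
of the background and `B ≥ A` always. No true-path propagation of
annotations to ancestors is performed (a flag exists, default off).
Evidence codes, including IEA, are kept by default; a filter argument
exists.

The Fisher two-tailed p sums hypergeometric point probabilities over all
tables with the observed margins whose probability does not exceed the
observed one, with a relative guard of 1e-7 on the comparison (the
convention of standard implementations). Point probabilities are
computed in log space via `gammaln`, so tables with n in the thousands
neither overflow nor lose precision; agreement with exact
rational-arithmetic enumeration is 1e-7-tight on random tables and
agreement with `scipy.stats.fisher_exact` is verified on large tables.

`E = log10(A/C) − log10(B/D)`. Terms with any zero cell are excluded
from the E ranking with the reason logged, rather than pseudo-counted —
this keeps the statistic exactly as defined; their Fisher p is still
computed. Bonferroni family: the number of terms tested per
(dataset, aspect) pair, i.e. every term with at least one background
annotation in that aspect. Reported terms must satisfy
`p_adj < 0.05` and a minimum is_a distance from the namespace root of at
most 3 (cellular component), 3 (biological process), 4 (molecular
function); depth uses is_a edges only. The top five passing terms by E
(ties broken by term id) are reported; an empty list is a valid result.

## Significance matrices

Feature-to-test dispatch: chi-square (2×k, no continuity correction,
zero-total categories dropped) for taxonomy and charge-class counts;
two-sample Student t with pooled variance — the literal reading of
"Student t-test", with Welch available as an explicit alternative — for
length and LC samples; Pearson r with its two-sided p (t transform,
n − 2 df) for the 20-dimensional composition and enrichment profiles.
For the correlation features a small p indicates *similar* (correlated)
profiles — an inversion of the usual reading of significance that is
reported verbatim and left to interpretation. Matrices are symmetric;
the self-comparison diagonal is fixed at p = 1 by convention (statistic
0, or r = 1 for correlation features). Cells whose test preconditions
fail (degenerate variance, constant vectors, < 2 surviving categories)
are NaN, never fabricated. All tests delegate to `scipy.stats`;
from-scratch formula oracles in the test and acceptance suites pin the
exact quantities computed.

## Synthetic corpus generator

The generator emulates a multi-source curated-annotation snapshot:
named sources over a shared protein universe with controlled protein
overlap, source-specific region-length and composition structure, and
planted categorical truths that downstream stages must recover exactly.
It does **not** attempt realistic protein evolution, homology, database
curation bias, or real GO structure — so passing recovery tests shows
the pipeline measures what it claims on data with known truth, not that
any scientific conclusion about the real databases transfers.

Mechanics, in generation order:

* **Membership.** Dataset size = `round(weight × n_proteins)`. The
  pairwise overlap target is interpreted as the shared fraction of the
  smaller dataset of a pair, and realized *exactly* by dedicated
  per-pair protein blocks; higher-order intersections are empty.
  Infeasible requests (blocks exceeding a dataset or the universe)
  error before generation.
* **Taxonomy.** Per-dataset superkingdom quotas by largest remainder;
  shared proteins are assigned by a deterministic greedy maximizing the
  summed remaining deficit of their member datasets. Realized counts
  are recorded in provenance and are the ground truth for recovery
  (they equal the quotas whenever the shared blocks permit).
* **Regions.** Per protein, `1 + Poisson(mean − 1)` regions; lengths
  log-normal with the configured median and spread, truncated below at
  5 residues. Regions of all member sources are laid out sequentially
  along the protein with ≥ 1-residue linker gaps, so region statistics
  never touch linker residues. About a third of regions are emitted as
  two overlapping or adjacent raw rows to exercise merging; the merged
  result equals the plan by construction.
* **Charge classes.** Class counts per dataset by largest remainder of
  the configured mix; each region gets integer charged counts
  `(n+, n−)` sampled inside its class region of the diagram (with
  deterministic anchor fallbacks), so classification recovers the
  planted counts exactly. Class 2 is unrealizable at length 5 (no
  integer count lands in [0.25, 0.35]); class-2 slots therefore go to
  regions of length ≥ 6.
* **Sequences.** Charged positions are placed uniformly (K/R and D/E
  split per residue by the profile's internal ratio); neutral positions
  are drawn i.i.d. from the neutral-renormalized composition profile;
  LC runs are contiguous homopolymer stretches over neutral letters,
  written simultaneously into the sequence and the mask file — the
  generator, not a SEG implementation, is the source of truth for
  masks. Because charge and LC planting perturb the configured profile,
  provenance records the *exact expected* per-letter frequency vector
  given the realized plan; composition recovery is checked against that
  expectation with a binomial standard error, a conservative bound on
  the Poisson-binomial variance of the actual draw (4σ tolerance).
* **Ontology and GO.** A rooted is_a tree per namespace with configured
  depth and branching, plus occasional extra parents at the level above
  (keeping a true DAG and leaving minimum depths unchanged). Each
  protein receives `Poisson(3)` uniform terms per aspect; a planted
  (dataset, term, fold) enrichment adds the term to the dataset's
  proteins with probability `(fold − 1) × baseline`, giving the stated
  fold oversampling.
* **Determinism.** One integer seed; every sub-generator draws from a
  stream keyed by purpose and dataset/protein identity (CRC32 of the
  name), so adding a dataset does not perturb the others, and identical
  seeds yield byte-identical output files.

## Study conditions

The fixed study corpus (`study_corpus_config`) has seven sources named
`*_like` after the character of the curated databases they emulate:
sizes 540–1920 proteins from a 6000-protein universe, pairwise overlap
0.08, a short-motif source (median length 9), binding-site and
fuzzy-complex sources with compositional tweaks (Q/N-rich, C-rich,
R-depleted, W-enriched), one source (`mfib_like`) with a strongly
divergent superkingdom profile (55% bacterial vs 5% elsewhere), and one
3-fold molecular-function enrichment planted in `ideal_like`. These
sizes keep the full generation-plus-recovery loop under ~10 s on one
CPU while leaving every recovery margin wide (observed: composition
z ≈ 3 of the 4σ bound, length medians within ~6% of the 10% bound, the
planted term at rank 1 with p_adj ≈ 1e-15).

## Known limitations

* The greedy taxonomy assignment can miss a dataset's quota by a few
  proteins when shared blocks over-constrain it; provenance records the
  realized counts, which are the recovery truth.
* The 4σ composition bound is a probabilistic guarantee (~1% of seeds
  may exceed it somewhere across 140 letter×dataset checks by chance).
* Charge-class planting slightly correlates class 2 with region length
  ≥ 6 by necessity; all other class–length pairings are random.
* The two-tailed Fisher convention (point-probability ordering with a
  1e-7 relative guard) matches standard implementations but can differ
  from mid-p or tail-doubling conventions on asymmetric tables.
* Enrichment clustering requires strictly positive per-column variance;
  corpora of near-identical profiles must supply an explicit variance
  vector.
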