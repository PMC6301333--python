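"""All-vs-all significance matrices between annotation sources.

Each feature has its natural test: chi-square on category counts for
taxonomy and Das–Pappu class histograms, two-sample Student t (pooled
variance) for region length and LC content, and the Pearson correlation
p-value for the 20-dimensional composition and enrichment profiles (there
a *small* p indicates correlated, i.e. similar, profiles). Cells whose
test preconditions fail are reported as missing (NaN), never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import Corpus, CorpusError
from .overlap_stats import taxonomy_counts
from .sequence_features import (
    aa_frequencies,
    charge_profiles,
    enrichment,
    lc_fractions,
    load_background,
    region_lengths,
    CHARGE_CLASSES,
)


class CompareError(CorpusError):
    pass


FEATURES = ("taxa", "charge_class", "length", "lc", "composition", "enrichment")

_CHI2_FEATURES = {"taxa", "charge_class"}
_TTEST_FEATURES = {"length", "lc"}
_PEARSON_FEATURES = {"composition", "enrichment"}


def chisq_pair(counts_a, counts_b) -> tuple[float, float]:
    """Chi-square test that two category count vectors share a distribution.

    The 2 x k contingency table has (k - 1) degrees of freedom after
    dropping categories with zero total across both vectors; no continuity
    correction is applied.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise CompareError("count vectors must share the category set")
    if a.sum() <= 0 or b.sum() <= 0:
        raise CompareError("each count vector must have a positive total")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise CompareError("fewer than 2 categories with nonzero totals")
    stat, p, _, _ = stats.chi2_contingency(np.vstack([a, b]),
                                           correction=False)
    return float(stat), float(p)


def ttest_pair(samples_a, samples_b) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance), two-sided."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CompareError("each sample needs at least 2 observations")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled <= 0:
        raise CompareError("degenerate (zero) pooled variance")
    stat, p = stats.ttest_ind(a, b, equal_var=True)
    return float(stat), float(p)


def welch_pair(samples_a, samples_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (optional alternative to the pooled t)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CompareError("each sample needs at least 2 observations")
    if a.var(ddof=1) + b.var(ddof=1) <= 0:
        raise CompareError("degenerate (zero) variance")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def pearson_pair(u, v) -> tuple[float, float]:
    """Pearson correlation coefficient with its two-sided p-value (t
    transform with n - 2 degrees of freedom)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 3:
        raise CompareError("vectors must have equal length >= 3")
    if u.std() == 0 or v.std() == 0:
        raise CompareError("correlation with a constant vector is undefined")
    r, p = stats.pearsonr(u, v)
    return float(r), float(p)


@dataclass
class SignificanceMatrix:
    feature: str
    p_values: pd.DataFrame
    statistics: pd.DataFrame


def _feature_data(corpus: Corpus, feature: str,
                  background: pd.Series | None) -> dict[str, np.ndarray]:
    sequences = {a: p.sequence for a, p in corpus.proteins.items()
                 if p.sequence}
    data: dict[str, np.ndarray] = {}
    for d in corpus.datasets:
        if feature == "taxa":
            data[d.name] = taxonomy_counts(d, corpus.proteins).to_numpy(float)
        elif feature == "charge_class":
            counts = {c: 0 for c in CHARGE_CLASSES}
            for prof in charge_profiles(d, sequences):
                counts[prof.das_pappu_class] += 1
            data[d.name] = np.array([counts[c] for c in CHARGE_CLASSES], float)
        elif feature == "length":
            data[d.name] = region_lengths(d)
        elif feature == "lc":
            data[d.name] = lc_fractions(d, corpus.lc_masks)["lc_fraction"].to_numpy()
        elif feature == "composition":
            data[d.name] = aa_frequencies(d, sequences).to_numpy()
        elif feature == "enrichment":
            bg = background if background is not None else load_background()
            data[d.name] = enrichment(aa_frequencies(d, sequences),
                                      bg).to_numpy()
        else:
            raise CompareError(
                f"unknown feature {feature!r}; one of {FEATURES}"
            )
    return data


def _pair_test(feature: str) -> Callable:
    if feature in _CHI2_FEATURES:
        return chisq_pair
    if feature in _TTEST_FEATURES:
        return ttest_pair
    return pearson_pair


def significance_matrix(
    corpus: Corpus, feature: str, background: pd.Series | None = None,
) -> SignificanceMatrix:
    """Square all-vs-all matrix of pairwise test p-values and statistics.

    Symmetric, with the self-comparison diagonal fixed at p = 1 (statistic
    0 for chi-square/t features, r = 1 for correlation features). A pair
    whose test preconditions fail yields a NaN cell.
    """
    if feature not in FEATURES:
        raise CompareError(f"unknown feature {feature!r}; one of {FEATURES}")
    data = _feature_data(corpus, feature, background)
    names = corpus.dataset_names
    test = _pair_test(feature)
    diag_stat = 1.0 if feature in _PEARSON_FEATURES else 0.0
    p = pd.DataFrame(np.nan, index=names, columns=names)
    s = pd.DataFrame(np.nan, index=names, columns=names)
    for name in names:
        p.loc[name, name] = 1.0
        s.loc[name, name] = diag_stat
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                stat, pval = test(data[a], data[b])
            except CompareError:
                continue
            p.loc[a, b] = p.loc[b, a] = pval
            s.loc[a, b] = s.loc[b, a] = stat
    return SignificanceMatrix(feature, p, s)
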