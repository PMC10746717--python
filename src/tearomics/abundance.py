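"""Differential protein abundance across severity levels.

The classical comparator to model-explanation rankings: per-protein
one-way ANOVA across severity groups with Benjamini-Hochberg FDR control
and a fold-change filter.  A protein is flagged significant when
q <= 0.01 and the ratio of the largest to smallest group mean (raw
scale) is >= 2, matching standard label-free quantification criteria.

The ANOVA runs on log-transformed values (variance stabilisation); the
fold change on raw group means with a pseudo-count guard of 1 so that a
fully-undetected group yields a finite ratio.  Pairwise level contrasts
use a two-sided Mann-Whitney rank-sum test by default (a Welch t-test is
available), marked significant at p < 0.05 and reported as borderline
just above that line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _group_slices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == lv) for lv in np.unique(labels)]


def anova_per_protein(log_values, labels) -> np.ndarray:
    """One-way ANOVA F-test p-value per protein (column) on log values.

    Degenerate columns with zero between- and within-group variance
    (all groups identical constants) get p = 1 by convention.
    """
    arr = np.asarray(log_values, dtype=float)
    if isinstance(log_values, pd.DataFrame):
        arr = log_values.to_numpy(dtype=float)
    groups = _group_slices(labels)
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 samples each")
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.f_oneway(*[arr[g] for g in groups], axis=0)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # NaN arises when every value in the column is identical -> no signal
    p[np.isnan(p)] = 1.0
    return p


def max_fold_change(raw_values, labels, pseudo: float = 1.0) -> np.ndarray:
    """Per protein: (max group mean + pseudo) / (min group mean + pseudo)."""
    arr = raw_values.to_numpy(dtype=float) if isinstance(raw_values, pd.DataFrame) else np.asarray(
        raw_values, dtype=float
    )
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("raw values must be non-negative")
    groups = _group_slices(labels)
    means = np.vstack([arr[g].mean(axis=0) for g in groups])
    return (means.max(axis=0) + pseudo) / (means.min(axis=0) + pseudo)


def significant_proteins(
    accessions,
    pvalues,
    fold_changes,
    q_max: float = 0.01,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust and flag by the joint q/FC criterion.

    Returns a DataFrame (accession, anova_p, q, max_fold_change,
    significant) sorted by input order.
    """
    accessions = list(accessions)
    p = np.asarray(pvalues, dtype=float)
    fc = np.asarray(fold_changes, dtype=float)
    if not (len(accessions) == p.size == fc.size):
        raise ValueError("inputs misaligned")
    if p.size == 0:
        return pd.DataFrame(columns=["accession", "anova_p", "q", "max_fold_change", "significant"])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    flag = (q <= q_max) & (fc >= fc_min)
    return pd.DataFrame(
        {"accession": accessions, "anova_p": p, "q": q,
         "max_fold_change": fc, "significant": flag}
    )


def differential_analysis(
    raw_values: pd.DataFrame,
    labels,
    q_max: float = 0.01,
    fc_min: float = 2.0,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Full per-protein pipeline: ANOVA on log1p values, FC on raw means."""
    p = anova_per_protein(np.log1p(raw_values.to_numpy(dtype=float)), labels)
    fc = max_fold_change(raw_values, labels, pseudo=pseudo)
    return significant_proteins(list(raw_values.columns), p, fc, q_max=q_max, fc_min=fc_min)


def pairwise_level_test(
    values,
    labels,
    level_a: int,
    level_b: int,
    method: str = "ranksum",
) -> float:
    """Two-sided test of one protein between two severity levels.

    ``method`` is "ranksum" (Mann-Whitney, default) or "ttest" (Welch).
    Two identical groups return p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == level_a]
    b = values[labels == level_b]
    if a.size < 2 or b.size < 2:
        raise ValueError("both levels need >=2 samples")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    if method == "ranksum":
        if np.ptp(np.concatenate([a, b])) == 0.0:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def significance_marker(p: float, alpha: float = 0.05, borderline_band: float = 0.06) -> str:
    """'*' below alpha, 'borderline' just above it, '' otherwise."""
    if p < alpha:
        return "*"
    if p < borderline_band:
        return "borderline"
    return ""
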