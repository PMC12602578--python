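"""Statistical machinery: AUC, DeLong's test for correlated ROC curves,
label-permutation tests, preprocessing-group AUC comparisons, and
clinical-characteristic association tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("tlradiomics")


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney estimator)
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute an AUC")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from midranks, equivalent to counting concordant pairs
    with half-credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)           # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# DeLong's test (fast structural-components algorithm)
# ---------------------------------------------------------------------------

@dataclass
class AUCComparison:
    """Result of DeLong's paired comparison of two correlated AUCs."""

    auc_1: float
    auc_2: float
    z: float
    p: float                    # two-sided normal p
    p_one_sided: float          # P(Z <= z): small when auc_1 < auc_2
    var_diff: float
    degenerate: bool = False    # True when the variance estimate is 0
    v01: np.ndarray | None = field(default=None, repr=False)
    v10: np.ndarray | None = field(default=None, repr=False)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_components(scores: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-positive (V01) and per-negative (V10) structural
    components of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    a = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    return float(a), v01, v10


def delong_test(scores_1, scores_2, labels) -> AUCComparison:
    """Compare two correlated AUCs measured on the same samples.

    Uses the fast structural-components estimator of the paired
    covariance; ``z = (auc_1 - auc_2)/sqrt(var)`` with a standard-normal
    reference.  When the estimated variance of the difference is zero
    (e.g. identical score vectors) the comparison is flagged degenerate
    and ``p = 1`` is reported.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = _check_labels(labels)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("scores_1, scores_2 and labels must share one shape")

    a1, v01_1, v10_1 = delong_components(s1, labels)
    a2, v01_2, v10_2 = delong_components(s2, labels)
    m, n = v01_1.size, v10_1.size
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
    cov = s01 / m + s10 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])

    if var_diff <= 0 or not np.isfinite(var_diff):
        return AUCComparison(a1, a2, z=0.0, p=1.0, p_one_sided=0.5,
                             var_diff=max(var_diff, 0.0), degenerate=True,
                             v01=np.stack([v01_1, v01_2]),
                             v10=np.stack([v10_1, v10_2]))
    z = (a1 - a2) / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return AUCComparison(a1, a2, z=float(z), p=p,
                         p_one_sided=float(sps.norm.cdf(z)),
                         var_diff=var_diff,
                         v01=np.stack([v01_1, v01_2]),
                         v10=np.stack([v10_1, v10_2]))


# ---------------------------------------------------------------------------
# Label-permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed statistic, its permutation null sample, and the
    add-one-corrected p-value ``(1 + #{null >= observed}) / (B + 1)``."""

    observed: float
    null_sample: np.ndarray
    p: float
    n_permutations: int
    seed: int


def permutation_test(statistic_fn, table, labels, B: int = 999,
                     seed: int = 0) -> PermutationResult:
    """Permute ``labels`` B times and recompute ``statistic_fn(table,
    labels)`` under each permutation.

    ``statistic_fn`` maps (table, labels) -> real; any exception it
    raises is re-raised annotated with the permutation index.  The
    p-value uses the (B+1) correction so it is never exactly zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(table, labels))
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(labels)
        try:
            null[b] = statistic_fn(table, perm)
        except Exception as err:
            raise RuntimeError(f"statistic failed at permutation {b}: {err}") from err
    p = (1.0 + np.count_nonzero(null >= observed)) / (B + 1.0)
    return PermutationResult(observed=observed, null_sample=null, p=float(p),
                             n_permutations=B, seed=seed)


# ---------------------------------------------------------------------------
# Preprocessing-group AUC comparisons
# ---------------------------------------------------------------------------

def compare_auc_groups(results: pd.DataFrame, factor: str,
                       value: str = "auc_mean") -> dict:
    """Summarise per-configuration AUCs by the levels of one grid factor.

    ``results`` is a tidy frame with one row per configuration, a column
    per config field and the averaged AUC columns.  Returns per-level
    mean AUC with a 95% percentile interval of the per-config AUC
    distribution, plus pairwise two-sided Welch-t and Mann-Whitney
    p-values.  Levels with fewer than two configurations are skipped
    with a warning.
    """
    if factor not in results.columns:
        raise KeyError(f"factor {factor!r} not in results")
    groups = {}
    for level, sub in results.groupby(factor, sort=False):
        v = sub[value].to_numpy(dtype=float)
        if v.size < 2:
            logger.warning("factor %s level %r has <2 configs; skipped",
                           factor, level)
            continue
        groups[level] = v
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 usable levels")

    summary = pd.DataFrame({
        level: {
            "n_configs": v.size,
            "mean_auc": v.mean(),
            "ci_low": np.percentile(v, 2.5),
            "ci_high": np.percentile(v, 97.5),
        } for level, v in groups.items()
    }).T.rename_axis(factor)

    levels = list(groups)
    pairwise = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            va, vb = groups[a], groups[b]
            if np.array_equal(va, vb) or (np.ptp(va) == 0 and np.ptp(vb) == 0
                                          and va[0] == vb[0]):
                t_p, u_p = 1.0, 1.0
            else:
                t_p = float(sps.ttest_ind(va, vb, equal_var=False).pvalue)
                u_p = float(sps.mannwhitneyu(va, vb,
                                             alternative="two-sided").pvalue)
            pairwise.append({"level_1": a, "level_2": b,
                             "mean_diff": float(va.mean() - vb.mean()),
                             "p_welch": t_p, "p_mannwhitney": u_p})
    return {"summary": summary, "pairwise": pd.DataFrame(pairwise)}


# ---------------------------------------------------------------------------
# Clinical characteristic tests
# ---------------------------------------------------------------------------

def clinical_tests(sample_meta: pd.DataFrame, outcome_col: str = "outcome",
                   categorical=("ER", "PR", "HER2"),
                   continuous=()) -> pd.DataFrame:
    """Association of each clinical variable with the pCR outcome.

    Categorical variables: chi-square test of independence, with
    Fisher's exact test as fallback when any expected cell count is
    below 5 (2x2 tables only).  Continuous variables: Welch t-test.
    Variables with a single observed level are skipped with a warning.
    """
    if outcome_col not in sample_meta:
        raise KeyError(f"outcome column {outcome_col!r} missing")
    y = sample_meta[outcome_col].astype(int)
    rows = []
    for var in categorical:
        if var not in sample_meta:
            continue
        x = sample_meta[var]
        if x.nunique() < 2:
            logger.warning("clinical variable %s has one level; skipped", var)
            continue
        ct = pd.crosstab(x, y)
        chi2, p, dof, expected = sps.chi2_contingency(ct, correction=False)
        test = "chi-square"
        if (expected < 5).any() and ct.shape == (2, 2):
            p = float(sps.fisher_exact(ct.to_numpy()).pvalue)
            test = "fisher"
        rows.append({"variable": var, "test": test, "p": float(p)})
    for var in continuous:
        if var not in sample_meta:
            continue
        x = sample_meta[var].astype(float)
        if x.nunique() < 2:
            logger.warning("clinical variable %s has one level; skipped", var)
            continue
        res = sps.ttest_ind(x[y == 1], x[y == 0], equal_var=False)
        rows.append({"variable": var, "test": "welch-t", "p": float(res.pvalue)})
    return pd.DataFrame(rows)
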