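"""Partition concordance, proportion tests, and cohort description tables.

Helpers for the reproducibility side of the analysis: matching two
partitions of (partly) shared patients under the best label bijection,
chi-squared comparison of endotype proportions across cohorts, and
Table-1-style covariate summaries with the conventional test routing
(Shapiro-Wilk -> ANOVA / Kruskal-Wallis for continuous covariates,
chi-squared / Fisher's exact for categorical ones).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = ["ConcordanceResult", "partition_concordance", "proportion_test", "describe_table"]

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Best bijective label matching between two partitions."""

    mapping: dict  # cluster of A -> cluster of B
    agreement: float
    n_common: int


def partition_concordance(
    patients_a, assignment_a, patients_b, assignment_b, k: int | None = None
) -> ConcordanceResult:
    """Agreement between two partitions under the best label bijection.

    Only patients present in both partitions count. For k <= 6 the bijection
    maximizing matched patients is found by exhaustive permutation search;
    larger k uses the assignment-problem solver on the contingency table.
    """
    a = pd.Series(np.asarray(assignment_a), index=np.asarray(patients_a))
    b = pd.Series(np.asarray(assignment_b), index=np.asarray(patients_b))
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("partitions share no patients")
    a, b = a.loc[common], b.loc[common]
    ka, kb = a.nunique(), b.nunique()
    k = k if k is not None else max(ka, kb)
    if ka > k or kb > k:
        raise ValueError(f"partitions have different cluster counts ({ka} vs {kb})")

    labels_a = sorted(a.unique())
    labels_b = sorted(b.unique())
    # pad to k labels so the mapping stays a bijection even with empty clusters
    table = np.zeros((k, k), dtype=int)
    ia = {lab: i for i, lab in enumerate(labels_a)}
    ib = {lab: i for i, lab in enumerate(labels_b)}
    for la, lb in zip(a, b):
        table[ia[la], ib[lb]] += 1

    if k <= 6:
        best_perm, best_matched = None, -1
        for perm in itertools.permutations(range(k)):
            matched = sum(table[i, perm[i]] for i in range(k))
            if matched > best_matched:
                best_matched, best_perm = matched, perm
        cols = best_perm
    else:
        rows, cols_arr = linear_sum_assignment(-table)
        cols = [int(cols_arr[list(rows).index(i)]) for i in range(k)]
        best_matched = int(table[np.arange(k), cols].sum())

    inv_a = {i: lab for lab, i in ia.items()}
    inv_b = {i: lab for lab, i in ib.items()}
    mapping = {inv_a.get(i, i): inv_b.get(cols[i], cols[i]) for i in range(k)}
    return ConcordanceResult(mapping=mapping, agreement=best_matched / len(common), n_common=len(common))


def proportion_test(counts_a, counts_b):
    """Pearson chi-squared on the k x 2 endotype-by-cohort count table.

    Categories empty in both cohorts are dropped (df shrinks accordingly).
    Returns (statistic, df, p, warning_flag) where the flag marks an
    expected cell below 1.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if ca.shape != cb.shape:
        raise ValueError("count vectors differ in length")
    if ca.sum() <= 0 or cb.sum() <= 0:
        raise ValueError("each cohort needs a positive total")
    keep = (ca + cb) > 0
    if not keep.all():
        logger.info("dropping %d empty endotype categories from proportion test", int((~keep).sum()))
    table = np.column_stack([ca[keep], cb[keep]])
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p), bool((expected < 1).any())


def _categorical_test(table: np.ndarray, rng: np.random.Generator):
    """Chi-squared or Fisher routing for a levels x groups count table."""
    stat, p, dof, expected = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
    if (expected < 5).any():
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return "fisher", float(p)
        # r x c exact test approximated by Monte-Carlo permutation of the
        # uncorrected chi-squared statistic under fixed margins
        stat0 = stats.chi2_contingency(table, correction=False)[0]
        groups = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
        levels = np.concatenate([np.repeat(np.arange(table.shape[0]), table[:, j].astype(int)) for j in range(table.shape[1])])
        n_sim = 2000
        count = 0
        for _ in range(n_sim):
            perm = rng.permutation(levels)
            sim = np.zeros_like(table)
            for g in range(table.shape[1]):
                vals, cnts = np.unique(perm[groups == g], return_counts=True)
                sim[vals, g] = cnts
            s = stats.chi2_contingency(sim, correction=False)[0]
            if s >= stat0 - 1e-12:
                count += 1
        return "fisher-mc", float((count + 1) / (n_sim + 1))
    name = "chi2-yates" if table.shape == (2, 2) else "chi2"
    return name, float(p)


def describe_table(
    rows: pd.DataFrame,
    group_col: str,
    covariates: dict | None = None,
    alpha_normal: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-covariate cohort description with the conventional test routing.

    ``covariates`` maps column name to "continuous" or "categorical";
    unlisted columns are inferred from dtype. Continuous covariates are
    summarized as median [IQR] and mean (SD) per group, tested by ANOVA when
    every group passes Shapiro-Wilk at ``alpha_normal``, else
    Kruskal-Wallis. Categorical covariates get counts (%) with chi-squared
    (Yates-corrected for 2x2) or Fisher's exact when an expected cell is
    below 5 (Monte-Carlo version beyond 2x2, seeded).
    """
    if group_col not in rows.columns:
        raise ValueError(f"missing group column {group_col!r}")
    rng = np.random.default_rng(seed)
    groups = [g for g, _ in rows.groupby(group_col, sort=True)]
    if covariates is None:
        covariates = {
            c: ("continuous" if pd.api.types.is_numeric_dtype(rows[c]) else "categorical")
            for c in rows.columns
            if c != group_col
        }

    out = []
    for cov, kind in covariates.items():
        col = rows[cov]
        if col.isna().all():
            logger.warning("covariate %r all-missing; skipped", cov)
            continue
        if kind == "continuous":
            by = [col[rows[group_col] == g].dropna().to_numpy(dtype=float) for g in groups]
            normal = all(len(v) >= 3 and stats.shapiro(v).pvalue >= alpha_normal for v in by)
            if normal:
                test, (stat, p) = "anova", stats.f_oneway(*by)
            else:
                test, (stat, p) = "kruskal", stats.kruskal(*by)
            summary = {
                str(g): f"{np.median(v):.1f} [{np.percentile(v, 25):.1f}-{np.percentile(v, 75):.1f}]; "
                f"{np.mean(v):.1f} ({np.std(v, ddof=1):.1f})"
                for g, v in zip(groups, by)
            }
        elif kind == "categorical":
            table_df = pd.crosstab(col, rows[group_col])
            table = table_df.to_numpy(dtype=float)
            if table.shape[0] < 2:
                logger.warning("covariate %r has a single level; skipped", cov)
                continue
            test, p = _categorical_test(table, rng)
            stat = np.nan
            summary = {
                str(g): "; ".join(
                    f"{lev}: {int(table_df.loc[lev, g])} ({100 * table_df.loc[lev, g] / table_df[g].sum():.1f}%)"
                    for lev in table_df.index
                )
                for g in groups
            }
        else:
            raise ValueError(f"covariate {cov!r}: unknown kind {kind!r}")
        out.append({"covariate": cov, "kind": kind, "test": test, "statistic": float(stat), "p": float(p), **summary})
    return pd.DataFrame(out)
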