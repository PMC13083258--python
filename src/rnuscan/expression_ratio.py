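"""Paralog expression-ratio biomarker and shared splicing-outlier test.

U2 snRNA has two near-identical paralogs: U2-2, a single-copy gene on
chromosome 11, and U2-1, a tandem repeat array on chromosome 17.  Because
their expression is highly correlated across individuals, the U2-2:U2-1
ratio of chromosome-normalized abundances (reads per million unique reads
on the gene's own chromosome) is a more specific marker of U2-2 depletion
than U2-2 expression alone.  This module computes RPM values and ratios,
compares groups with rank tests and OLS/Pearson fits, provides a simple
robust-z expression-outlier caller (a stand-in, not the published
autoencoder-based method) and tests whether cases share more aberrant
splicing events than random control subsets via a percentile-bootstrap
permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationFit",
    "SharedEventResult",
    "rpm_normalize",
    "paralog_ratio",
    "flag_against_reference",
    "quantify_expression",
    "mann_whitney_two_tailed",
    "correlation_fit",
    "expression_outliers",
    "count_shared_events",
    "shared_event_permutation",
]


def rpm_normalize(gene_count: float, chromosome_total: float) -> float:
    """Reads per million: gene count / chromosome unique-read total * 1e6."""
    if chromosome_total <= 0:
        raise ValueError("chromosome total must be > 0")
    if gene_count < 0:
        raise ValueError("gene count must be >= 0")
    return gene_count / chromosome_total * 1e6


def paralog_ratio(rpm_u2_2: float, rpm_u2_1: float) -> float:
    """U2-2:U2-1 expression ratio; requires RPM(U2-1) > 0."""
    if rpm_u2_1 <= 0:
        raise ValueError("ratio undefined: RPM(U2-1) must be > 0")
    if rpm_u2_2 < 0:
        raise ValueError("RPM(U2-2) must be >= 0")
    return rpm_u2_2 / rpm_u2_1


def flag_against_reference(
    ratio: float, reference_low: float, reference_high: float | None = None
) -> bool:
    """Flag a ratio falling outside a control reference interval.

    With only ``reference_low`` given, flags ratios below it (depletion);
    with both bounds, flags ratios outside [low, high].
    """
    if ratio < reference_low:
        return True
    if reference_high is not None and ratio > reference_high:
        return True
    return False


def quantify_expression(
    counts: pd.DataFrame,
    u2_2_gene: str = "RNU2-2",
    u2_1_gene: str = "RNU2-1",
) -> pd.DataFrame:
    """Per-sample RPM and ratio table from a long-format count table.

    ``counts`` columns: sample_id, gene_id, count, chromosome,
    chromosome_total.  U2-1 counts are accepted pre-summed over its repeat
    array copies.  Returns one row per sample with rpm_u2_2, rpm_u2_1 and
    ratio.
    """
    required = {"sample_id", "gene_id", "count", "chromosome_total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    rows = []
    for sample, sub in counts.groupby("sample_id", sort=True):
        by_gene = sub.set_index("gene_id")
        record = {"sample_id": sample}
        for gene, key in ((u2_2_gene, "u2_2"), (u2_1_gene, "u2_1")):
            if gene not in by_gene.index:
                raise KeyError(f"sample {sample}: no counts for gene {gene}")
            row = by_gene.loc[gene]
            record[f"rpm_{key}"] = rpm_normalize(
                float(row["count"]), float(row["chromosome_total"])
            )
        record["ratio"] = paralog_ratio(record["rpm_u2_2"], record["rpm_u2_1"])
        rows.append(record)
    return pd.DataFrame(rows)


def mann_whitney_two_tailed(
    sample_x: Sequence[float], sample_y: Sequence[float]
) -> float:
    """Two-tailed Mann-Whitney U test p value.

    Uses exact enumeration when the combined sample size is at most 20 and
    the pooled data are tie-free, and the normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass(frozen=True)
class CorrelationFit:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def correlation_fit(x: Sequence[float], y: Sequence[float]) -> CorrelationFit:
    """Pearson correlation with two-sided test and the OLS regression line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationFit(
        r=float(r), p=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), n=int(x.size),
    )


def expression_outliers(
    rpm_values,
    flag_threshold: float = 3.0,
    min_samples: int = 20,
    mad_epsilon: float = 1e-12,
) -> pd.DataFrame:
    """Robust-z expression outliers on log RPM.

    z = (ln(RPM + 1) - median) / (MAD * 1.4826); a sample is flagged iff
    |z| >= ``flag_threshold``.  With MAD below ``mad_epsilon`` (e.g. all
    samples equal) every z is 0 and nothing is flagged.  This is a simple
    robust stand-in, not the published autoencoder-based outlier caller;
    results carry a ``method`` column saying so.
    """
    series = pd.Series(rpm_values, dtype=float)
    if series.size < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples for outlier calling, got {series.size}"
        )
    if (series < 0).any():
        raise ValueError("RPM values must be >= 0")
    log_rpm = np.log(series + 1.0)
    med = float(np.median(log_rpm))
    mad = float(np.median(np.abs(log_rpm - med)))
    if mad < mad_epsilon:
        z = pd.Series(0.0, index=series.index)
    else:
        z = (log_rpm - med) / (mad * 1.4826)
    return pd.DataFrame(
        {
            "rpm": series,
            "z": z,
            "outlier": z.abs() >= flag_threshold,
            "method": "robust_z_log_rpm",
        }
    )


def count_shared_events(event_matrix: pd.DataFrame, sample_ids) -> int:
    """Events flagged in more than one of the given samples (once per event)."""
    ids = list(sample_ids)
    missing = set(ids) - set(event_matrix.columns)
    if missing:
        raise KeyError(f"samples absent from event matrix: {sorted(missing)}")
    sub = event_matrix[ids].astype(bool)
    return int((sub.sum(axis=1) > 1).sum())


@dataclass(frozen=True)
class SharedEventResult:
    observed: int
    null: np.ndarray
    n_perm: int
    seed: object
    p: float
    p_bonferroni: float
    n_tests: int


def shared_event_permutation(
    event_matrix: pd.DataFrame,
    case_ids,
    n_perm: int = 1000,
    seed=None,
    n_tests: int = 8,
) -> SharedEventResult:
    """Do cases share more outlier events than random control subsets?

    ``event_matrix`` is a Boolean events x samples table of nominally
    significant outlier calls (one matrix per aberrant-splicing event
    class).  The observed statistic is the number of events flagged in more
    than one case; the null is the same statistic over ``n_perm`` random
    equal-size control subsets.  Two-sided percentile-bootstrap p: doubled
    smaller add-one tail, floored at 1/(n_perm+1) and capped at 1;
    Bonferroni correction over ``n_tests`` event classes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cases = list(case_ids)
    controls = [c for c in event_matrix.columns if c not in set(cases)]
    if len(controls) < len(cases):
        raise ValueError(
            f"need >= {len(cases)} controls, found {len(controls)}"
        )
    observed = count_shared_events(event_matrix, cases)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(controls, size=len(cases), replace=False)
        null[i] = count_shared_events(event_matrix, list(draw))
    p_high = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    p_low = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_high, p_low))
    return SharedEventResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        seed=seed,
        p=p,
        p_bonferroni=min(1.0, p * n_tests),
        n_tests=n_tests,
    )
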