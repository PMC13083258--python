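"""Exact 2x2 association statistics and the per-gene enrichment scan.

Case/control enrichment of rare biallelic genotypes is tested per gene with
a two-sided Fisher's exact test on the carriers-vs-non-carriers 2x2 table,
Bonferroni-corrected over the genes actually tested (those with at least
one carrier anywhere).  Odds ratios default to the cross-product estimator
with Woolf (log-scale normal) confidence intervals; tables containing a
zero cell can be handled with the Haldane-Anscombe correction (0.5 added to
every cell), which keeps the OR finite.  Benjamini-Hochberg FDR adjustment
and the chi-squared goodness-of-fit test used by the transmission analysis
live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwoTable",
    "EnrichmentResult",
    "GofResult",
    "ScanResult",
    "DegenerateTableError",
    "fisher_exact_2x2",
    "odds_ratio_ha",
    "snrna_enrichment_scan",
    "bh_adjust",
    "bonferroni_adjust",
    "chisq_goodness_of_fit",
]


class DegenerateTableError(ValueError):
    """A 2x2 table has an empty row or column margin and cannot be tested."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b, c, d) = (cases with, cases without, controls with,
    controls without)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError(f"table cells must be nonnegative integers: {self}")

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def check_margins(self) -> None:
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DegenerateTableError(f"empty row margin: {self}")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise DegenerateTableError(f"empty column margin: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    p: float
    estimator: str = "cross_product"
    ci_method: str = "woolf"


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p: float


def _as_table(table) -> TwoByTwoTable:
    if isinstance(table, TwoByTwoTable):
        return table
    flat = np.asarray(table).ravel()
    if flat.size != 4:
        raise ValueError("expected a 2x2 table")
    return TwoByTwoTable(*(int(x) for x in flat))


def _woolf_ci(a, b, c, d, ci_level: float) -> tuple:
    """Woolf log-OR interval; (0, inf) when undefined (a zero cell)."""
    if min(a, b, c, d) <= 0:
        return (0.0, math.inf)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def _cross_product(a, b, c, d) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_2x2(
    table,
    ci_level: float = 0.95,
    estimator: str = "cross_product",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test with odds ratio and Woolf CI.

    The two-sided p value follows the point-probability convention: the sum
    over all tables with the observed margins whose hypergeometric point
    probability does not exceed the observed table's.  ``estimator`` selects
    the OR point estimate: "cross_product" (ad/bc, default) or
    "conditional" (conditional maximum likelihood).
    """
    t = _as_table(table)
    t.check_margins()
    p = float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])
    if estimator == "cross_product":
        oratio = _cross_product(*t.cells)
    elif estimator == "conditional":
        oratio = float(stats.contingency.odds_ratio(t.as_array()).statistic)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    low, high = _woolf_ci(*t.cells, ci_level)
    return EnrichmentResult(
        odds_ratio=oratio,
        ci_low=low,
        ci_high=high,
        ci_level=ci_level,
        p=min(p, 1.0),
        estimator=estimator,
    )


def odds_ratio_ha(table, ci_level: float = 0.95) -> EnrichmentResult:
    """Cross-product OR with Haldane-Anscombe correction for zero cells.

    If any cell is zero, 0.5 is added to all four cells before computing the
    OR and its Woolf interval, keeping both finite; otherwise identical to
    the uncorrected cross-product estimate.  The p value is not corrected
    and is reported as NaN (use :func:`fisher_exact_2x2` for testing).
    """
    t = _as_table(table)
    a, b, c, d = t.cells
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EnrichmentResult(
        odds_ratio=oratio,
        ci_low=oratio * math.exp(-z * se),
        ci_high=oratio * math.exp(z * se),
        ci_level=ci_level,
        p=math.nan,
        estimator="haldane_anscombe",
    )


@dataclass
class ScanResult:
    """Per-gene enrichment scan output with its Bonferroni threshold."""

    results: pd.DataFrame
    n_tests: int
    alpha: float
    threshold: float

    def significant_genes(self) -> list:
        return sorted(self.results.loc[self.results["significant"], "gene"])


def snrna_enrichment_scan(
    per_gene_case_counts: Mapping[str, int],
    per_gene_control_counts: Mapping[str, int],
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    ci_level: float = 0.95,
) -> ScanResult:
    """Fisher-test biallelic carrier counts per gene, Bonferroni-corrected.

    Genes with zero carriers in both cohorts are excluded from testing; the
    significance threshold is ``alpha`` divided by the number of genes
    actually tested.  Each tested gene contributes a carriers vs
    non-carriers 2x2 table.  Run separate scans per genotype class
    (homozygous-only, compound-het-only, combined) by passing the
    corresponding counts.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    genes = sorted(set(per_gene_case_counts) | set(per_gene_control_counts))
    rows = []
    for gene in genes:
        k_case = int(per_gene_case_counts.get(gene, 0))
        k_ctrl = int(per_gene_control_counts.get(gene, 0))
        if k_case > n_cases or k_ctrl > n_controls:
            raise ValueError(
                f"gene {gene}: carrier count exceeds cohort size "
                f"({k_case}/{n_cases} cases, {k_ctrl}/{n_controls} controls)"
            )
        if k_case == 0 and k_ctrl == 0:
            continue
        res = fisher_exact_2x2(
            TwoByTwoTable(k_case, n_cases - k_case, k_ctrl, n_controls - k_ctrl),
            ci_level=ci_level,
        )
        rows.append(
            {
                "gene": gene,
                "case_carriers": k_case,
                "control_carriers": k_ctrl,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    n_tests = len(rows)
    threshold = alpha / n_tests if n_tests else math.nan
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "case_carriers",
            "control_carriers",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "p",
        ],
    )
    df["significant"] = df["p"] < threshold if n_tests else False
    return ScanResult(results=df, n_tests=n_tests, alpha=alpha, threshold=threshold)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def chisq_goodness_of_fit(
    observed_counts: Sequence[float],
    expected_probabilities: Sequence[float],
) -> GofResult:
    """Chi-squared goodness of fit of observed counts to expected ratios.

    ``statistic = sum (O_i - E_i)^2 / E_i`` with ``E_i = N * p_i``,
    ``df = k - 1`` and an upper-tail chi-squared p value.
    """
    observed = np.asarray(observed_counts, dtype=float)
    probs = np.asarray(expected_probabilities, dtype=float)
    if observed.shape != probs.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(probs <= 0):
        raise ValueError("every expected probability must be > 0")
    if not math.isclose(float(probs.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected probabilities must sum to 1")
    expected = observed.sum() * probs
    statistic, p = stats.chisquare(observed, f_exp=expected)
    return GofResult(statistic=float(statistic), df=observed.size - 1, p=float(p))
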