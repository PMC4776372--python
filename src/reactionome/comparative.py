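"""Between-species statistical battery for category and transition tables.

Implements the comparison conventions used throughout the analysis:

* Pearson χ² tests of independence on r × c count tables, with Yates
  continuity correction for 2 × 2 tables;
* a one-proportion χ² test (with continuity correction) for whether the two
  species contribute responsive transcripts in equal proportion;
* the Stuart–Maxwell test of marginal homogeneity on the paired 5 × 5
  category transition table;
* observed-minus-expected deviation matrices under marginal independence;
* pooled-variance two-sample t-tests and Wilcoxon/Mann–Whitney rank tests
  for induction-temperature and baseline-expression comparisons.

The Pearson and one-proportion statistics are written out from their closed
forms rather than delegated, because the exact correction conventions are
what the package reproduces; scipy serves as an independent cross-check in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DegenerateDataError, NumericalError

__all__ = [
    "TestResult",
    "chi_square_independence",
    "one_proportion_test",
    "stuart_maxwell",
    "deviation_matrix",
    "students_t_test",
    "paired_rank_test",
    "aphaenogaster_category_counts",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    method: str
    correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise NumericalError(f"p-value out of range: {self.p}")


def aphaenogaster_category_counts() -> pd.DataFrame:
    """Published category counts for the two-Aphaenogaster thermal study.

    Thermally responsive transcript counts by expression type for the
    cool-climate *A. picea* and warm-climate *A. carolinensis* (2078
    transcripts per species).  Bundled as the reference fixture for the
    comparative battery.
    """
    return pd.DataFrame(
        [[1193, 249, 248, 278, 110],
         [920, 680, 232, 117, 129]],
        index=pd.Index(["A_picea", "A_carolinensis"], name="species"),
        columns=["Low", "Intermediate", "High", "Bimodal", "NotResp"],
    )


def _as_count_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ContractError("count table must be two-dimensional")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ContractError("count table must hold non-negative integers")
    return arr


def chi_square_independence(table, yates: bool = False) -> TestResult:
    """Pearson χ² test of independence on an r × c count table.

    Expected counts come from the row/column margins.  With ``yates`` (2 × 2
    only) each |O − E| is reduced by 0.5, floored at 0, before squaring.
    """
    obs = _as_count_table(table)
    r, c = obs.shape
    if yates and obs.shape != (2, 2):
        raise ContractError("Yates correction applies only to 2×2 tables")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateDataError("zero row or column margin")
    expected = np.outer(rows, cols) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev * dev / expected))
    df = (r - 1) * (c - 1)
    return TestResult(statistic, df, float(stats.chi2.sf(statistic, df)),
                      method="pearson-chi2", correction=yates)


def one_proportion_test(successes: int, n: int, p0: float,
                        correction: bool = True) -> TestResult:
    """χ² test of a binomial proportion against ``p0`` (df = 1).

    ``correction`` applies the 0.5 continuity adjustment to |successes − n·p0|.
    """
    if n <= 0:
        raise DegenerateDataError("n must be positive")
    if not 0 <= successes <= n:
        raise ContractError(f"successes {successes} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ContractError("p0 must lie strictly in (0, 1)")
    dev = abs(successes - n * p0)
    if correction:
        dev = max(dev - 0.5, 0.0)
    statistic = dev * dev / (n * p0 * (1.0 - p0))
    return TestResult(float(statistic), 1, float(stats.chi2.sf(statistic, 1)),
                      method="one-proportion-chi2", correction=correction)


def stuart_maxwell(table) -> TestResult:
    """Stuart–Maxwell test of marginal homogeneity on a paired k × k table.

    With ``d`` the first k−1 row-minus-column marginal differences and ``S``
    their covariance under marginal homogeneity
    (``S_ii = row_i + col_i − 2 n_ii``, ``S_ij = −(n_ij + n_ji)``), the
    statistic is ``dᵀ S⁻¹ d`` on k−1 degrees of freedom, solved through a
    pseudo-inverse so that structurally empty categories do not abort the
    test.  Reduces to the uncorrected McNemar statistic for k = 2.
    """
    obs = _as_count_table(table)
    k = obs.shape[0]
    if obs.shape[1] != k or k < 2:
        raise ContractError("Stuart–Maxwell needs a square k×k table, k ≥ 2")
    off = obs.sum() - np.trace(obs)
    if off == 0:
        raise DegenerateDataError(
            "all observations on the diagonal; margins identical by construction"
        )
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    d = (rows - cols)[: k - 1]
    S = np.empty((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                S[i, j] = rows[i] + cols[i] - 2.0 * obs[i, i]
            else:
                S[i, j] = -(obs[i, j] + obs[j, i])
    try:
        Sinv = np.linalg.pinv(S, rcond=1e-12)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise NumericalError(f"covariance pseudo-inverse failed: {exc}")
    statistic = float(d @ Sinv @ d)
    if statistic < -1e-8:
        raise NumericalError(
            f"negative quadratic form ({statistic}); S conditioning "
            f"eigvals={np.linalg.eigvalsh(S)}"
        )
    statistic = max(statistic, 0.0)
    df = k - 1
    return TestResult(statistic, df, float(stats.chi2.sf(statistic, df)),
                      method="stuart-maxwell")


def deviation_matrix(table) -> pd.DataFrame:
    """Observed − expected counts under independence of the margins.

    Cells sum to zero; positive cells mark an excess of transcripts over the
    margins-only expectation.
    """
    obs = _as_count_table(table)
    total = obs.sum()
    if total <= 0:
        raise DegenerateDataError("empty table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    dev = obs - expected
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(dev, index=table.index, columns=table.columns)
    return pd.DataFrame(dev)


def students_t_test(x, y) -> TestResult:
    """Two-sample pooled-variance t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ContractError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    delta = float(np.mean(x) - np.mean(y))
    if sp2 <= 0.0:
        if abs(delta) < 1e-12:
            return TestResult(0.0, df, 1.0, method="student-t")
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TestResult(float(t), df, float(2.0 * stats.t.sf(abs(t), df)),
                      method="student-t")


def paired_rank_test(x, y, paired: bool = True) -> TestResult:
    """Wilcoxon signed-rank (paired) or Mann–Whitney rank-sum (unpaired).

    Paired mode reports V, the sum of ranks of positive differences
    ``y − x`` (zero differences dropped, ties mid-ranked) with a tie-corrected
    normal-approximation p.  Unpaired mode reports the Mann–Whitney U for x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ContractError("paired test requires equal-length samples")
        d = y - x
        d = d[d != 0.0]
        n = len(d)
        if n == 0:
            raise DegenerateDataError("all paired differences are zero")
        ranks = stats.rankdata(np.abs(d))
        v = float(ranks[d > 0].sum())
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            raise DegenerateDataError("degenerate signed-rank variance")
        z = (v - mu) / np.sqrt(sigma2)
        return TestResult(v, n, float(2.0 * stats.norm.sf(abs(z))),
                          method="wilcoxon-signed-rank")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(float(res.statistic), len(x) + len(y),
                      float(res.pvalue), method="mann-whitney-u")
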