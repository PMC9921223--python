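"""Nonparametric statistics: Spearman, Mann-Whitney U, Bonferroni.

Performance and connectivity values carry no normality guarantee, so every
test here is rank-based.  Reproducibility rules are pinned explicitly:

* Spearman's rho is computed on mean ranks (ties averaged).  The two-sided
  p-value uses the t-approximation for n > 10 and exact permutation
  enumeration (all n! orderings, conditional on the observed ties) for
  n <= 10.
* Mann-Whitney U reports U for the first sample.  The p-value is exact
  when n1*n2 <= 400 and the pooled data has no ties, otherwise the normal
  approximation with tie correction (and continuity correction) is used.
* Bonferroni correction is min(1, m * p); family sizes are always computed
  from the actual decomposition or connection count, never hard-coded.

All tests are two-sided: motif-behavior correlations of either sign are
meaningful.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, DomainError, UsageError
from .io import ConnectomeCohort, stack

SPEARMAN_EXACT_MAX_N = 10
MANNWHITNEY_EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test with its Bonferroni-corrected p-value."""

    name: str
    statistic: float
    p_raw: float
    p_corrected: float
    n: int
    family_size: int
    alpha: float = 0.05
    variable: str = ""
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_corrected < self.alpha


def bonferroni(p_raw: float, family_size: int) -> float:
    """Family-wise corrected p-value: min(1, family_size * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise DomainError(f"p-value {p_raw} outside [0, 1]")
    if family_size < 1:
        raise DomainError("family size must be >= 1")
    return min(1.0, p_raw * family_size)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho on given rank vectors.

    Enumerates all n! orderings of the y ranks (conditional on ties) and
    counts |rho| >= |rho_obs|.  Chunked so n = 10 stays within memory.
    """
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt(np.sum(rxc**2) * np.sum(ryc**2))
    target = abs(rho_obs) * denom - 1e-12
    hits = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    chunk_size = 100_000

    def flush(chunk: list[tuple[int, ...]]) -> int:
        perm = np.array(chunk, dtype=np.intp)
        perm_dots = np.abs(ryc[perm] @ rxc)
        return int(np.count_nonzero(perm_dots >= target))

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == chunk_size:
            hits += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        hits += flush(chunk)
        total += len(chunk)
    return hits / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Raises :class:`DegenerateInputError` for constant input rather than
    returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise UsageError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        # t-approximation: t = rho * sqrt((n-2) / (1-rho^2))
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        return x.size * y.size / 2.0, 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    exact = (x.size * y.size <= MANNWHITNEY_EXACT_MAX_PRODUCT) and no_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_vectorized(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise asymptotic Mann-Whitney over (n1, k) vs (n2, k) arrays.

    Constant pooled columns get U = n1*n2/2 and p = 1 (the tie-corrected
    normal approximation is 0/0 there).
    """
    n1, n2 = X.shape[0], Y.shape[0]
    pooled = np.vstack([X, Y])
    constant = np.ptp(pooled, axis=0) == 0
    U = np.full(X.shape[1], n1 * n2 / 2.0)
    p = np.ones(X.shape[1])
    todo = ~constant
    if np.any(todo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.mannwhitneyu(
                X[:, todo], Y[:, todo], alternative="two-sided",
                method="asymptotic", axis=0,
            )
        U[todo] = res.statistic
        p[todo] = res.pvalue
    return U, np.clip(p, 0.0, 1.0)


def connectionwise_group_test(
    cohort: ConnectomeCohort,
    scan_x: str,
    scan_y: str,
    alpha: float = 0.05,
    mode: str = "symmetric",
    subjects: list[str] | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Group-level per-connection test between two scan time points.

    One Mann-Whitney U test per vectorized connection compares the
    cross-subject distribution of that connection's value at ``scan_x``
    against ``scan_y``; Bonferroni family = number of connections tested
    (``symmetric`` mode on 185 regions: 17,020).  ``paired=True`` swaps in
    the Wilcoxon signed-rank test on within-subject differences — the
    scans are paired within subject, but the independent-sample test is
    the default convention here.

    Returns a DataFrame (source, target, statistic, p_raw, p_corrected,
    significant) with ``family_size`` in ``.attrs``.
    """
    if subjects is None:
        subjects = [
            s for s in cohort.subjects if cohort.has(s, scan_x) and cohort.has(s, scan_y)
        ]
    if len(subjects) < 3:
        warnings.warn(
            f"only {len(subjects)} subjects with both scans: tests have little power",
            stacklevel=2,
        )
    Mx, _, index_map = stack(cohort, [scan_x], mode=mode, subjects=subjects)
    My, _, _ = stack(cohort, [scan_y], mode=mode, subjects=subjects)
    X = Mx.T  # (n_subjects, n_connections)
    Y = My.T
    n1, n2 = X.shape[0], Y.shape[0]
    k = X.shape[1]

    if paired:
        diffs = Y - X
        U = np.zeros(k)
        p = np.ones(k)
        for j in range(k):
            d = diffs[:, j]
            if np.all(d == 0):
                continue
            res = sps.wilcoxon(d, alternative="two-sided")
            U[j], p[j] = float(res.statistic), float(res.pvalue)
    elif n1 * n2 <= MANNWHITNEY_EXACT_MAX_PRODUCT:
        U = np.zeros(k)
        p = np.ones(k)
        for j in range(k):
            U[j], p[j] = mann_whitney_u(X[:, j], Y[:, j])
    else:
        U, p = _mann_whitney_vectorized(X, Y)

    p_corr = np.minimum(1.0, p * k)
    df = pd.DataFrame(
        {
            "source": [s for s, _ in index_map],
            "target": [t for _, t in index_map],
            "statistic": U,
            "p_raw": p,
            "p_corrected": p_corr,
            "significant": p_corr < alpha,
        }
    )
    df.attrs["family_size"] = k
    df.attrs["n_subjects"] = len(subjects)
    df.attrs["test"] = "wilcoxon_paired" if paired else "mann_whitney_u"
    return df
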