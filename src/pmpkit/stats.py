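"""Frequency-data tests and two-sample comparisons.

Binary phenotype data (GSB failure, anterior-retraction defects, pupal
death) are tested per genotype against phenotype-specific expected
proportions with an exact binomial test and a Bonferroni-corrected
alpha; specific 2x2 contrasts use Fisher's exact test.  Quantitative
two-group comparisons use a one-tailed unpaired t test or the
Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PHENOTYPE_NULL_P",
    "BinomialResult",
    "binomial_phenotype_test",
    "fisher_exact_2x2",
    "two_sample_compare",
    "event_percent",
]

#: expected failure proportions under the null, per phenotype
PHENOTYPE_NULL_P = {
    "gsb_failure": 0.005,          # 1/376 control animals failed GSB
    "anterior_retraction": 0.01,
    "death": 0.05,
}


@dataclass
class BinomialResult:
    p_value: float
    corrected_alpha: float
    significant: bool
    p0: float


def binomial_phenotype_test(
    k: int,
    n: int,
    phenotype: str | None = None,
    p0: float | None = None,
    n_comparisons: int = 1,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> BinomialResult:
    """Exact binomial tail test of k events in n animals against p0.

    The default direction is one-sided toward an excess of events
    (P[X >= k]); the corrected alpha is ``alpha / n_comparisons``
    (Bonferroni).  ``phenotype`` looks p0 up in
    :data:`PHENOTYPE_NULL_P`; passing ``p0`` directly overrides it.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if p0 is None:
        if phenotype is None:
            raise ValueError("give either phenotype or p0")
        p0 = PHENOTYPE_NULL_P[phenotype]
    if alternative == "greater":
        p = float(sps.binom.sf(k - 1, n, p0))
    elif alternative == "less":
        p = float(sps.binom.cdf(k, n, p0))
    elif alternative == "two-sided":
        p = float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    corrected = alpha / n_comparisons
    return BinomialResult(
        p_value=min(p, 1.0), corrected_alpha=corrected,
        significant=p < corrected, p0=p0,
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def two_sample_compare(
    x,
    y,
    method: str = "mann_whitney",
    alternative: str = "greater",
) -> tuple[float, float]:
    """Unpaired two-sample comparison: (statistic, p value).

    ``t_one_tailed`` runs the unpaired Student's t with a one-sided
    alternative (default: x greater); ``mann_whitney`` runs the
    rank-sum test, exact for small untied samples and with the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if method == "t_one_tailed":
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            raise ValueError("zero pooled variance")
        res = sps.ttest_ind(x, y, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        mode = "exact" if (max(x.size, y.size) <= 25 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative=alternative, method=mode)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def event_percent(k: int, n: int, decimals: int = 1) -> float:
    """Event frequency as the percentage printed in reports (e.g. 4/21
    -> 19.0)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    return round(100.0 * k / n, decimals)
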