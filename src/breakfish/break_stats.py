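"""Break calling and the statistical procedures of the FISH/4C analysis.

Break calling is quantile-based: the distribution of intact inter-signal
distances in untreated control cells defines a threshold (its 99th
quantile by default) above which an allele is called "broken".  By
construction about 1% of control alleles exceed the threshold, so the
interesting quantity in a treated cohort is the *excess* of broken
calls over that floor.

Three inference procedures accompany the calls:

* an empirical-tail significance rule: with observed tail proportion
  P* out of n points, sigma = sqrt(P*(1-P*)) and x = k*sigma/sqrt(n)
  (k = 3 for a 0.997 confidence level); the tail has strictly positive
  probability mass when P* - x > 0;
* a Pearson chi-square test (2x2, no continuity correction) for the
  association between break status and outside-territory localization;
* the Mann-Whitney rank test used to compare 4C signal over gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TailTestResult",
    "BreakCallSet",
    "broken_threshold",
    "classify_broken",
    "tail_test",
    "territory_association",
    "mann_whitney",
]


@dataclass
class TailTestResult:
    """Outcome of the empirical-tail significance rule."""

    p_star: float
    n: int
    sigma: float
    x: float
    margin: float
    significant: bool
    k_sigma: float = 3.0


@dataclass
class BreakCallSet:
    """Per-allele broken/intact calls at a fixed distance threshold."""

    threshold_nm: float
    calls: np.ndarray
    broken_fraction: float


def broken_threshold(control_distances, q: float = 0.99) -> float:
    """Break-distance threshold: the q-quantile of control pair distances.

    Uses the linear-interpolation quantile estimator.  At least 10
    control values are required for the upper tail to be estimable at
    all.
    """
    d = np.asarray(control_distances, dtype=float)
    if d.size == 0:
        raise ValueError("control distance list is empty")
    if d.size < 10:
        raise ValueError("need at least 10 control distances")
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(d, q))


def classify_broken(distances, threshold: float) -> BreakCallSet:
    """Call an allele broken when its pair distance strictly exceeds threshold.

    Boundary equality is an intact call: the threshold is itself a value
    of the control distribution.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(distances, dtype=float)
    calls = d > threshold
    return BreakCallSet(
        threshold_nm=float(threshold),
        calls=calls,
        broken_fraction=float(calls.mean()) if calls.size else 0.0,
    )


def tail_test(p_star: float, n: int, k_sigma: float = 3.0) -> TailTestResult:
    """Empirical-tail significance: is the observed tail mass non-random?

    With plug-in sigma = sqrt(p*(1-p*)) the true tail probability P
    differs from the empirical P* by at most x = k*sigma/sqrt(n) at the
    k-sigma confidence level (0.997 for k = 3); P* - x > 0 therefore
    certifies a strictly positive tail measure.
    """
    if not 0.0 <= p_star <= 1.0:
        raise ValueError("p_star must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    sigma = math.sqrt(p_star * (1.0 - p_star))
    x = k_sigma * sigma / math.sqrt(n)
    margin = p_star - x
    return TailTestResult(
        p_star=p_star,
        n=int(n),
        sigma=sigma,
        x=x,
        margin=margin,
        significant=margin > 0,
        k_sigma=k_sigma,
    )


def territory_association(counts) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 broken/intact x outside/inside table.

    ``counts`` is [[a, b], [c, d]] with rows = groups (e.g. broken vs
    intact alleles) and columns = (outside, inside) territory.  Returns
    (chi2, p, fold) where fold is the ratio of outside proportions
    row1 / row2.  No continuity correction is applied (df = 1).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("chi-square undefined: zero row or column sum")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    prop1 = table[0, 0] / table[0].sum()
    prop2 = table[1, 0] / table[1].sum()
    fold = prop1 / prop2 if prop2 > 0 else math.inf
    return float(chi2), float(p), float(fold)


def mann_whitney(group_a, group_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test comparing two samples.

    Returns (U of group_a, p).  The exact null distribution is used for
    small tie-free samples (min group size <= 8); otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
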