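"""Exact binomial tests, Holm step-down adjustment, tie-corrected Spearman
rank correlation, and Akaike weights.

All p-values are kept at full precision here; rounding to a report's printed
precision happens only in the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, FlexbanditError

__all__ = [
    "BinomialResult",
    "SpearmanResult",
    "binom_two_tailed",
    "holm_adjust",
    "adjust_family",
    "spearman_tied",
    "akaike_weights",
]


@dataclass(frozen=True)
class BinomialResult:
    """An exact two-tailed binomial test, optionally Holm-adjusted in a family."""

    successes: int
    n: int
    p0: float
    p_raw: float
    p_adjusted: Optional[float] = None
    family_size: Optional[int] = None


@dataclass(frozen=True)
class SpearmanResult:
    """Tie-corrected Spearman correlation with the classical S statistic.

    ``S`` is reported through the identity S = (1 - rho)(n^3 - n)/6, which
    coincides with the sum of squared rank differences when there are no
    ties; ``p_approx`` uses the two-sided t-approximation with n - 2 degrees
    of freedom.
    """

    rho: float
    S: float
    n: int
    p_approx: float
    tie_corrected: bool = True


def binom_two_tailed(successes: int, n: int, p0: float = 0.5) -> BinomialResult:
    """Exact two-tailed binomial test by tail doubling.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) under Binomial(n, p0).  At
    p0 = 0.5 this coincides with the minimum-likelihood two-sided test, so
    the choice of two-sided convention is observationally irrelevant for
    symmetric nulls.
    """
    if not (0 <= successes <= n):
        raise FlexbanditError(f"successes must lie in [0, {n}], got {successes}")
    if not (0.0 < p0 < 1.0):
        raise FlexbanditError(f"p0 must lie in (0, 1), got {p0}")
    lower = sps.binom.cdf(successes, n, p0)
    upper = sps.binom.sf(successes - 1, n, p0)
    p = min(1.0, 2.0 * min(lower, upper))
    return BinomialResult(successes=successes, n=n, p0=p0, p_raw=float(p))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm (step-down Bonferroni) adjusted p-values, in input order.

    Ascending sort, multiplier m - i + 1, cumulative maximum enforced,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise FlexbanditError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=0.05, method="holm")
    return [float(v) for v in adjusted]


def adjust_family(results: Sequence[BinomialResult]) -> list[BinomialResult]:
    """Holm-adjust a family of binomial tests, returning annotated copies."""
    adjusted = holm_adjust([r.p_raw for r in results])
    m = len(results)
    return [
        replace(r, p_adjusted=a, family_size=m) for r, a in zip(results, adjusted)
    ]


def spearman_tied(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with mid-rank tie correction.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    S = (1 - rho)(n^3 - n)/6.  Constant ranks on either side leave rho
    undefined and raise :class:`DegenerateInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FlexbanditError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise FlexbanditError(f"need n >= 3, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("constant ranks: rho undefined")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if not np.isfinite(rho):
        raise DegenerateInputError("constant ranks: rho undefined")
    s_stat = (1.0 - rho) * (n**3 - n) / 6.0
    return SpearmanResult(rho=rho, S=float(s_stat), n=n, p_approx=float(res.pvalue))


def akaike_weights(information_criteria: Sequence[float]) -> list[float]:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    delta_i = IC_i - min(IC); the weights sum to 1 and are invariant to
    adding a constant to every input.
    """
    ic = np.asarray(information_criteria, dtype=float)
    if ic.size == 0:
        raise FlexbanditError("need at least one information-criterion value")
    if np.any(~np.isfinite(ic)):
        raise FlexbanditError("information criteria must be finite")
    delta = ic - ic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return [float(v) for v in w]
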