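"""Shared statistical kernels used across the pipeline.

Standard tests are delegated to the established implementations
(:func:`scipy.stats.mannwhitneyu`, :func:`scipy.stats.fisher_exact`,
statsmodels' Benjamini--Hochberg); highest-density intervals and the
cross-product odds ratio are implemented here with documented conventions:

* Mann--Whitney U uses exact enumeration when both samples have at most 8
  observations and no ties, otherwise the tie- and continuity-corrected
  normal approximation.
* The two-sided Fisher p-value follows the probability-mass rule: the sum of
  hypergeometric probabilities of all tables (fixed margins) no more probable
  than the observed one.
* The odds ratio is the unconditional cross-product ratio a*d/(b*c), with
  ``inf`` when b*c == 0 and a*d > 0 (``nan`` for 0/0).
* The HDI of a flat/plateau density is tie-broken to the central interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "CredibleInterval",
    "AdjustedPValues",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "set_overlap_test",
    "bh_adjust",
    "hdi_of_samples",
    "hdi_of_beta",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts.

    Row 1 = condition A present, row 2 = absent; column 1 = condition B
    present, column 2 = absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"table entry {name}={v!r} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class CredibleInterval:
    """Interval [lower, upper] holding ``mass`` posterior probability."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mass < 1.0:
            raise ValueError(f"mass must lie in (0, 1), got {self.mass}")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "fdr_bh"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann--Whitney U test.

    Returns ``(U, p)`` where U counts pairs (x_i, y_j) with x_i > y_j plus
    half the tied pairs. Exact when both samples have n <= 8 and no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # degenerate: every observation identical
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _cross_product_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def fisher_exact_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``; the odds ratio is the cross-product ratio.
    """
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return _cross_product_ratio(t.a, t.b, t.c, t.d), float(p)


def set_overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Fisher test of the overlap of two gene sets within a universe.

    Builds the 2x2 membership table over ``universe`` and delegates to
    :func:`fisher_exact_2x2`.
    """
    sa, sb, uni = set(set_a), set(set_b), set(universe)
    if not sa <= uni:
        raise ValueError(f"set A has {len(sa - uni)} element(s) outside the universe")
    if not sb <= uni:
        raise ValueError(f"set B has {len(sb - uni)} element(s) outside the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - len(sa | sb)
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))


def bh_adjust(pvals: Sequence[float]) -> AdjustedPValues:
    """Benjamini--Hochberg step-up adjustment (clipped at 1, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return AdjustedPValues(raw=tuple(p.tolist()), adjusted=tuple(adjusted.tolist()))


def hdi_of_samples(draws: Sequence[float], mass: float = 0.98) -> CredibleInterval:
    """Highest-density interval from posterior draws.

    The shortest window over the sorted draws that contains ``ceil(mass * n)``
    of them; width ties are broken toward the central window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    d = np.sort(np.asarray(draws, dtype=float).ravel())
    n = d.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for a sample-mode HDI, got {n}")
    m = int(math.ceil(mass * n))
    widths = d[m - 1 :] - d[: n - m + 1]
    best = widths.min()
    # ties -> pick the candidate window closest to the centre
    candidates = np.flatnonzero(widths <= best + 1e-12 * max(1.0, abs(best)))
    centre = (n - m) / 2.0
    i = int(candidates[np.argmin(np.abs(candidates - centre))])
    return CredibleInterval(float(d[i]), float(d[i + m - 1]), mass)


def hdi_of_beta(alpha: float, beta: float, mass: float = 0.98, grid: int = 10001) -> CredibleInterval:
    """Highest-density interval of a Beta(alpha, beta) distribution.

    Minimises ``ppf(q + mass) - ppf(q)`` over a dense grid of lower tail
    probabilities q in [0, 1 - mass]; for flat/plateau densities the tie-break
    returns the central (equal-tailed) interval.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    dist = stats.beta(alpha, beta)
    q = np.linspace(0.0, 1.0 - mass, grid)
    lo = dist.ppf(q)
    hi = dist.ppf(q + mass)
    widths = hi - lo
    best = widths.min()
    candidates = np.flatnonzero(widths <= best + 1e-12 * max(1.0, best))
    central = (1.0 - mass) / 2.0
    i = int(candidates[np.argmin(np.abs(q[candidates] - central))])
    return CredibleInterval(float(lo[i]), float(hi[i]), mass)
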