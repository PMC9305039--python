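"""Shared oracles and fixtures for the test suite.

The oracles here are deliberately brute-force and independent of the package
implementations they check: exhaustive rank-assignment enumeration for the
Mann--Whitney U test, hypergeometric table enumeration for Fisher's exact
test, the O(n^2) pairwise-difference Gini, and a density-level grid search
for Beta HDIs.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest


def mwu_null_distribution(nx: int, ny: int) -> dict[int, int]:
    """Exact null counts of the U statistic for tie-free samples."""
    counts: dict[int, int] = {}
    ranks = range(1, nx + ny + 1)
    base = nx * (nx + 1) // 2
    for subset in itertools.combinations(ranks, nx):
        u = sum(subset) - base
        counts[u] = counts.get(u, 0) + 1
    return counts


def mwu_exact_p(u: float, nx: int, ny: int) -> float:
    """Two-sided exact p from the enumerated null distribution."""
    dist = mwu_null_distribution(nx, ny)
    total = comb(nx + ny, nx)
    m = nx * ny
    u_lo, u_hi = min(u, m - u), max(u, m - u)
    p = (
        sum(c for v, c in dist.items() if v <= u_lo)
        + sum(c for v, c in dist.items() if v >= u_hi)
    ) / total
    return min(p, 1.0)


def ranks_with_u(u: int, nx: int, ny: int) -> tuple[list[int], list[int]]:
    """A concrete tie-free sample pair whose U statistic equals ``u``."""
    assert 0 <= u <= nx * ny
    x = list(range(1, nx + 1))
    extra = u
    for i in reversed(range(nx)):
        inc = min(extra, ny)
        x[i] += inc
        extra -= inc
    y = [r for r in range(1, nx + ny + 1) if r not in set(x)]
    return x, y


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the fixed margins.

    Probability-mass rule with the standard relative-epsilon guard for
    floating-point comparison of hypergeometric probabilities.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa: int) -> float:
        bb, cc, dd = r1 - aa, c1 - aa, r2 - (c1 - aa)
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(
        1.0,
        sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= p_obs * (1 + 1e-7)),
    )


def gini_pairwise(values) -> float:
    """O(n^2) population Gini: sum |x_i - x_j| / (2 n sum x)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2.0 * n * x.sum()))


def beta_hdi_grid(alpha: float, beta: float, mass: float, n_grid: int = 1_000_000):
    """Density-level HDI of a Beta distribution on a dense grid."""
    from scipy import stats

    x = np.linspace(0.0, 1.0, n_grid)
    pdf = stats.beta.pdf(x, alpha, beta)
    order = np.argsort(pdf)[::-1]
    cum = np.cumsum(pdf[order]) / pdf.sum()
    keep = order[: int(np.searchsorted(cum, mass)) + 1]
    return float(x[keep].min()), float(x[keep].max())


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
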