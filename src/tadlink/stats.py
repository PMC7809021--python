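"""Statistical kernel: proportion, hypergeometric, rank and permutation tests.

Every test here is small enough to verify against brute-force enumeration;
the test suite does exactly that. scipy supplies the distribution tails;
the test semantics (continuity correction, exact small-sample branches,
empirical p-value convention) are defined here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True, slots=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    statistic: float
    p: float


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    p_one_sided: float

    @property
    def fg_fraction(self) -> float:
        return self.k_fg / self.n_fg

    @property
    def bg_fraction(self) -> float:
        return self.k_bg / self.n_bg


def _check_counts(k: int, n: int, label: str) -> None:
    if n < 1:
        raise ValueError(f"{label}: n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"{label}: k={k} outside [0, n={n}]")


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> ProportionTestResult:
    """Two-sample test of equal proportions (chi-square, Yates correction).

    Follows R's ``prop.test`` default: the 2x2 chi-square statistic with the
    continuity correction clamped at |O - E|, so equal proportions give
    statistic 0 and p = 1. Set ``correction=False`` for the plain chi-square.
    """
    _check_counts(k1, n1, "group 1")
    _check_counts(k2, n2, "group 2")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected == 0):
        # one outcome absent in both groups: no evidence either way
        return ProportionTestResult(k1, n1, k2, n2, 0.0, 1.0)
    dev = np.abs(table - expected)
    if correction:
        # all four |O - E| are equal in a 2x2 table, so the clamp keeps dev >= 0
        yates = min(0.5, float(dev.min()))
        dev = dev - yates
    stat = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ProportionTestResult(k1, n1, k2, n2, stat, p)


def fisher_exact_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for the same 2x2 table (fallback variant)."""
    _check_counts(k1, n1, "group 1")
    _check_counts(k2, n2, "group 2")
    return float(sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1])


def hypergeom_enrichment(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> EnrichmentResult:
    """One-sided over-representation test of the foreground hit count.

    p = P(X >= k_fg) with X ~ Hypergeometric(population n_fg + n_bg,
    successes k_fg + k_bg, draws n_fg).
    """
    _check_counts(k_fg, n_fg, "foreground")
    _check_counts(k_bg, n_bg, "background")
    p = float(sps.hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
    return EnrichmentResult(k_fg, n_fg, k_bg, n_bg, min(p, 1.0))


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration of all group assignments when combined n <= 12 and
    there are no ties; otherwise the normal approximation with tie correction
    and a 0.5 continuity correction. Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _mw_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= 12 and not has_ties:
        # exact null: U is distribution-free; enumerate all C(n1+n2, n1) splits
        dev = abs(u - mu)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u_perm = _mw_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - 1e-9:
                count += 1
        return u, count / total
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sps.norm.sf(z)))


def empirical_p(observed: float, null: Iterable[float], tail: str = "lower") -> float:
    """Permutation p-value with the +1 correction: (1 + #beyond) / (N + 1)."""
    null = np.asarray(list(null), dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if tail == "lower":
        exceed = int((null <= observed).sum())
    elif tail == "upper":
        exceed = int((null >= observed).sum())
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1 + exceed) / (null.size + 1)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
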