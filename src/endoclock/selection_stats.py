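"""Nonparametric selection statistics for paired and grouped ω estimates.

The questions served here are directional contrasts of dN/dS (ω) between
loci or regions under purifying selection:

* paired contrasts (ω of a rescue locus vs its partner toxin locus across
  the same genome pairs): one-sided exact Wilcoxon signed-rank test,
  Hodges–Lehmann estimator of the median difference with the exact CI
  obtained by inverting the signed-rank test;
* unpaired contrasts: one-sided exact Mann–Whitney test with the
  two-sample Hodges–Lehmann estimator and rank-sum-inversion CI;
* Bayesian bootstrap (Dirichlet(1,…,1) weights via normalized Exp(1)
  draws) of the linearly interpolated weighted median, giving a posterior
  for the median effect and P(Δ < 0);
* domain-vs-background contrasts of per-site posterior ω: within-group
  site bootstrap for the CI and a site-label permutation test, one-sided
  in the observed direction.

Exact null distributions are computed by the standard generating-function
recursion (equivalent to enumerating all 2^n sign vectors / all rank
assignments, but polynomial time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PairedOmegaTable",
    "SitePosteriorOmega",
    "signed_rank_one_sided",
    "hodges_lehmann_paired",
    "hl_two_sample",
    "bayesian_bootstrap_median",
    "region_summary_and_tests",
    "signed_rank_cdf",
    "rank_sum_cdf",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedOmegaTable:
    """Paired ω contrasts; differences are omega_a − omega_b per contrast."""

    labels: tuple[str, ...]
    omega_a: tuple[float, ...]
    omega_b: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n == 0 or len(self.omega_a) != n or len(self.omega_b) != n:
            raise ValueError("labels/omega_a/omega_b must be non-empty, same length")
        if any(o < 0 for o in self.omega_a + self.omega_b):
            raise ValueError("omega values must be non-negative")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.omega_a) - np.asarray(self.omega_b)

    @classmethod
    def from_tsv(cls, path) -> "PairedOmegaTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=tuple(df["label"].astype(str)),
            omega_a=tuple(df["omega_a"].astype(float)),
            omega_b=tuple(df["omega_b"].astype(float)),
        )


@dataclass
class SitePosteriorOmega:
    """Ordered per-codon posterior mean ω with region labels and mask flags.

    Masked sites (e.g. sites whose positive-selection signal is an artifact
    of multi-nucleotide mutations) are excluded from every summary.
    """

    omega: np.ndarray
    region: np.ndarray  # str labels; background sites labelled "non_domain"
    masked: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        self.masked = np.asarray(self.masked, dtype=bool)
        if not (len(self.omega) == len(self.region) == len(self.masked)):
            raise ValueError("omega/region/masked must share one length")

    def group(self, label: str) -> np.ndarray:
        return self.omega[(self.region == label) & ~self.masked]

    @classmethod
    def from_tsv(cls, path) -> "SitePosteriorOmega":
        df = pd.read_csv(path, sep="\t").sort_values("site_index")
        return cls(
            omega=df["omega"].to_numpy(float),
            region=df["region"].to_numpy(object),
            masked=df["masked"].to_numpy(bool),
        )


# ---------------------------------------------------------------------------
# Exact null distributions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> np.ndarray:
    """counts[v] = number of the 2^n sign vectors with positive-rank sum v."""
    vmax = n * (n + 1) // 2
    counts = np.zeros(vmax + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank <= vmax else 0.0
        counts = counts + shifted
    return counts


def signed_rank_cdf(n: int, v: float) -> float:
    """Exact P(V <= v) for the signed-rank statistic with n non-zero pairs."""
    counts = _signed_rank_counts(n)
    k = int(np.floor(v + 1e-9))
    if k < 0:
        return 0.0
    k = min(k, len(counts) - 1)
    return float(counts[: k + 1].sum() / 2.0**n)


@lru_cache(maxsize=64)
def _rank_sum_counts(m: int, n: int) -> np.ndarray:
    """counts[u] = number of rank arrangements with Mann–Whitney U = u.

    Standard recursion f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u): the
    largest observation belongs to sample 1 (beating all n of sample 2) or
    to sample 2.
    """
    umax = m * n
    # table[j] = distribution for (i, j) while iterating i = 0..m
    table = [np.zeros(umax + 1) for _ in range(n + 1)]
    for j in range(n + 1):
        table[j][0] = 1.0  # f(0, j, 0) = 1
    for _i in range(1, m + 1):
        new = [np.zeros(umax + 1) for _ in range(n + 1)]
        new[0][0] = 1.0  # f(i, 0, 0) = 1
        for j in range(1, n + 1):
            shifted = np.zeros(umax + 1)
            shifted[j:] = table[j][: umax + 1 - j]
            new[j] = shifted + new[j - 1]
        table = new
    return table[n]


def rank_sum_cdf(m: int, n: int, u: float) -> float:
    """Exact P(U <= u) for the Mann–Whitney U with sample sizes (m, n)."""
    counts = _rank_sum_counts(m, n)
    k = int(np.floor(u + 1e-9))
    if k < 0:
        return 0.0
    k = min(k, len(counts) - 1)
    from math import comb

    return float(counts[: k + 1].sum() / comb(m + n, m))


# ---------------------------------------------------------------------------
# Signed-rank test and paired HL
# ---------------------------------------------------------------------------

def _drop_zeros(diffs: np.ndarray) -> np.ndarray:
    nz = diffs[diffs != 0.0]
    if len(nz) == 0:
        raise ValueError("degenerate: all differences are zero")
    if len(nz) < len(diffs):
        warnings.warn(
            f"dropped {len(diffs) - len(nz)} zero difference(s) "
            "(Wilcoxon convention)",
            stacklevel=3,
        )
    return nz


def signed_rank_one_sided(diffs: Sequence[float]) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test of location < 0.

    Returns (V, p) where V is the sum of the ranks of positive differences
    and p = P(V <= v_obs) under sign symmetry. Exact when n <= 25 and the
    absolute differences are tie-free; otherwise a mid-rank normal
    approximation with tie correction and continuity correction is used
    (with a warning).
    """
    d = _drop_zeros(np.asarray(diffs, dtype=float))
    n = len(d)
    absd = np.abs(d)
    # mid-ranks
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (pos + (pos + (j - i))) / 2.0
        pos += j - i + 1
        i = j + 1
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= EXACT_N_MAX and not has_ties:
        p = signed_rank_cdf(n, v)
    else:
        if has_ties:
            warnings.warn(
                "ties among |differences|; exact distribution unavailable, "
                "using mid-rank normal approximation",
                stacklevel=2,
            )
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, t_counts = np.unique(absd, return_counts=True)
        var -= float(((t_counts**3 - t_counts) / 48.0).sum())
        p = float(norm.cdf((v + 0.5 - mean) / np.sqrt(var)))
    return v, p


def _walsh_averages(diffs: np.ndarray) -> np.ndarray:
    n = len(diffs)
    idx_i, idx_j = np.triu_indices(n)
    return np.sort((diffs[idx_i] + diffs[idx_j]) / 2.0)


def hodges_lehmann_paired(
    diffs: Sequence[float], conf: float = 0.95
) -> tuple[float, float, float]:
    """Hodges–Lehmann paired estimate with signed-rank-inversion CI.

    The estimate is the median of all n(n+1)/2 Walsh averages; the CI
    endpoints are the Walsh-average order statistics at the exact two-sided
    critical values of the signed-rank test.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) == 0:
        raise ValueError("empty differences")
    walsh = _walsh_averages(d)
    est = float(np.median(walsh))
    n = len(d)
    m = len(walsh)
    alpha = 1.0 - conf
    # largest k with P(V <= k) <= alpha/2
    counts = _signed_rank_counts(n)
    cdf = np.cumsum(counts) / 2.0**n
    ks = np.nonzero(cdf <= alpha / 2.0)[0]
    k = int(ks[-1]) if len(ks) else -1
    lo_idx = k + 1
    hi_idx = m - k - 2
    if lo_idx > hi_idx:  # tiny n: widest attainable interval
        lo_idx, hi_idx = 0, m - 1
    return est, float(walsh[lo_idx]), float(walsh[hi_idx])


# ---------------------------------------------------------------------------
# Two-sample HL / Mann–Whitney
# ---------------------------------------------------------------------------

def hl_two_sample(
    xs: Sequence[float], ys: Sequence[float], conf: float = 0.95
) -> tuple[float, float, float, float]:
    """Two-sample Hodges–Lehmann shift with rank-sum-inversion CI.

    Returns (estimate, ci_lower, ci_upper, p_one_sided) where the estimate
    is the median of all pairwise differences x_i − y_j and the one-sided p
    tests shift(x) < shift(y), i.e. P(U <= u_obs) with U the count of pairs
    with x_i > y_j (ties counted half; exact distribution when tie-free).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    dmat = (x[:, None] - y[None, :]).ravel()
    dmat.sort()
    est = float(np.median(dmat))
    u = float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())
    has_ties = len(np.unique(np.concatenate([x, y]))) < m + n
    if not has_ties and m * n <= 40_000:
        p = rank_sum_cdf(m, n, u)
    else:
        if has_ties:
            warnings.warn(
                "ties across samples; using normal approximation",
                stacklevel=2,
            )
        mean = m * n / 2.0
        var = m * n * (m + n + 1) / 12.0
        pooled = np.concatenate([x, y])
        _, t_counts = np.unique(pooled, return_counts=True)
        var -= m * n * float(((t_counts**3 - t_counts)).sum()) / (
            12.0 * (m + n) * (m + n - 1)
        )
        p = float(norm.cdf((u + 0.5 - mean) / np.sqrt(var)))
    alpha = 1.0 - conf
    counts = _rank_sum_counts(m, n)
    from math import comb

    cdf = np.cumsum(counts) / comb(m + n, m)
    ks = np.nonzero(cdf <= alpha / 2.0)[0]
    k = int(ks[-1]) if len(ks) else -1
    lo_idx = k + 1
    hi_idx = m * n - k - 2
    if lo_idx > hi_idx:
        lo_idx, hi_idx = 0, m * n - 1
    return est, float(dmat[lo_idx]), float(dmat[hi_idx]), p


# ---------------------------------------------------------------------------
# Bayesian bootstrap of the weighted median
# ---------------------------------------------------------------------------

def _weighted_median(sorted_vals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linearly interpolated 0.5-quantile of the weighted empirical CDF.

    ``weights`` has shape (B, n) aligned with ``sorted_vals`` (ascending);
    CDF positions are the mid-cumulative weights c_i − w_i/2, clipped at the
    extremes, so a single observation returns itself and equal weights
    reduce to the ordinary interpolated median.
    """
    if len(sorted_vals) == 1:
        return np.full(weights.shape[0], sorted_vals[0])
    cum = np.cumsum(weights, axis=1)
    mid = cum - 0.5 * weights
    out = np.empty(weights.shape[0])
    for b in range(weights.shape[0]):
        out[b] = np.interp(0.5, mid[b], sorted_vals)
    return out


def bayesian_bootstrap_median(
    diffs: Sequence[float], B: int = 20_000, seed: int = 0
) -> tuple[float, float, float, float]:
    """Bayesian bootstrap posterior for the median of ``diffs``.

    Per replicate, observation weights are independent Exp(1) draws
    normalized to sum to 1 (a flat Dirichlet), and the statistic is the
    linearly interpolated weighted median. Returns (posterior_mean,
    ci_lower, ci_upper, p_neg) with an equal-tailed 95% credible interval
    and p_neg = fraction of replicates with a negative weighted median.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) == 0:
        raise ValueError("empty differences")
    if B < 1:
        raise ValueError("B must be at least 1")
    order = np.argsort(d)
    sorted_d = d[order]
    rng = np.random.default_rng(seed)
    w = rng.exponential(1.0, size=(B, len(d)))
    w /= w.sum(axis=1, keepdims=True)
    medians = _weighted_median(sorted_d, w[:, order])
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return (
        float(medians.mean()),
        float(lo),
        float(hi),
        float((medians < 0.0).mean()),
    )


# ---------------------------------------------------------------------------
# Domain vs background site tests
# ---------------------------------------------------------------------------

def region_summary_and_tests(
    sites: SitePosteriorOmega,
    region: str,
    B_boot: int = 10_000,
    B_perm: int = 10_000,
    seed: int = 0,
    background: str = "non_domain",
    alternative: str = "less",
) -> dict[str, float]:
    """Mean-ω contrast of one region against the pooled background.

    delta = mean ω over region sites − mean ω over background sites.
    The CI is a percentile bootstrap resampling sites with replacement
    within each group; the p-value is a site-label permutation test with
    the add-one convention p = (r + 1) / (B + 1). ``alternative`` fixes
    the tested direction a priori ("less": delta < 0, the usual
    domain-under-stronger-constraint hypothesis; "greater"; or "observed"
    to take the direction from delta's sign — anti-conservative under the
    null, kept for exploratory scans).
    """
    dom = sites.group(region)
    bg = sites.group(background)
    if len(dom) < 2 or len(bg) < 2:
        raise ValueError(
            f"need >= 2 unmasked sites per group, got {len(dom)} in "
            f"{region!r} and {len(bg)} in {background!r}"
        )
    delta = float(dom.mean() - bg.mean())
    rng = np.random.default_rng(seed)
    # within-group bootstrap
    bi = rng.integers(0, len(dom), size=(B_boot, len(dom)))
    bj = rng.integers(0, len(bg), size=(B_boot, len(bg)))
    boot = dom[bi].mean(axis=1) - bg[bj].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    # label permutation
    pooled = np.concatenate([dom, bg])
    n_dom = len(dom)
    perm = np.empty(B_perm)
    for b in range(B_perm):
        rng.shuffle(pooled)
        perm[b] = pooled[:n_dom].mean() - pooled[n_dom:].mean()
    if alternative == "observed":
        direction = "less" if delta < 0 else "greater"
    elif alternative in {"less", "greater"}:
        direction = alternative
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if direction == "less":
        r = int((perm <= delta).sum())
    else:
        r = int((perm >= delta).sum())
    p_perm = (r + 1) / (B_perm + 1)
    return {
        "mean_region": float(dom.mean()),
        "mean_background": float(bg.mean()),
        "delta": delta,
        "boot_lower": float(lo),
        "boot_upper": float(hi),
        "p_perm": float(p_perm),
        "n_region": float(len(dom)),
        "n_background": float(len(bg)),
    }
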