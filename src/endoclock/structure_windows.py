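"""Spherical sliding-window Ka/Ks over a 3D structure and block resampling.

Selection often acts on spatial neighborhoods of a folded protein rather
than on linear sequence windows. For each residue of a reference
structure, all residues within a fixed Euclidean radius (default 10 Å,
inclusive, self included) are pooled and a counting Ka/Ks is computed on
the pooled codons. Windows are filtered to a reliable regime
(0.1 <= Ks <= 2.0, residue confidence pLDDT >= 70; a Ks = 99 sentinel
marks windows with no synonymous variation).

Because neighboring windows share residues, the per-residue log(ω + 1e−6)
series is autocorrelated; inference on median contrasts between two such
series therefore uses block methods: block length from the integrated
autocorrelation time (L = clamp(round(2·IAT), 6, 30)), a non-circular
non-overlapping moving-block bootstrap with BCa intervals, and a
block-label permutation test with p = (r + 1)/(B + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .seqdiv import CodonAlignment, SaturationError, ng86_kaks

__all__ = [
    "ResidueCloud",
    "WindowSeries",
    "BlockPlan",
    "KS_SENTINEL",
    "LOG_OFFSET",
    "spherical_window_kaks",
    "filter_windows",
    "delta_log_omega",
    "delta_log_omega_pairs",
    "integrated_autocorrelation_time",
    "block_plan",
    "moving_block_bootstrap_bca",
    "block_permutation_p",
]

KS_SENTINEL = 99.0
LOG_OFFSET = 1e-6
BLOCK_MIN, BLOCK_MAX = 6, 30


@dataclass(frozen=True)
class ResidueCloud:
    """Ordered residue coordinates (Å) with per-residue confidence (pLDDT)."""

    index: np.ndarray
    xyz: np.ndarray  # shape (n, 3)
    plddt: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", np.asarray(self.index, dtype=int))
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        object.__setattr__(self, "plddt", np.asarray(self.plddt, dtype=float))
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not (len(self.index) == len(self.xyz) == len(self.plddt)):
            raise ValueError("index/xyz/plddt must share one length")
        if np.any(np.diff(self.index) <= 0):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.index)

    @classmethod
    def from_tsv(cls, path) -> "ResidueCloud":
        df = pd.read_csv(path, sep="\t")
        return cls(
            index=df["index"].to_numpy(int),
            xyz=df[["x", "y", "z"]].to_numpy(float),
            plddt=df["plddt"].to_numpy(float),
        )


@dataclass
class WindowSeries:
    """Per-residue window statistics ordered by residue index."""

    residue: np.ndarray
    Ka: np.ndarray
    Ks: np.ndarray
    plddt: np.ndarray
    retained: np.ndarray  # bool filter flags

    def __post_init__(self) -> None:
        self.residue = np.asarray(self.residue, dtype=int)
        self.Ka = np.asarray(self.Ka, dtype=float)
        self.Ks = np.asarray(self.Ks, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def omega(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.Ks > 0, self.Ka / self.Ks, np.nan)

    def log_omega(self) -> np.ndarray:
        """Ordered log(ω + 1e−6) over retained windows."""
        om = self.omega[self.retained]
        return np.log(om + LOG_OFFSET)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue,
                "Ka": self.Ka,
                "Ks": self.Ks,
                "omega": self.omega,
                "plddt": self.plddt,
                "retained": self.retained,
            }
        )


@dataclass(frozen=True)
class BlockPlan:
    """Block length derived from integrated autocorrelation times."""

    tau: float
    L: int

    def __post_init__(self) -> None:
        if not BLOCK_MIN <= self.L <= BLOCK_MAX:
            raise ValueError(f"block length {self.L} outside [{BLOCK_MIN}, {BLOCK_MAX}]")


def spherical_window_kaks(
    cloud: ResidueCloud,
    aln: CodonAlignment,
    a: str,
    b: str,
    radius: float = 10.0,
) -> WindowSeries:
    """Counting Ka/Ks in a spherical window around every residue.

    Residue i's window pools the codons of all residues within ``radius`` Å
    (inclusive; the residue itself is always included) and computes NG86
    Ka/Ks on the pooled codon subset of taxa ``a`` and ``b``. A window with
    zero synonymous differences and zero synonymous sites — no synonymous
    signal at all — or with a saturated subset receives the Ks = 99
    sentinel. Windows with pS = 0 but positive synonymous sites get Ks = 0
    (ω undefined there; such windows fall to the Ks filter downstream).
    """
    if len(cloud) != aln.n_codons:
        raise ValueError(
            f"residue count {len(cloud)} != codon count {aln.n_codons}"
        )
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(cloud.xyz)
    neighbors = tree.query_ball_point(cloud.xyz, r=radius)
    codons_a = aln.codons(a)
    codons_b = aln.codons(b)
    ka = np.empty(len(cloud))
    ks = np.empty(len(cloud))
    for i, idxs in enumerate(neighbors):
        idxs = sorted(idxs)
        sub_a = "".join(codons_a[j] for j in idxs)
        sub_b = "".join(codons_b[j] for j in idxs)
        sub = CodonAlignment(
            taxa=(a, b), sequences={a: sub_a, b: sub_b}, frame_offset=0
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = ng86_kaks(sub, a, b)
        except SaturationError:
            ka[i] = np.nan
            ks[i] = KS_SENTINEL
            continue
        if est.Ks == 0.0 and est.n_syn_sites == 0.0:
            ka[i] = est.Ka
            ks[i] = KS_SENTINEL
        else:
            ka[i] = est.Ka
            ks[i] = est.Ks
    return WindowSeries(
        residue=cloud.index,
        Ka=ka,
        Ks=ks,
        plddt=cloud.plddt,
        retained=np.ones(len(cloud), dtype=bool),
    )


def filter_windows(
    series: WindowSeries,
    ks_min: float = 0.1,
    ks_max: float = 2.0,
    plddt_min: float = 70.0,
) -> WindowSeries:
    """Flag windows outside the reliable regime; order preserved, idempotent."""
    keep = (
        series.retained
        & (series.Ks != KS_SENTINEL)
        & (series.Ks >= ks_min)
        & (series.Ks <= ks_max)
        & (series.plddt >= plddt_min)
        & np.isfinite(series.Ka)
    )
    return WindowSeries(
        residue=series.residue,
        Ka=series.Ka,
        Ks=series.Ks,
        plddt=series.plddt,
        retained=keep,
    )


def delta_log_omega(log_a: np.ndarray, log_b: np.ndarray) -> float:
    """Δ = median(log(ω+1e−6)) of series a − the same median of series b."""
    log_a = np.asarray(log_a, dtype=float)
    log_b = np.asarray(log_b, dtype=float)
    if len(log_a) == 0 or len(log_b) == 0:
        raise ValueError("both series must be non-empty after filtering")
    return float(np.median(log_a) - np.median(log_b))


def delta_log_omega_pairs(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """(Δp, exp(Δp)): mean per-pair Δ and the geometric-mean ω ratio."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    deltas = [delta_log_omega(a, b) for a, b in pairs]
    dp = float(np.mean(deltas))
    return dp, math.exp(dp)


def integrated_autocorrelation_time(series: Sequence[float]) -> float:
    """IAT = 1 + 2·Σ ρ̂(k), initial-positive truncation, floored at 0.5.

    The sum runs over lags k >= 1 and stops at the first non-positive
    sample autocorrelation (that terminating term is included, so strongly
    anti-correlated series yield IAT below 1). A constant series has no
    defined autocorrelation and returns 1 with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short for IAT estimation (need >= 10)")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        warnings.warn("constant series; IAT defined as 1", stacklevel=2)
        return 1.0
    tau = 1.0
    for k in range(1, len(x)):
        rho = float(np.dot(x[:-k], x[k:]) / denom)
        tau += 2.0 * rho
        if rho <= 0.0:
            break
    return max(tau, 0.5)


def block_plan(tau_a: float, tau_b: float) -> BlockPlan:
    """L = max over the two series of clamp(round(2·tau), 6, 30)."""
    if tau_a < 0 or tau_b < 0:
        raise ValueError("taus must be non-negative")
    la = min(max(round(2.0 * tau_a), BLOCK_MIN), BLOCK_MAX)
    lb = min(max(round(2.0 * tau_b), BLOCK_MIN), BLOCK_MAX)
    return BlockPlan(tau=max(tau_a, tau_b), L=int(max(la, lb)))


def _blocks(x: np.ndarray, L: int) -> list[np.ndarray]:
    """Non-overlapping blocks of length L; the last partial block is kept."""
    return [x[i : i + L] for i in range(0, len(x), L)]


def _resample_series(x: np.ndarray, L: int, rng: np.random.Generator) -> np.ndarray:
    blocks = _blocks(x, L)
    out: list[np.ndarray] = []
    total = 0
    while total < len(x):
        blk = blocks[rng.integers(0, len(blocks))]
        out.append(blk)
        total += len(blk)
    return np.concatenate(out)[: len(x)]


def moving_block_bootstrap_bca(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    L: int,
    B: int = 5_000,
    seed: int = 0,
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """BCa interval for Δp from a non-circular non-overlapping block bootstrap.

    Per replicate and per series, blocks of length ``L`` are resampled with
    replacement until the rebuilt series reaches the original length (excess
    truncated); Δ is recomputed per pair and averaged. The bias correction
    z0 uses the fraction of replicates strictly below the observed Δp (ties
    counted half); acceleration comes from a leave-one-pair-out jackknife of
    Δp. With a single pair acceleration is undefined and a percentile
    interval is returned with a warning.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    if B < 1000:
        raise ValueError("B must be at least 1000")
    dp_obs, _ = delta_log_omega_pairs(pairs)
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        deltas = []
        for xa, xb in pairs:
            ra = _resample_series(np.asarray(xa, float), L, rng)
            rb = _resample_series(np.asarray(xb, float), L, rng)
            deltas.append(float(np.median(ra) - np.median(rb)))
        boot[b] = np.mean(deltas)
    alpha = 1.0 - conf
    if len(pairs) < 2:
        warnings.warn(
            "single pair: acceleration undefined, returning percentile interval",
            stacklevel=2,
        )
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return dp_obs, float(lo), float(hi)
    frac_below = ((boot < dp_obs).sum() + 0.5 * (boot == dp_obs).sum()) / B
    frac_below = min(max(frac_below, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(frac_below))
    # leave-one-pair-out jackknife of Δp
    deltas_obs = np.array([delta_log_omega(a, b) for a, b in pairs])
    n = len(pairs)
    jack = np.array(
        [np.delete(deltas_obs, i).mean() for i in range(n)]
    )
    jmean = jack.mean()
    num = float(((jmean - jack) ** 3).sum())
    den = float(((jmean - jack) ** 2).sum()) ** 1.5
    a_hat = num / (6.0 * den) if den > 0 else 0.0
    z_lo = norm.ppf(alpha / 2)
    z_hi = norm.ppf(1 - alpha / 2)
    def _adj(z: float) -> float:
        return float(norm.cdf(z0 + (z0 + z) / (1 - a_hat * (z0 + z))))
    q_lo = 100 * _adj(z_lo)
    q_hi = 100 * _adj(z_hi)
    lo, hi = np.percentile(boot, [q_lo, q_hi])
    return dp_obs, float(lo), float(hi)


def block_permutation_p(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    L: int,
    B: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided block-label permutation p-value for Δp < 0.

    Within each pair, both series are cut into non-overlapping blocks of
    length ``L`` and pooled; one random permutation of the pooled blocks is
    dealt to the first label until its original length is reached (excess
    truncated) and the remainder to the second label (wrapping around the
    permutation only to cover the at-most-L−1 shortfall truncation can
    leave). Each block therefore carries its label exchangeably, matching
    the variance of the observed statistic under the null.
    p = (r + 1)/(B + 1) with r the number of permuted Δp values <= the
    observed Δp.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    dp_obs, _ = delta_log_omega_pairs(pairs)
    rng = np.random.default_rng(seed)
    pair_blocks = []
    for xa, xb in pairs:
        blocks = _blocks(np.asarray(xa, float), L) + _blocks(np.asarray(xb, float), L)
        pair_blocks.append((blocks, len(xa), len(xb)))

    r = 0
    for _ in range(B):
        deltas = []
        for blocks, na, nb in pair_blocks:
            order = list(rng.permutation(len(blocks)))
            out_a: list[np.ndarray] = []
            total = 0
            k = 0
            while total < na:
                out_a.append(blocks[order[k]])
                total += len(out_a[-1])
                k += 1
            out_b = [blocks[i] for i in order[k:]]
            total_b = sum(len(b) for b in out_b)
            j = 0
            while total_b < nb:  # cover truncation shortfall
                out_b.append(blocks[order[j % k]])
                total_b += len(out_b[-1])
                j += 1
            sa = np.concatenate(out_a)[:na]
            sb = np.concatenate(out_b)[:nb]
            deltas.append(float(np.median(sa) - np.median(sb)))
        if np.mean(deltas) <= dp_obs:
            r += 1
    return (r + 1) / (B + 1)
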