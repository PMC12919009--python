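"""Substitution-rate calibration from host–symbiont codivergence.

When an endosymbiont codiverges with its host, a fossil-calibrated host
MRCA age T converts sequence divergence d (substitutions/site, tip-to-tip)
into a substitution rate r = d / (2T): the divergence between two extant
lineages spans two branches of length T. Host-age uncertainty propagates
directly: the slow bound of the rate comes from the old bound of T and
vice versa.

Rate uncertainty is summarised two ways:

* a lognormal multiplier X = exp(Normal(0, sigma)) on the point rate,
  with sigma chosen so that P[X < 1/fold] = P[X > fold] = tail_prob
  (defaults fold = 2, tail_prob = 0.025 — the empirical support ranges of
  the calibrations run roughly from half to double the point estimate);
* a "conservative plausible range" (CPR): the point estimate averages the
  fastest and slowest calibration, while the interval runs from the
  statistical lower bound of the fastest calibration to the upper bound of
  the slowest, deliberately bracketing both statistical and
  between-calibration uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "HostCalibration",
    "RateEstimate",
    "LognormalRatePrior",
    "PlausibleEstimate",
    "rate_from_divergence",
    "average_divergence_to_outgroup",
    "lognormal_rate_prior",
    "plausible_estimate",
    "divergence_time_from_rate",
    "read_calibration_table",
    "rates_table",
]


@dataclass(frozen=True)
class HostCalibration:
    """A host MRCA age in years with its HPD/support interval."""

    label: str
    t_mrca: float
    t_lower: float
    t_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.t_lower <= self.t_mrca <= self.t_upper):
            raise ValueError(
                f"{self.label}: need 0 < t_lower <= t_mrca <= t_upper, got "
                f"({self.t_lower}, {self.t_mrca}, {self.t_upper})"
            )


@dataclass(frozen=True)
class RateEstimate:
    """Substitutions/site/year with a support interval."""

    rate: float
    rate_lower: float
    rate_upper: float
    site_class: str = "third_position"
    source_label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.rate_lower <= self.rate <= self.rate_upper):
            raise ValueError(
                f"need 0 < rate_lower <= rate <= rate_upper, got "
                f"({self.rate_lower}, {self.rate}, {self.rate_upper})"
            )


@dataclass(frozen=True)
class PlausibleEstimate:
    """A plausible point (years) with its conservative plausible range."""

    point: float
    cpr_lower: float
    cpr_upper: float

    def __post_init__(self) -> None:
        if not self.cpr_lower <= self.point <= self.cpr_upper:
            raise ValueError(
                f"CPR ({self.cpr_lower}, {self.cpr_upper}) must contain the "
                f"point {self.point}"
            )


class LognormalRatePrior:
    """Multiplicative lognormal uncertainty X = exp(Normal(0, sigma)).

    median(X) = 1 by construction; mean(X) = exp(sigma^2 / 2). A seeded
    sampler draws rate * X.
    """

    def __init__(self, point_rate: float, sigma: float) -> None:
        if point_rate <= 0:
            raise ValueError("point_rate must be positive")
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        self.point_rate = float(point_rate)
        self.sigma = float(sigma)
        self.mu = 0.0

    @property
    def mean_multiplier(self) -> float:
        return math.exp(self.sigma**2 / 2.0)

    @property
    def median_multiplier(self) -> float:
        return 1.0

    def multiplier_quantile(self, q: float) -> float:
        return float(np.exp(norm.ppf(q, scale=self.sigma))) if self.sigma else 1.0

    def tail_prob(self, fold: float) -> float:
        """P[X > fold] (equals P[X < 1/fold] by log-symmetry)."""
        if self.sigma == 0:
            return 0.0 if fold > 1 else 1.0
        return float(norm.sf(math.log(fold), scale=self.sigma))

    def sample_rates(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        return self.point_rate * np.exp(rng.normal(0.0, self.sigma, size=n))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LognormalRatePrior(point_rate={self.point_rate:.3g}, "
            f"sigma={self.sigma:.6f})"
        )


def rate_from_divergence(
    d: float, cal: HostCalibration, site_class: str = "third_position"
) -> RateEstimate:
    """Substitution rate r = d / (2 * t_mrca) with interval from the host HPD.

    The interval bounds invert: the host age upper bound gives the slow rate
    bound, the age lower bound gives the fast bound.
    """
    if d <= 0:
        raise ValueError(f"divergence d must be positive, got {d}")
    return RateEstimate(
        rate=d / (2.0 * cal.t_mrca),
        rate_lower=d / (2.0 * cal.t_upper),
        rate_upper=d / (2.0 * cal.t_lower),
        site_class=site_class,
        source_label=cal.label,
    )


def average_divergence_to_outgroup(divs: Sequence[float]) -> float:
    """Arithmetic mean of the sister-to-outgroup divergence estimates."""
    if len(divs) == 0:
        raise ValueError("empty divergence list")
    return float(np.mean(divs))


def lognormal_rate_prior(
    point_rate: float, tail_prob: float = 0.025, fold: float = 2.0
) -> LognormalRatePrior:
    """Build the lognormal multiplier prior from its defining tail condition.

    sigma = ln(fold) / z where z is the standard-normal upper-``tail_prob``
    quantile, so that P[X < 1/fold] = P[X > fold] = tail_prob exactly.
    """
    if not 0 < tail_prob < 0.5:
        raise ValueError(f"tail_prob must be in (0, 0.5), got {tail_prob}")
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    z = float(norm.isf(tail_prob))
    sigma = math.log(fold) / z
    return LognormalRatePrior(point_rate=point_rate, sigma=sigma)


def plausible_estimate(
    fast_point: float,
    slow_point: float,
    fast_lower: float,
    slow_upper: float,
) -> PlausibleEstimate:
    """Average the fastest and slowest calibrations; CPR from their outer bounds.

    ``fast_point`` is the (younger) time estimate from the fastest rate;
    ``slow_point`` from the slowest. The CPR runs from the fast calibration's
    lower bound to the slow calibration's upper bound.
    """
    if fast_lower > fast_point:
        raise ValueError("fast_lower must not exceed fast_point")
    if slow_point > slow_upper:
        raise ValueError("slow_point must not exceed slow_upper")
    point = 0.5 * (fast_point + slow_point)
    return PlausibleEstimate(point=point, cpr_lower=fast_lower, cpr_upper=slow_upper)


def divergence_time_from_rate(d: float, rate: RateEstimate) -> PlausibleEstimate:
    """Time back to the MRCA implied by a rate: T = d / (2r).

    The interval inverts the rate interval (fast rate bound -> young time
    bound).
    """
    if d < 0:
        raise ValueError(f"divergence d must be non-negative, got {d}")
    if rate.rate <= 0:
        raise ValueError("rate must be positive")
    return PlausibleEstimate(
        point=d / (2.0 * rate.rate),
        cpr_lower=d / (2.0 * rate.rate_upper) if d > 0 else 0.0,
        cpr_upper=d / (2.0 * rate.rate_lower) if d > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

CALIBRATION_COLUMNS = [
    "label",
    "divergence",
    "t_mrca",
    "t_lower",
    "t_upper",
    "site_class",
]


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (label, divergence, t_mrca, t_lower, t_upper, site_class)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"calibration table {path} is empty")
    return df


def rates_table(calibrations: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`rate_from_divergence` row-wise to a calibration table."""
    rows = []
    for row in calibrations.itertuples(index=False):
        cal = HostCalibration(
            label=row.label,
            t_mrca=float(row.t_mrca),
            t_lower=float(row.t_lower),
            t_upper=float(row.t_upper),
        )
        est = rate_from_divergence(
            float(row.divergence), cal, site_class=str(row.site_class)
        )
        rows.append(
            {
                "label": est.source_label,
                "site_class": est.site_class,
                "rate": est.rate,
                "rate_lower": est.rate_lower,
                "rate_upper": est.rate_upper,
            }
        )
    return pd.DataFrame(rows)
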