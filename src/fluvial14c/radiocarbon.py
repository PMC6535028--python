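"""Radiocarbon unit conversions and flux-weighted descriptive statistics.

Δ¹⁴C values (per mil, ‰) are converted to fraction modern and conventional
radiocarbon ages using the standard Stuiver–Polach convention: the sample
activity is decay-corrected from the collection year back to the 1950
reference with the true decay constant (1/8267 y⁻¹), and ages are computed
with the Libby mean life (8033 y).

Flux weighting gives each isotope observation a weight proportional to the
instantaneous DOC or POC flux at the time of sampling, so that high-export
periods (e.g. the spring freshet) dominate means, dispersions, quantiles
and significance tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "RadiocarbonConstants",
    "CONSTANTS",
    "WeightedSeries",
    "delta14c_to_fraction_modern",
    "fraction_modern_to_age",
    "delta14c_to_conventional_age",
    "weighted_mean_sd",
    "weighted_t_test",
    "weighted_percentiles",
    "effective_sample_size",
    "TTestResult",
]

#: Default collection year for summary-level conversions (midpoint of the
#: 2003–2013 observational record).
DEFAULT_COLLECTION_YEAR = 2010


@dataclass(frozen=True)
class RadiocarbonConstants:
    """Physical constants of the conventional radiocarbon scale."""

    true_decay_constant: float = 1.0 / 8267.0  # y⁻¹, from the 5730 y half-life
    libby_mean_life: float = 8033.0  # y, conventional (Libby) mean life
    reference_year: int = 1950

    def __post_init__(self) -> None:
        if self.true_decay_constant <= 0 or self.libby_mean_life <= 0:
            raise ValueError("radiocarbon constants must be strictly positive")
        if self.reference_year != 1950:
            raise ValueError("the conventional reference year is fixed at 1950")


CONSTANTS = RadiocarbonConstants()


def delta14c_to_fraction_modern(
    delta14c: float,
    collection_year: float = DEFAULT_COLLECTION_YEAR,
    constants: RadiocarbonConstants = CONSTANTS,
) -> float:
    """Convert a Δ¹⁴C value (‰) to fraction modern F.

    F = (Δ/1000 + 1) · exp(λ·(collection_year − 1950)) with λ = 1/8267 y⁻¹,
    i.e. the measured activity is corrected for decay between collection and
    the 1950 reference year.
    """
    if delta14c <= -1000.0:
        raise ValueError(
            f"delta14c={delta14c}‰ implies no remaining ¹⁴C (must be > -1000‰)"
        )
    if collection_year < constants.reference_year:
        raise ValueError("collection_year must be >= 1950")
    decay = math.exp(
        constants.true_decay_constant * (collection_year - constants.reference_year)
    )
    return (delta14c / 1000.0 + 1.0) * decay


def fraction_modern_to_age(
    fraction_modern: float, constants: RadiocarbonConstants = CONSTANTS
) -> float:
    """Conventional radiocarbon age (y BP) from fraction modern.

    age = −8033 · ln(F). Negative for post-bomb samples (F > 1).
    """
    if fraction_modern <= 0.0:
        raise ValueError("fraction modern must be > 0")
    return -constants.libby_mean_life * math.log(fraction_modern)


def delta14c_to_conventional_age(
    delta14c: float,
    collection_year: float = DEFAULT_COLLECTION_YEAR,
    rounding: int | None = 100,
    constants: RadiocarbonConstants = CONSTANTS,
) -> float:
    """Conventional ¹⁴C age (y BP) of a Δ¹⁴C value, optionally rounded.

    Parameters
    ----------
    delta14c : Δ¹⁴C in ‰, must exceed −1000.
    collection_year : calendar year of sampling (decay correction to 1950).
    rounding : round the age to the nearest multiple of this many years
        (reported values use 100); ``None`` or 1 disables rounding.
    """
    age = fraction_modern_to_age(
        delta14c_to_fraction_modern(delta14c, collection_year, constants), constants
    )
    if rounding in (None, 1):
        return age
    if rounding <= 0:
        raise ValueError("rounding must be a positive number of years")
    return rounding * round(age / rounding)


# ---------------------------------------------------------------------------
# Flux-weighted statistics
# ---------------------------------------------------------------------------


@dataclass
class WeightedSeries:
    """A series of scalar values with nonnegative (flux) weights."""

    values: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.ndim != 1 or self.values.shape != self.weights.shape:
            raise ValueError("values and weights must be 1-D and the same length")
        if self.values.size == 0:
            raise ValueError("series must not be empty")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.weights)):
            raise ValueError("values and weights must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)


def _as_series(x: "WeightedSeries | Sequence[float]") -> WeightedSeries:
    return x if isinstance(x, WeightedSeries) else WeightedSeries(np.asarray(x, float))


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size n_eff = (Σw)² / Σw²."""
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w) ** 2 / np.sum(w**2))


def weighted_mean_sd(series: WeightedSeries) -> tuple[float, float]:
    """Flux-weighted mean and standard deviation.

    The variance uses the frequency-weight (Σw-normalised) convention with a
    reliability correction through the effective sample size:
    s² = n_eff/(n_eff − 1) · Σw(x − x̄)²/Σw. With equal weights this equals
    the ordinary unbiased sample SD.
    """
    series = _as_series(series)
    w, x = series.weights, series.values
    mean = float(np.sum(w * x) / np.sum(w))
    neff = effective_sample_size(w)
    biased_var = float(np.sum(w * (x - mean) ** 2) / np.sum(w))
    if neff > 1.0:
        var = biased_var * neff / (neff - 1.0)
    else:
        var = 0.0
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def weighted_t_test(a: WeightedSeries, b: WeightedSeries) -> TTestResult:
    """Two-sample t test of flux-weighted means (Welch-type).

    Weighted means and reliability-corrected weighted variances are combined
    with effective sample sizes; degrees of freedom follow Welch–
    Satterthwaite on those effective sizes. With unit weights this reduces
    to the ordinary Welch t test.

    A zero pooled standard error with equal means is undefined and raises;
    with differing means it returns t = ±inf, p = 0.
    """
    a, b = _as_series(a), _as_series(b)
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least two observations")
    ma, sa = weighted_mean_sd(a)
    mb, sb = weighted_mean_sd(b)
    na, nb = effective_sample_size(a.weights), effective_sample_size(b.weights)
    va, vb = sa**2 / na, sb**2 / nb
    se2 = va + vb
    diff = ma - mb
    if se2 == 0.0:
        if diff == 0.0:
            raise ValueError("zero variance in both groups with equal means")
        return TTestResult(math.copysign(math.inf, diff), math.inf, 0.0)
    t = diff / math.sqrt(se2)
    if va == 0.0 or vb == 0.0:
        # one degenerate group: df driven by the other
        df = (na - 1.0) if vb > 0 and va == 0 else (nb - 1.0)
        df = max(df, 1.0)
    else:
        df = se2**2 / (va**2 / (na - 1.0) + vb**2 / (nb - 1.0))
    p = 2.0 * float(_sstats.t.sf(abs(t), df))
    return TTestResult(t, df, min(p, 1.0))


def weighted_percentiles(
    series: WeightedSeries, probs: Sequence[float]
) -> np.ndarray:
    """Weighted quantiles by inversion of the weighted empirical CDF.

    Returns, for each probability p, the smallest value whose cumulative
    weight fraction reaches p. With equal weights this is the ordinary
    (inverted-CDF) sample quantile.
    """
    series = _as_series(series)
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("probs must not be empty")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.quantile(
        series.values, probs, weights=series.weights, method="inverted_cdf"
    )
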