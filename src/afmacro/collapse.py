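"""Data collapse and distribution-family comparison for allele frequencies.

Pooled nonzero frequencies for each species are log10-transformed and
z-scored; when species share a common underlying distribution shape the
rescaled samples fall on one curve. On the log scale the candidate families
are fit directly — the log of a gamma variate is log-gamma and the log of a
lognormal is Gaussian — and compared by AIC. Empirical survival curves give
an unsmoothed view of the tails.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RescaledSample",
    "FitResult",
    "AICComparison",
    "pool_and_rescale",
    "fit_log_frequency_distribution",
    "aic_compare",
    "survival_curve",
]


@dataclasses.dataclass
class RescaledSample:
    """z-scored log10 values plus the bookkeeping of what was dropped."""

    z: np.ndarray
    n_used: int
    n_zero_dropped: int
    n_one_dropped: int
    mean_log10: float
    sd_log10: float


@dataclasses.dataclass
class FitResult:
    """Maximum-likelihood fit of one family on log10-transformed values."""

    family: str
    params: tuple
    loglik: float
    k: int
    n: int


@dataclasses.dataclass
class AICComparison:
    aic: dict
    winner: str
    margin: float


def pool_and_rescale(values, exclude_f1: bool = False) -> RescaledSample:
    """Pool frequencies, drop zeros, log10-transform, and z-score.

    ``values`` is an array-like of frequencies or a DataFrame with an ``f``
    column. ``exclude_f1`` additionally drops exact ones (used for the
    across-host mean-frequency variant, where f = 1 observations reflect the
    bounded support rather than the distribution of interest).
    """
    if isinstance(values, pd.DataFrame):
        values = values["f"]
    v = np.asarray(values, dtype=float)
    n_zero = int((v == 0).sum())
    v = v[v > 0]
    n_one = 0
    if exclude_f1:
        n_one = int((v == 1).sum())
        v = v[v < 1]
    if v.size < 2:
        raise ValueError(f"need at least 2 nonzero frequencies, got {v.size}")
    logv = np.log10(v)
    mean = float(logv.mean())
    sd = float(logv.std())
    if sd == 0:
        raise ValueError("cannot rescale: zero standard deviation of log10 frequencies")
    return RescaledSample(
        z=(logv - mean) / sd,
        n_used=int(v.size),
        n_zero_dropped=n_zero,
        n_one_dropped=n_one,
        mean_log10=mean,
        sd_log10=sd,
    )


def fit_log_frequency_distribution(values, family: str) -> FitResult:
    """ML fit of a family to log10-transformed nonzero frequencies.

    ``family="gamma"`` fits the log-gamma distribution (the law of the log
    of a gamma variate; 3 free parameters) and ``family="lognormal"`` fits a
    Gaussian (2 free parameters) — fitting on the log scale, where the
    rescaled distributions live.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError(f"need at least 10 values to fit, got {v.size}")
    if family == "gamma":
        params = stats.loggamma.fit(v)
        loglik = float(stats.loggamma.logpdf(v, *params).sum())
        k = 3
    elif family == "lognormal":
        params = stats.norm.fit(v)
        loglik = float(stats.norm.logpdf(v, *params).sum())
        k = 2
    else:
        raise ValueError(f"family must be 'gamma' or 'lognormal', got {family!r}")
    if not np.isfinite(loglik):
        raise RuntimeError(
            f"{family} fit did not converge to a finite log-likelihood (params={params})"
        )
    return FitResult(family=family, params=tuple(params), loglik=loglik, k=k, n=int(v.size))


def aic_compare(fits) -> AICComparison:
    """AIC = 2k - 2 logL per family; the lower value wins.

    All fits must have been computed on the same data (checked via n).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 family fits to compare")
    sizes = {fit.n for fit in fits}
    if len(sizes) != 1:
        raise ValueError(f"fits were computed on different data (n values {sorted(sizes)})")
    aic = {fit.family: 2 * fit.k - 2 * fit.loglik for fit in fits}
    ranked = sorted(aic.items(), key=lambda kv: kv[1])
    return AICComparison(aic=aic, winner=ranked[0][0], margin=ranked[1][1] - ranked[0][1])


def survival_curve(values) -> pd.DataFrame:
    """Empirical survival probability P(X >= x) at each distinct value.

    Monotone nonincreasing from 1 down to (count of maximum)/n; ties
    collapse into a single step; no smoothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    uniq, counts = np.unique(v, return_counts=True)
    # P(X >= uniq[i]) = (n - number strictly below) / n
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    sf = (v.size - below) / v.size
    return pd.DataFrame({"value": uniq, "survival": sf})
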