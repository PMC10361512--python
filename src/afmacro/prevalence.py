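"""Sampling distribution of read counts and zero-free-parameter prevalence.

The frequency of an allele across hosts is modeled as gamma with mean
``fbar`` and squared inverse CV ``beta``, both estimated directly from the
data (no fitting). Read counts at depth D are Poisson given the latent
frequency (the large-D, small-f approximation of binomial sampling), and
integrating the Poisson over the gamma yields a negative-binomial-form pmf

    Pr[A | D, beta, beta/fbar]
        = Gamma(beta + A) / (A! Gamma(beta))
          * (fbar D / (beta + fbar D))^A * (beta / (beta + fbar D))^beta

evaluated in log space. Absence is the A = 0 term; prevalence across M
hosts is one minus the host-averaged probability of observing fewer than
``a_cutoff`` alternate reads, which reduces to the plain absence form when
the detection cutoff is a single read.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "sampling_pmf",
    "absence_probability",
    "predicted_prevalence",
    "predicted_prevalence_truncated",
    "observed_prevalence",
    "relative_error",
    "prevalence_curve",
    "site_moments_for_prediction",
    "predict_cohort",
]


def _var_floor(fbar):
    # variance at the float rounding scale of the mean is numerically zero
    return (np.asarray(fbar) * 1e-9) ** 2


def _validate_params(fbar, beta) -> None:
    if not np.all(np.asarray(fbar) > 0):
        raise ValueError("fbar must be positive")
    if not np.all(np.asarray(beta) > 0):
        raise ValueError("beta must be positive")


def sampling_pmf(A, D, fbar: float, beta: float) -> np.ndarray | float:
    """Probability of observing A alternate reads at depth D.

    Vectorized over ``A`` and ``D``; computed via log-gamma for stability.
    """
    A = np.asarray(A)
    if np.any(A < 0):
        raise ValueError("read counts A must be nonnegative")
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("depth D must be positive")
    _validate_params(fbar, beta)
    fD = fbar * D
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(fD) - np.log(beta + fD)
        logp = (
            gammaln(beta + A)
            - gammaln(A + 1)
            - gammaln(beta)
            + np.where(A > 0, A * log_ratio, 0.0)
            + beta * (np.log(beta) - np.log(beta + fD))
        )
    out = np.exp(logp)
    return out if out.ndim else float(out)


def absence_probability(D, fbar: float, beta: float) -> np.ndarray | float:
    """Probability of zero alternate reads: (1 + D fbar / beta)^(-beta).

    Strictly decreasing in D and fbar; D = 0 returns 1 (nothing sampled).
    """
    _validate_params(fbar, beta)
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("depth D must be nonnegative")
    out = np.exp(-beta * np.log1p(D * fbar / beta))
    out = np.where(D == 0, 1.0, out)
    return out if out.ndim else float(out)


def predicted_prevalence(D_by_host, fbar: float, beta: float) -> float:
    """Expected prevalence over M hosts: 1 - mean_m Pr[0 | D_m]."""
    D = np.asarray(D_by_host, dtype=float)
    if D.size == 0:
        raise ValueError("empty host depth list")
    return float(1.0 - np.mean(absence_probability(D, fbar, beta)))


def predicted_prevalence_truncated(
    D_by_host, fbar: float, beta: float, a_cutoff: int = 10
) -> float:
    """Expected prevalence under a minor-allele detection cutoff.

    Read counts below ``a_cutoff`` are observed as zeros, so presence
    requires A >= a_cutoff: 1 - mean_m sum_{A < a_cutoff} Pr[A | D_m].
    Equals the untruncated prediction when a_cutoff = 1.
    """
    if a_cutoff < 1:
        raise ValueError(f"a_cutoff must be >= 1, got {a_cutoff}")
    D = np.asarray(D_by_host, dtype=float)
    if D.size == 0:
        raise ValueError("empty host depth list")
    A_grid = np.arange(a_cutoff)[:, None]
    below = sampling_pmf(A_grid, D[None, :], fbar, beta).sum(axis=0)
    return float(max(0.0, 1.0 - np.mean(below)))


def observed_prevalence(f_by_host) -> float:
    """Fraction of hosts in which the allele is detected (f > 0)."""
    f = np.asarray(f_by_host, dtype=float)
    if f.size == 0:
        raise ValueError("empty host frequency list")
    return float(np.mean(f > 0))


def relative_error(observed: float, predicted: float) -> float:
    """Relative error |observed - predicted| / observed of a prediction."""
    if not observed > 0:
        raise ValueError("relative error undefined for observed prevalence of zero")
    return abs(observed - predicted) / observed


def prevalence_curve(
    fbar_grid, beta: float, D_by_host, a_cutoff: int = 1
) -> pd.DataFrame:
    """Predicted prevalence along a grid of mean frequencies at fixed beta."""
    grid = np.asarray(fbar_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty fbar grid")
    prev = [
        predicted_prevalence_truncated(D_by_host, fb, beta, a_cutoff=a_cutoff) for fb in grid
    ]
    return pd.DataFrame({"fbar": grid, "predicted": prev})


def _pivot(freqs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Wide (site x host) frequency and depth matrices, NaN where unobserved.

    Rows failing the minimum-depth condition (depth_ok False) are treated as
    unobserved so that observed and predicted prevalence condition on the
    same hosts.
    """
    use = freqs
    if "depth_ok" in freqs.columns:
        use = freqs[freqs["depth_ok"]]
    f_wide = use.pivot(index="site_id", columns="host_id", values="f")
    d_wide = use.pivot(index="site_id", columns="host_id", values="D")
    return f_wide.to_numpy(dtype=float), d_wide.to_numpy(dtype=float), f_wide.index


def _matrix_moments(f: np.ndarray, include_zeros: bool) -> tuple[np.ndarray, np.ndarray]:
    if include_zeros:
        fbar = np.nanmean(f, axis=1)
        var = np.nanvar(f, axis=1)
    else:
        pos = np.where(f > 0, f, np.nan)
        with np.errstate(invalid="ignore"):
            fbar = np.nanmean(pos, axis=1)
            var = np.nanvar(pos, axis=1)
    return fbar, var


def site_moments_for_prediction(
    freqs: pd.DataFrame, include_zeros: bool = True
) -> pd.DataFrame:
    """Per-site empirical (fbar, beta) used as the prediction's inputs.

    Moments are taken across all hosts, zeros included (the default): under
    the ecological model a zero is a sampling artifact of a strain that is
    present, so the zeros carry information. ``include_zeros=False`` computes
    moments over detected hosts only. Sites that are all-zero or have zero
    variance are excluded with a logged count.
    """
    f, _, index = _pivot(freqs)
    fbar, var = _matrix_moments(f, include_zeros)
    n_hosts = np.sum(~np.isnan(f), axis=1)
    ok = (fbar > 0) & (var > _var_floor(fbar))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "excluded %d site(s) with all-zero frequencies or zero variance", n_dropped
        )
    return pd.DataFrame(
        {
            "site_id": index[ok],
            "fbar": fbar[ok],
            "var": var[ok],
            "beta": fbar[ok] ** 2 / var[ok],
            "n_hosts": n_hosts[ok],
        }
    ).reset_index(drop=True)


def predict_cohort(
    freqs: pd.DataFrame,
    a_cutoff: int | None = None,
    include_zeros: bool = True,
) -> pd.DataFrame:
    """Per-site observed and predicted prevalence with relative errors.

    For every site with at least one detection and nonzero variance, the
    empirical (fbar, beta) parameterize the sampling distribution, and both
    the truncated (detection-cutoff-aware) and untruncated predictions are
    evaluated over that site's per-host depths. ``a_cutoff`` defaults to the
    threshold recorded on ``freqs`` by the detection filter, or 1.
    """
    if a_cutoff is None:
        a_cutoff = int(freqs.attrs.get("a_cutoff", 1))
    f, d, index = _pivot(freqs)
    fbar, var = _matrix_moments(f, include_zeros)
    mean_all = np.nanmean(f, axis=1)  # detections are defined over all hosts
    ok = (fbar > 0) & (var > _var_floor(fbar)) & (mean_all > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("excluded %d undefined site(s) from prevalence prediction", n_dropped)
    f, d, index = f[ok], d[ok], index[ok]
    fbar, var = fbar[ok], var[ok]
    beta = fbar**2 / var

    observed_mask = ~np.isnan(f)
    n_hosts = observed_mask.sum(axis=1)
    observed = np.where(observed_mask, f > 0, False).sum(axis=1) / n_hosts

    # untruncated: host-averaged absence under each site's own parameters
    with np.errstate(invalid="ignore"):
        absent = np.exp(-beta[:, None] * np.log1p(d * fbar[:, None] / beta[:, None]))
    predicted_untrunc = 1.0 - np.nansum(absent, axis=1) / n_hosts

    below = np.zeros_like(f)
    fD = fbar[:, None] * d
    b = beta[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(fD) - np.log(b + fD)
        log_base = b * (np.log(b) - np.log(b + fD)) - gammaln(b)
        for a in range(a_cutoff):
            below += np.exp(
                gammaln(b + a) - gammaln(a + 1) + log_base + (a * log_ratio if a else 0.0)
            )
    predicted = np.maximum(0.0, 1.0 - np.nansum(below, axis=1) / n_hosts)

    records = pd.DataFrame(
        {
            "site_id": index,
            "observed": observed,
            "predicted": predicted,
            "predicted_untruncated": predicted_untrunc,
            "epsilon": np.abs(observed - predicted) / observed,
            "fbar": fbar,
            "beta": beta,
            "n_hosts": n_hosts,
        }
    ).reset_index(drop=True)
    records.attrs["a_cutoff"] = a_cutoff
    return records
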