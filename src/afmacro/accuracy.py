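"""Accuracy of prevalence predictions and its relation to strain structure.

Summaries of the relative-error distribution, binned observed-versus-
predicted prevalence, a permutation test for the (negative) correlation
between prediction error and observed prevalence within a species, and the
across-species scan correlating mean error above increasing prevalence
thresholds with the fraction of hosts harboring strain structure.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .collapse import RescaledSample, pool_and_rescale

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorSummary",
    "PermutationResult",
    "StrainScanResult",
    "error_summary",
    "rescale_error_distribution",
    "bin_observed_vs_predicted",
    "error_prevalence_correlation",
    "strain_structure_scan",
]


@dataclasses.dataclass
class ErrorSummary:
    fraction_within: float
    mean_log10_error: float
    epsilon_threshold: float
    n_sites: int
    n_within: int
    n_zero_error: int


@dataclasses.dataclass
class PermutationResult:
    statistic: float
    null_lower: float
    null_upper: float
    n_permutations: int
    significant: bool
    n_sites: int


@dataclasses.dataclass
class StrainScanResult:
    thresholds: np.ndarray
    correlation: np.ndarray
    null_lower: np.ndarray
    null_upper: np.ndarray
    n_species: np.ndarray
    species: list
    n_sites: pd.DataFrame
    mean_epsilon: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "correlation": self.correlation,
                "null_lower": self.null_lower,
                "null_upper": self.null_upper,
                "n_species": self.n_species,
            }
        )


def error_summary(records: pd.DataFrame, epsilon_threshold: float = 0.1) -> ErrorSummary:
    """Fraction of sites with relative error <= threshold, and mean log10 error.

    Exact-zero errors count toward the fraction but are excluded (with a
    recorded count) from the mean of log10 epsilon.
    """
    if records.empty:
        raise ValueError("empty prevalence-record table")
    eps = records["epsilon"].to_numpy(dtype=float)
    within = eps <= epsilon_threshold
    pos = eps[eps > 0]
    n_zero = int((eps == 0).sum())
    if n_zero:
        logger.info("%d exact-zero errors excluded from the log10 mean", n_zero)
    mean_log10 = float(np.log10(pos).mean()) if pos.size else float("nan")
    return ErrorSummary(
        fraction_within=float(within.mean()),
        mean_log10_error=mean_log10,
        epsilon_threshold=epsilon_threshold,
        n_sites=int(eps.size),
        n_within=int(within.sum()),
        n_zero_error=n_zero,
    )


def rescale_error_distribution(epsilon_values) -> RescaledSample:
    """z-scored log10 relative errors (positive errors only), per species."""
    return pool_and_rescale(epsilon_values)


def bin_observed_vs_predicted(
    records: pd.DataFrame, n_bins: int = 20, min_sites: int = 5
) -> pd.DataFrame:
    """Median observed and predicted prevalence in log10-spaced bins.

    Bins are laid over the range of positive observed prevalences; bins
    holding fewer than ``min_sites`` sites are dropped.
    """
    obs = records["observed"].to_numpy(dtype=float)
    pred = records["predicted"].to_numpy(dtype=float)
    keep = obs > 0
    obs, pred = obs[keep], pred[keep]
    if obs.size == 0:
        raise ValueError("no sites with positive observed prevalence")
    lo, hi = np.log10(obs.min()), np.log10(obs.max())
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(np.log10(obs), edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.sum() < min_sites:
            continue
        rows.append(
            {
                "bin_left": 10 ** edges[b],
                "bin_right": 10 ** edges[b + 1],
                "n_sites": int(mask.sum()),
                "median_observed": float(np.median(obs[mask])),
                "median_predicted": float(np.median(pred[mask])),
            }
        )
    return pd.DataFrame(rows)


def _permuted_dot(rng: np.random.Generator, y: np.ndarray, xc: np.ndarray, n_perm: int) -> np.ndarray:
    """Dot products of xc with row-wise permutations of y, chunked."""
    n = y.size
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    base = np.tile(y, (chunk, 1))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(base[:b], axis=1)
        out[done : done + b] = perm @ xc
        done += b
    return out


def error_prevalence_correlation(
    records: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Pearson correlation of log10 observed prevalence with relative error.

    The null distribution comes from ``n_perm`` independent shuffles of the
    errors against the prevalences; the 95% interval is the 2.5th-97.5th
    percentile window, and the observed statistic is flagged significant
    when it falls outside it.
    """
    keep = (records["observed"] > 0) & np.isfinite(records["epsilon"])
    x = np.log10(records.loc[keep, "observed"].to_numpy(dtype=float))
    y = records.loc[keep, "epsilon"].to_numpy(dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 usable sites, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant prevalence or error vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r = float((xc @ yc) / denom)

    rng = np.random.default_rng(seed)
    null = (_permuted_dot(rng, y, xc, n_perm) - y.mean() * xc.sum()) / denom
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        statistic=r,
        null_lower=float(lo),
        null_upper=float(hi),
        n_permutations=n_perm,
        significant=bool(r < lo or r > hi),
        n_sites=int(x.size),
    )


def _pearson_rows(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with v."""
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (vc @ vc))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (Xc @ vc) / denom


def strain_structure_scan(
    records_by_species: dict,
    strain_fraction: dict,
    thresholds=None,
    min_sites: int = 10,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    mode: str = "at_or_above",
) -> StrainScanResult:
    """Correlate mean prediction error with strain-structure fraction.

    For each prevalence threshold t, each species contributes the mean
    relative error over its sites with observed prevalence >= t (mode
    "at_or_above"; mode "between" uses the window up to the next threshold)
    — but only if it holds at least ``min_sites`` such sites. The observed
    Pearson correlation of those species means against the fraction of
    hosts with strain structure is compared with a null built by permuting
    errors within species, recomputing every threshold mean, and
    recorrelating. Thresholds where fewer than 3 species survive are
    reported as undefined (NaN).
    """
    if mode not in ("at_or_above", "between"):
        raise ValueError(f"mode must be 'at_or_above' or 'between', got {mode!r}")
    species = sorted(records_by_species)
    if len(species) < 5:
        raise ValueError(f"need at least 5 species, got {len(species)}")
    missing = [sp for sp in species if sp not in strain_fraction]
    if missing:
        raise ValueError(f"strain fractions missing for species: {missing}")
    if thresholds is None:
        thresholds = np.logspace(np.log10(0.01), np.log10(0.5), 20)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    T = thresholds.size
    sf = np.array([strain_fraction[sp] for sp in species], dtype=float)
    rng = np.random.default_rng(seed)

    n_sp = len(species)
    counts = np.zeros((n_sp, T), dtype=int)
    obs_mean = np.full((n_sp, T), np.nan)
    null_means = np.full((n_perm, n_sp, T), np.nan)

    for i, sp in enumerate(species):
        rec = records_by_species[sp]
        keep = (rec["observed"] > 0) & np.isfinite(rec["epsilon"])
        obs = rec.loc[keep, "observed"].to_numpy(dtype=float)
        eps = rec.loc[keep, "epsilon"].to_numpy(dtype=float)
        order = np.argsort(-obs)  # descending prevalence: threshold sets are prefixes
        eps_sorted = eps[order]
        obs_sorted = obs[order]
        n_at = np.searchsorted(-obs_sorted, -thresholds, side="right")
        if mode == "at_or_above":
            lo_idx = np.zeros(T, dtype=int)
            hi_idx = n_at
        else:
            # window [t_j, t_{j+1}): sites with obs >= t_j minus those >= t_{j+1};
            # the last window extends to 1
            hi_idx = n_at
            lo_idx = np.concatenate([n_at[1:], [0]])
        counts[i] = hi_idx - lo_idx

        csum = np.concatenate([[0.0], np.cumsum(eps_sorted)])
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (csum[hi_idx] - csum[lo_idx]) / counts[i]
        obs_mean[i] = means

        # under permutation of eps across sites, any fixed subset of size k
        # receives k exchangeable draws, so prefix means of a permuted eps
        # vector reproduce the Methods' within-species permutation scheme
        perm = rng.permuted(np.tile(eps_sorted, (n_perm, 1)), axis=1)
        pcsum = np.concatenate(
            [np.zeros((n_perm, 1)), np.cumsum(perm, axis=1)], axis=1
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            null_means[:, i, :] = (pcsum[:, hi_idx] - pcsum[:, lo_idx]) / counts[i]

    valid = counts >= min_sites
    correlation = np.full(T, np.nan)
    null_lo = np.full(T, np.nan)
    null_hi = np.full(T, np.nan)
    n_species_used = valid.sum(axis=0)
    for t in range(T):
        use = valid[:, t]
        if use.sum() < 3:
            continue
        v = sf[use]
        if np.ptp(v) == 0:
            continue  # correlation undefined when strain fractions are identical
        m = obs_mean[use, t]
        correlation[t] = _pearson_rows(m[None, :], v)[0]
        null_r = _pearson_rows(null_means[:, use, t], v)
        null_lo[t], null_hi[t] = np.nanpercentile(null_r, [2.5, 97.5])

    return StrainScanResult(
        thresholds=thresholds,
        correlation=correlation,
        null_lower=null_lo,
        null_upper=null_hi,
        n_species=n_species_used,
        species=species,
        n_sites=pd.DataFrame(counts, index=species, columns=thresholds),
        mean_epsilon=pd.DataFrame(obs_mean, index=species, columns=thresholds),
    )
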