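"""Per-site moments and Taylor's Law mean-variance scaling across hosts.

Each site's across-host mean frequency and variance (zeros included) are
regressed against one another on a log10-log10 scale; an exponent of 2
means the coefficient of variation of frequency is constant across sites,
the signature the ecological model predicts. Sites detected in too few
hosts are excluded (their moments are dominated by zeros), and the fit is
restricted to low mean frequencies where the power law is not confounded by
the bounded support of f — at high means the variance instead tracks the
Bhatia-Davis ceiling (1 - fbar) fbar.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaylorFit",
    "compute_site_moments",
    "site_moments_from_matrix",
    "occupancy_filter",
    "taylor_fit",
    "bhatia_davis_bound",
]


@dataclasses.dataclass
class TaylorFit:
    slope: float
    intercept: float
    n_sites: int
    ci_lower: float
    ci_upper: float
    fbar_max: float
    n_bootstrap: int


def site_moments_from_matrix(
    f: np.ndarray, site_ids=None
) -> pd.DataFrame:
    """Moments from a site x host frequency matrix (NaN = unobserved)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[1] < 2:
        raise ValueError("need a 2-D site x host matrix with >= 2 hosts")
    if site_ids is None:
        site_ids = [f"s{i:06d}" for i in range(f.shape[0])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows yield NaN
        fbar = np.nanmean(f, axis=1)
        var = np.nanvar(f, axis=1)
        occupancy = np.nanmean(np.where(np.isnan(f), np.nan, f > 0), axis=1)
    n_hosts = np.sum(~np.isnan(f), axis=1)
    bound = (1.0 - fbar) * fbar
    bad = var > bound + 1e-9
    if bad.any():
        raise RuntimeError(
            "variance exceeds the Bhatia-Davis bound (1 - fbar) fbar at "
            f"{int(bad.sum())} site(s) — moment estimator bug"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(var > 0, fbar**2 / var, np.nan)
    return pd.DataFrame(
        {
            "site_id": np.asarray(site_ids, dtype=object),
            "fbar": fbar,
            "var": var,
            "beta": beta,
            "occupancy": occupancy,
            "n_hosts": n_hosts,
        }
    )


def compute_site_moments(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-site across-host moments from a long frequency table.

    Zeros (non-detections at adequate depth) are included in the moments;
    rows below the depth minimum (depth_ok False) are treated as unobserved.
    The Bhatia-Davis inequality is asserted on every site.
    """
    use = freqs[freqs["depth_ok"]] if "depth_ok" in freqs.columns else freqs
    wide = use.pivot(index="site_id", columns="host_id", values="f")
    return site_moments_from_matrix(wide.to_numpy(dtype=float), site_ids=wide.index)


def occupancy_filter(moments: pd.DataFrame, min_occupancy: float = 0.35) -> pd.DataFrame:
    """Drop sites detected in fewer than ``min_occupancy`` of hosts.

    Exclusion is strict (< threshold), so a site exactly at the threshold is
    kept. The removal count is logged; an empty result warns.
    """
    if not 0 < min_occupancy <= 1:
        raise ValueError(f"min_occupancy must lie in (0, 1], got {min_occupancy}")
    kept = moments[moments["occupancy"] >= min_occupancy].reset_index(drop=True)
    logger.info("occupancy filter removed %d of %d sites", len(moments) - len(kept), len(moments))
    if kept.empty:
        warnings.warn("occupancy filter removed every site", stacklevel=2)
    return kept


def _slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    denom = xc @ xc
    slope = (xc @ y) / denom
    return float(slope), float(y.mean() - slope * x.mean())


def taylor_fit(
    moments: pd.DataFrame,
    fbar_max: float = 0.35,
    n_bootstrap: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> TaylorFit:
    """OLS of log10 variance on log10 mean with a percentile-bootstrap CI.

    The fit uses sites with 0 < fbar <= fbar_max and positive variance
    (zero-variance sites are logged and excluded). The 95% CI comes from
    resampling sites with replacement and refitting ``n_bootstrap`` times —
    the CI quantifies the scatter across sites.
    """
    sel = (moments["fbar"] > 0) & (moments["fbar"] <= fbar_max) & (moments["var"] > 0)
    n_zero_var = int(((moments["fbar"] > 0) & (moments["var"] == 0)).sum())
    if n_zero_var:
        logger.info("excluded %d zero-variance site(s) from the Taylor fit", n_zero_var)
    x = np.log10(moments.loc[sel, "fbar"].to_numpy())
    y = np.log10(moments.loc[sel, "var"].to_numpy())
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 sites for the Taylor fit, got {n}")
    slope, intercept = _slope_intercept(x, y)

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_bootstrap)
    chunk = max(1, min(n_bootstrap, int(2e7 // max(n, 1))))
    done = 0
    while done < n_bootstrap:
        b = min(chunk, n_bootstrap - done)
        idx = rng.integers(0, n, size=(b, n))
        xb = x[idx]
        yb = y[idx]
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        sxx = ((xb - xm) ** 2).sum(axis=1)
        sxy = ((xb - xm) * (yb - ym)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes[done : done + b] = sxy / sxx
        done += b
    lo, hi = np.nanpercentile(slopes, [2.5, 97.5])
    return TaylorFit(
        slope=slope,
        intercept=intercept,
        n_sites=n,
        ci_lower=float(lo),
        ci_upper=float(hi),
        fbar_max=fbar_max,
        n_bootstrap=n_bootstrap,
    )


def bhatia_davis_bound(fbar):
    """Maximum variance of a [0, 1]-bounded variable with mean fbar."""
    fb = np.asarray(fbar, dtype=float)
    if np.any((fb < 0) | (fb > 1)):
        raise ValueError("fbar must lie in [0, 1]")
    out = (1.0 - fb) * fb
    return out if out.ndim else float(out)
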