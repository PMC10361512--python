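"""Seeded synthetic cohorts emulating processed across-host metagenomic data.

The generator emits per-species site x host tables of alternate-allele read
counts ``A`` and depths ``D`` whose latent statistical structure matches what
the downstream analysis assumes about processed shotgun data from a cohort of
unrelated hosts:

* "strain-backed" sites — the allele rides a colonizing strain whose
  frequency across hosts is gamma distributed with site-specific mean and a
  shared squared inverse CV (constant beta, hence a Taylor exponent of 2);
* "evolutionary" sites — low-prevalence alleles maintained by
  mutation-selection balance, gamma distributed with a small shape;
* read sampling (binomial or Poisson) at depths drawn from a discretized
  lognormal truncated to the pipeline's minimum coverage;
* per-host strain-structure presence indicators as ground truth for the
  strain-structure scan.

Detection filtering and major-allele polarization, the two operations the
upstream inference pipeline imposes on real data, are provided here as well
so every downstream module sees identically conditioned input.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .slm import EvoParams, evo_gamma_params

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_ensemble",
    "apply_detection_filter",
    "polarize",
    "polarize_counts",
]

#: default evolutionary-site parameters: shape 2*N*mu = 0.05 and mean
#: mu/|s| = 0.01, so evo alleles sit at the low-frequency, low-prevalence
#: end of the observable window.
DEFAULT_EVO_PARAMS = EvoParams(N=1e6, mu=2.5e-8, s=-2.5e-6)


@dataclasses.dataclass
class CohortSpec:
    """Conditions under which a synthetic cohort is generated.

    Defaults emulate the processed cohort this analysis targets: 182 hosts,
    ~10k sites of which a minority are evolutionary, per-site mean
    frequencies log-uniform over [1e-3, 0.35], constant beta = 1, coverage
    lognormal with median 40 truncated at D >= 20, and the detection
    thresholds D >= 20, A >= 10.
    """

    n_hosts: int = 182
    n_strain_sites: int = 8000
    n_evo_sites: int = 2000
    fbar_min: float = 1e-3
    fbar_max: float = 0.35
    beta: float = 1.0
    evo: EvoParams = DEFAULT_EVO_PARAMS
    coverage_median: float = 40.0
    coverage_sigma: float = 0.5
    d_min: int = 20
    a_cutoff: int = 10
    sampling: str = "binomial"
    strain_host_fraction: float = 0.27
    synonymous_fraction: float = 0.66

    def __post_init__(self) -> None:
        if self.n_hosts < 2:
            raise ValueError(f"n_hosts must be >= 2, got {self.n_hosts}")
        if self.n_strain_sites < 0 or self.n_evo_sites < 0:
            raise ValueError("site counts must be nonnegative")
        if self.n_strain_sites + self.n_evo_sites == 0:
            raise ValueError("empty cohort: no strain-backed or evolutionary sites requested")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0 < self.fbar_min <= self.fbar_max < 1):
            raise ValueError("fbar range must satisfy 0 < fbar_min <= fbar_max < 1")
        if self.sampling not in ("binomial", "poisson"):
            raise ValueError(f"sampling must be 'binomial' or 'poisson', got {self.sampling!r}")
        if self.coverage_median < self.d_min:
            raise ValueError("coverage median must respect the minimum depth")
        if not 0 <= self.strain_host_fraction <= 1:
            raise ValueError("strain_host_fraction must lie in [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    """Latent state behind a generated cohort, for parameter-recovery tests.

    ``sites`` carries per-site class and true (fbar, beta); ``latent`` is the
    site x host matrix of true frequencies before read sampling; ``hosts``
    carries the per-host strain-structure indicator.
    """

    sites: pd.DataFrame
    latent: np.ndarray
    hosts: pd.DataFrame


def _clipped_gamma_moments(shape: np.ndarray, scale: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean, squared inverse CV) of min(X, 1) for X ~ Gamma(shape, scale).

    Latent frequencies are clipped at 1, so the ground truth recorded per
    site describes the clipped law actually sampled, not the nominal gamma:
    E[min(X,1)] = k*theta*F_{k+1}(1) + S_k(1) and similarly for the second
    moment via the shape+2 CDF.
    """
    F1 = stats.gamma.cdf(1.0, a=shape + 1, scale=scale)
    F2 = stats.gamma.cdf(1.0, a=shape + 2, scale=scale)
    sf = stats.gamma.sf(1.0, a=shape, scale=scale)
    m1 = shape * scale * F1 + sf
    m2 = shape * (shape + 1) * scale**2 * F2 + sf
    var = m2 - m1**2
    return m1, m1**2 / var


def _truncated_lognormal_depths(
    rng: np.random.Generator, size: int, median: float, sigma: float, d_min: int
) -> np.ndarray:
    """Integer depths from a discretized lognormal, resampled until >= d_min."""
    depths = np.rint(rng.lognormal(np.log(median), sigma, size=size))
    for _ in range(100):
        low = depths < d_min
        if not low.any():
            break
        depths[low] = np.rint(rng.lognormal(np.log(median), sigma, size=int(low.sum())))
    else:  # pragma: no cover - pathological spec
        depths = np.maximum(depths, d_min)
    return depths.astype(np.int64)


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a (CountMatrix, GroundTruth) pair under ``spec``.

    Strain-backed sites draw latent per-host frequencies from
    Gamma(beta, beta/fbar) with site-specific fbar; evolutionary sites draw
    from the mutation-selection-balance gamma of ``spec.evo``. Latent draws
    above 1 are clipped (a warning is logged if the analytic clip
    probability exceeds 1% at any site). Reads are then sampled binomially
    (or Poisson) given (f, D). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    M = spec.n_hosts
    S = spec.n_strain_sites + spec.n_evo_sites

    fbar = np.empty(S)
    beta = np.empty(S)
    site_class_model = np.array(
        ["strain"] * spec.n_strain_sites + ["evo"] * spec.n_evo_sites, dtype=object
    )
    if spec.n_strain_sites:
        if spec.fbar_min == spec.fbar_max:
            fbar[: spec.n_strain_sites] = spec.fbar_min
        else:
            fbar[: spec.n_strain_sites] = stats.loguniform.rvs(
                spec.fbar_min, spec.fbar_max, size=spec.n_strain_sites, random_state=rng
            )
        beta[: spec.n_strain_sites] = spec.beta
    if spec.n_evo_sites:
        gp = evo_gamma_params(spec.evo)
        fbar[spec.n_strain_sites :] = gp.mean
        beta[spec.n_strain_sites :] = gp.shape

    clip_prob = stats.gamma.sf(1.0, a=beta, scale=fbar / beta)
    if (clip_prob > 0.01).any():
        logger.warning(
            "gamma mass above f=1 exceeds 1%% at %d site(s); latent draws will be clipped",
            int((clip_prob > 0.01).sum()),
        )
    true_fbar, true_beta = _clipped_gamma_moments(beta, fbar / beta)

    latent = rng.gamma(shape=beta[:, None], scale=(fbar / beta)[:, None], size=(S, M))
    np.clip(latent, 0.0, 1.0, out=latent)

    depths = _truncated_lognormal_depths(
        rng, S * M, spec.coverage_median, spec.coverage_sigma, spec.d_min
    ).reshape(S, M)
    if spec.sampling == "binomial":
        A = rng.binomial(depths, latent)
    else:
        A = np.minimum(rng.poisson(depths * latent), depths)

    site_ids = np.array([f"s{i:06d}" for i in range(S)], dtype=object)
    gene_ids = np.array([f"g{i // 20:05d}" for i in range(S)], dtype=object)
    site_class = np.where(
        rng.random(S) < spec.synonymous_fraction, "synonymous", "nonsynonymous"
    ).astype(object)
    host_ids = np.array([f"h{m:04d}" for m in range(M)], dtype=object)

    counts = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, M),
            "gene_id": np.repeat(gene_ids, M),
            "site_class": np.repeat(site_class, M),
            "host_id": np.tile(host_ids, S),
            "A": A.ravel(),
            "D": depths.ravel(),
        }
    )
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "model_class": site_class_model,
            "true_fbar": true_fbar,
            "true_beta": true_beta,
            "nominal_fbar": fbar,
            "nominal_beta": beta,
        }
    )
    hosts = pd.DataFrame(
        {
            "host_id": host_ids,
            "has_strains": (rng.random(M) < spec.strain_host_fraction).astype(np.int64),
        }
    )
    return counts, GroundTruth(sites=sites, latent=latent, hosts=hosts)


def generate_ensemble(
    n_species: int,
    base_spec: CohortSpec | None = None,
    strain_fractions: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, dict]:
    """Generate a multi-species ensemble for the strain-structure scan.

    Species are assigned strain-structure host fractions spanning the
    observed range [0.089, 0.64] and an evolutionary-site share that
    decreases with the strain fraction: species whose hosts are rich in
    strain structure carry mostly strain-backed (predictable) alleles.
    Returns a mapping species_id -> {"counts", "truth", "strain_fraction"}.
    """
    if n_species < 2:
        raise ValueError(f"n_species must be >= 2, got {n_species}")
    if base_spec is None:
        base_spec = CohortSpec()
    rng = np.random.default_rng(seed)
    if strain_fractions is None:
        strain_fractions = np.linspace(0.089, 0.64, n_species)
    strain_fractions = np.asarray(strain_fractions, dtype=float)
    if strain_fractions.shape != (n_species,):
        raise ValueError("strain_fractions must have one entry per species")

    total_sites = base_spec.n_strain_sites + base_spec.n_evo_sites
    lo, hi = strain_fractions.min(), strain_fractions.max()
    span = hi - lo if hi > lo else 1.0
    ensemble: dict[str, dict] = {}
    for k in range(n_species):
        sf = strain_fractions[k]
        evo_share = 0.05 + 0.45 * (1.0 - (sf - lo) / span)
        n_evo = max(1, int(round(evo_share * total_sites)))
        spec_k = dataclasses.replace(
            base_spec,
            n_strain_sites=total_sites - n_evo,
            n_evo_sites=n_evo,
            strain_host_fraction=float(sf),
        )
        counts, truth = generate_cohort(spec_k, seed=rng)
        ensemble[f"sp{k:02d}"] = {
            "counts": counts,
            "truth": truth,
            "strain_fraction": float(sf),
        }
    return ensemble


def apply_detection_filter(
    counts: pd.DataFrame, d_min: int = 20, a_cutoff: int = 10
) -> pd.DataFrame:
    """Convert read counts to detection-filtered allele frequencies.

    f = A/D where D >= d_min and A >= a_cutoff, else 0 (non-detection).
    Rows with D < d_min are kept with f = 0 but flagged ``depth_ok=False``;
    prevalence operations condition on depth_ok so observed and predicted
    prevalence are computed over the same host set. The thresholds used are
    recorded in ``DataFrame.attrs`` so predictions can match them.
    """
    if d_min < 1 or a_cutoff < 1:
        raise ValueError("detection thresholds must be >= 1")
    depth_ok = counts["D"].to_numpy() >= d_min
    detected = depth_ok & (counts["A"].to_numpy() >= a_cutoff)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(detected, counts["A"].to_numpy() / counts["D"].to_numpy(), 0.0)
    freqs = pd.DataFrame(
        {
            "site_id": counts["site_id"].to_numpy(),
            "host_id": counts["host_id"].to_numpy(),
            "f": f,
            "D": counts["D"].to_numpy(),
            "depth_ok": depth_ok,
        }
    )
    freqs.attrs["d_min"] = d_min
    freqs.attrs["a_cutoff"] = a_cutoff
    return freqs


def _flip_sites(values: pd.Series, site_ids: pd.Series) -> np.ndarray:
    means = values.groupby(site_ids, sort=False).transform("mean").to_numpy()
    return means > 0.5


def polarize(freqs: pd.DataFrame) -> pd.DataFrame:
    """Polarize a frequency table onto the across-host minor allele.

    Sites whose across-host mean frequency exceeds 0.5 are flipped
    f -> 1 - f. A mean of exactly 0.5 is left unflipped (deterministic
    tie-break). Idempotent: a flipped site's mean is below 0.5 afterward.
    """
    out = freqs.copy()
    flip = _flip_sites(out["f"], out["site_id"])
    out.loc[flip, "f"] = 1.0 - out.loc[flip, "f"]
    out.attrs = dict(freqs.attrs)
    return out


def polarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Polarize a count table: sites with mean A/D > 0.5 get A -> D - A."""
    out = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(out["D"].to_numpy() > 0, out["A"].to_numpy() / out["D"].to_numpy(), 0.0)
    flip = _flip_sites(pd.Series(f), out["site_id"])
    out.loc[flip, "A"] = out.loc[flip, "D"] - out.loc[flip, "A"]
    return out
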