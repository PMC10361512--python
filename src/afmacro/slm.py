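"""Mechanistic models of allele-frequency dynamics across hosts.

Two families of Langevin equations are housed here, both of which admit a
gamma stationary distribution of the frequency ``f`` of an allele:

* the Stochastic Logistic Model (SLM) of the ecological dynamics of the
  strain carrying the allele — self-limiting growth toward a carrying
  capacity ``K`` plus multiplicative environmental noise with coefficient
  of variation ``sigma``;
* linearized single-locus models of evolution in the low-frequency regime
  (``f << 1``), where forward mutation, selection and genetic drift
  balance into a gamma under either purifying (``s < 0``) or positive
  (``s > 0``) selection.

Analytic stationary solutions are paired with Euler–Maruyama simulators
(Itô convention) that serve as numerical oracles for them.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GammaParams",
    "SLMParams",
    "EvoParams",
    "SdePath",
    "slm_stationary",
    "gamma_from_moments",
    "moments_of",
    "simulate_slm",
    "sample_slm_stationary",
    "f_max",
    "evo_gamma_params",
    "simulate_evo_langevin",
]


@dataclasses.dataclass(frozen=True)
class GammaParams:
    """Gamma distribution in the shape/rate parameterization."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError(
                f"gamma shape and rate must be positive, got shape={self.shape}, rate={self.rate}"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    @property
    def cv2(self) -> float:
        """Squared coefficient of variation, 1/shape."""
        return 1.0 / self.shape

    @property
    def beta(self) -> float:
        """Squared inverse CV — identical to the shape parameter."""
        return self.shape

    def scipy(self):
        from scipy import stats

        return stats.gamma(a=self.shape, scale=1.0 / self.rate)


@dataclasses.dataclass(frozen=True)
class SLMParams:
    """Stochastic Logistic Model parameters.

    tau
        Intrinsic growth timescale of the strain (1/tau is the growth rate).
    K
        Carrying capacity as a relative frequency, 0 < K < 1.
    sigma
        Coefficient of variation of growth-rate fluctuations. A stationary
        gamma exists only for sigma < 2 (shape 2/sigma - 1 > 0).
    """

    tau: float
    K: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not 0 < self.K < 1:
            raise ValueError(f"K must lie in (0, 1), got {self.K}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.sigma >= 2:
            raise ValueError(
                f"no stationary gamma: sigma={self.sigma} >= 2 makes the shape 2/sigma - 1 nonpositive"
            )


@dataclasses.dataclass(frozen=True)
class EvoParams:
    """Linearized single-locus model parameters.

    N is the population size, mu/upsilon the forward/backward mutation
    rates per generation, s the selection coefficient whose sign selects
    the regime, and t the elapsed time in generations (required for the
    s > 0 regime, where it sets the maximum reachable frequency).
    """

    N: float
    mu: float
    s: float
    upsilon: float = 0.0
    t: float | None = None

    def __post_init__(self) -> None:
        if not self.N >= 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.mu < 0 or self.upsilon < 0:
            raise ValueError("mutation rates must be nonnegative")
        if self.s > 0:
            if self.t is None or not self.t > 0:
                raise ValueError("the s > 0 regime requires an elapsed time t > 0")


@dataclasses.dataclass
class SdePath:
    """Result of an Euler–Maruyama integration.

    ``f`` has shape (n_chains, n_kept); boundary-event counters record how
    often the scheme stepped below 0 (reflected) or above 1 (capped).
    """

    f: np.ndarray
    dt: float
    n_steps: int
    n_reflected: int = 0
    n_capped: int = 0

    @property
    def samples(self) -> np.ndarray:
        return self.f.ravel()

    @property
    def boundary_fraction(self) -> float:
        total = self.n_steps * self.f.shape[0]
        return (self.n_reflected + self.n_capped) / total if total else 0.0


def slm_stationary(params: SLMParams) -> GammaParams:
    """Stationary gamma of the SLM: Gamma(2/sigma - 1, 2/(K sigma))."""
    if params.sigma >= 2:
        raise ValueError("no stationary gamma for sigma >= 2")
    shape = 2.0 / params.sigma - 1.0
    rate = 2.0 / (params.K * params.sigma)
    return GammaParams(shape=shape, rate=rate)


def gamma_from_moments(fbar: float, beta: float) -> GammaParams:
    """Gamma parameterized by its mean and squared inverse CV.

    Returns Gamma(shape=beta, rate=beta/fbar), so that the mean is ``fbar``
    and the squared inverse coefficient of variation is ``beta``.
    """
    if not fbar > 0:
        raise ValueError(f"fbar must be positive, got {fbar}")
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return GammaParams(shape=beta, rate=beta / fbar)


def moments_of(params: GammaParams) -> tuple[float, float]:
    """(mean, squared inverse CV) of a gamma — the inverse of gamma_from_moments."""
    return params.mean, params.shape


def simulate_slm(
    params: SLMParams,
    f0: float | None = None,
    dt: float | None = None,
    n_steps: int = 10_000,
    burn_in: int = 0,
    seed: int | np.random.Generator | None = None,
    n_chains: int = 1,
    thin: int = 1,
    clip_upper: float | None = None,
) -> SdePath:
    """Euler–Maruyama integration of the SLM (Itô convention).

    df = (f/tau) (1 - f/K) dt + sqrt(sigma/tau) f dW

    Steps producing f < 0 are reflected to |f|, with a count kept on the
    returned path. The process is left unbounded above by default so that
    its stationary law is exactly the analytic gamma (whose support is
    unbounded; excursions above 1 are transients of the self-limiting
    drift); pass ``clip_upper=1.0`` to cap trajectories at the frequency
    bound instead, which truncates the stationary tail. Samples are kept
    after ``burn_in`` steps, every ``thin`` steps.
    """
    if f0 is None:
        f0 = params.K
    if not 0 < f0 < 1:
        raise ValueError(f"f0 must lie in (0, 1), got {f0}")
    if dt is None:
        dt = params.tau / 100.0
    if dt >= params.tau:
        warnings.warn(
            f"dt={dt} is not small relative to tau={params.tau}; the scheme may be inaccurate",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    f = np.full(n_chains, float(f0))
    growth = dt / params.tau
    noise = math.sqrt(params.sigma / params.tau) * math.sqrt(dt)
    kept: list[np.ndarray] = []
    n_reflected = 0
    n_capped = 0
    for step in range(1, n_steps + 1):
        dw = rng.standard_normal(n_chains)
        f = f + growth * f * (1.0 - f / params.K) + noise * f * dw
        neg = f < 0
        if neg.any():
            n_reflected += int(neg.sum())
            np.abs(f, out=f)
        if clip_upper is not None:
            over = f > clip_upper
            if over.any():
                n_capped += int(over.sum())
                f[over] = clip_upper
        if step > burn_in and (step - burn_in) % thin == 0:
            kept.append(f.copy())
    samples = np.stack(kept, axis=1) if kept else np.empty((n_chains, 0))
    if n_reflected or n_capped:
        logger.debug(
            "SLM boundary events: %d reflections, %d caps over %d chain-steps",
            n_reflected,
            n_capped,
            n_steps * n_chains,
        )
    return SdePath(f=samples, dt=dt, n_steps=n_steps, n_reflected=n_reflected, n_capped=n_capped)


def sample_slm_stationary(
    params: SLMParams,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    dt: float | None = None,
    burn_in_time: float | None = None,
    spacing_time: float | None = None,
) -> SdePath:
    """Draw approximately stationary SLM samples with many parallel chains.

    Chains start at K, run for ``burn_in_time`` (default 50 tau), then emit
    samples spaced ``spacing_time`` (default tau, about one autocorrelation
    time) apart until ``n_samples`` values are collected. The default step
    here is tau/400, finer than the general-purpose simulator's, so that
    discretization bias in the stationary moments stays well below 1%.
    """
    if dt is None:
        dt = params.tau / 400.0
    if burn_in_time is None:
        burn_in_time = 50.0 * params.tau
    if spacing_time is None:
        spacing_time = params.tau
    thin = max(1, round(spacing_time / dt))
    burn_in = round(burn_in_time / dt)
    n_chains = min(2000, max(1, math.ceil(n_samples / 100)))
    per_chain = math.ceil(n_samples / n_chains)
    n_steps = burn_in + per_chain * thin
    path = simulate_slm(
        params,
        f0=params.K,
        dt=dt,
        n_steps=n_steps,
        burn_in=burn_in,
        seed=seed,
        n_chains=n_chains,
        thin=thin,
    )
    path.f = path.f[:, :per_chain]
    return path


def f_max(s: float, t: float, N: float) -> float:
    """Maximum frequency reachable by a sweeping allele: (e^{st} - 1)/(2Ns)."""
    if not s > 0:
        raise ValueError(f"s must be positive, got {s}")
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    if not N >= 1:
        raise ValueError(f"N must be >= 1, got {N}")
    value = math.expm1(s * t) / (2.0 * N * s)
    if value > 1:
        warnings.warn(
            f"f_max={value:.3g} exceeds 1; the model has left the f << 1 regime", stacklevel=2
        )
    return value


def evo_gamma_params(params: EvoParams) -> GammaParams:
    """Gamma stationary forms of mutation–selection balance.

    Purifying selection (s < 0): Gamma(2 N mu, 2 N |s|), mean mu/|s|.
    Positive selection (s > 0): Gamma(2 N mu, 1/f_max), mean 2 N mu f_max.
    """
    if params.s == 0:
        raise ValueError("neutral case (s = 0) has no gamma stationary form here")
    shape = 2.0 * params.N * params.mu
    if params.s < 0:
        rate = 2.0 * params.N * abs(params.s)
    else:
        rate = 1.0 / f_max(params.s, params.t, params.N)
    return GammaParams(shape=shape, rate=rate)


def simulate_evo_langevin(
    params: EvoParams,
    regime: str | None = None,
    f0: float = 1e-4,
    dt: float | None = None,
    n_steps: int = 10_000,
    burn_in: int = 0,
    seed: int | np.random.Generator | None = None,
    n_chains: int = 1,
    thin: int = 1,
) -> SdePath:
    """Euler–Maruyama path of the linearized single-locus Langevin equation.

    df = (-|s| f + mu) dt + sqrt(f/N) dW   (regime "s_neg")
    df = (+|s| f + mu) dt + sqrt(f/N) dW   (regime "s_pos")

    The regime defaults to the sign of ``params.s``. A warning is emitted if
    any trajectory reaches f >= 0.5, outside the f << 1 regime the
    linearization assumes.
    """
    if regime is None:
        regime = "s_neg" if params.s < 0 else "s_pos"
    if regime not in ("s_neg", "s_pos"):
        raise ValueError(f"regime must be 's_neg' or 's_pos', got {regime!r}")
    if not 0 <= f0 < 1:
        raise ValueError(f"f0 must lie in [0, 1), got {f0}")
    drift_sign = -1.0 if regime == "s_neg" else 1.0
    s_mag = abs(params.s)
    if dt is None:
        # resolve the selective timescale 1/|s| (or an arbitrary unit if s=0)
        dt = 0.01 / s_mag if s_mag > 0 else 1.0
    rng = np.random.default_rng(seed)

    f = np.full(n_chains, float(f0))
    sqrt_dt = math.sqrt(dt)
    kept: list[np.ndarray] = []
    n_reflected = 0
    hit_half = False
    for step in range(1, n_steps + 1):
        dw = rng.standard_normal(n_chains)
        f = f + (drift_sign * s_mag * f + params.mu) * dt + np.sqrt(f / params.N) * sqrt_dt * dw
        neg = f < 0
        if neg.any():
            n_reflected += int(neg.sum())
            np.abs(f, out=f)
        if not hit_half and (f >= 0.5).any():
            hit_half = True
        if step > burn_in and (step - burn_in) % thin == 0:
            kept.append(f.copy())
    if hit_half:
        warnings.warn("trajectory reached f >= 0.5, outside the f << 1 regime", stacklevel=2)
    samples = np.stack(kept, axis=1) if kept else np.empty((n_chains, 0))
    return SdePath(f=samples, dt=dt, n_steps=n_steps, n_reflected=n_reflected)
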