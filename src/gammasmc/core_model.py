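"""Core SMC mathematics for gamma-projected TMRCA inference.

The pairwise sequentially Markovian coalescent (SMC) treats the coalescence
time (TMRCA) of two homologous sequences as a Markov chain along the genome:
at each base pair a recombination may occur, resampling the coalescence time,
and each site emits a heterozygous/homozygous observation whose probability
depends on the current TMRCA.  This module implements the continuous-state
building blocks: the per-base transition density, the compound distribution
obtained by pushing a gamma-distributed state through one transition, its
projection back onto the gamma family, the conjugate Poisson-gamma emission
update, the forward/backward combination rule, and unit conversions.

Time is measured in coalescent units throughout: one unit equals 2*Ne
generations, so the equilibrium (prior) TMRCA distribution is Exp(1), i.e.
``GammaState(1, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Tuple

import numpy as np

__all__ = [
    "GammaState",
    "ModelParams",
    "Observation",
    "STATIONARY_STATE",
    "smc_transition_density",
    "transition_atom_weight",
    "compound_moments",
    "gamma_project",
    "emission_update",
    "combine_forward_backward",
    "to_generations",
]

LN10 = math.log(10.0)


class Observation(IntEnum):
    """Per-site observation class for a haplotype pair."""

    HOM = 0
    HET = 1
    MISSING = 2


@dataclass(frozen=True)
class GammaState:
    """A gamma-distributed TMRCA density Gamma(alpha, beta).

    ``alpha`` is the shape and ``beta`` the rate (per coalescent time unit).
    The state can equivalently be addressed by its log10 mean ``l_mu`` and
    log10 coefficient of variation ``l_cv``:

        mu = alpha / beta,   cv = 1 / sqrt(alpha)

    so ``alpha = cv**-2`` and ``beta = alpha / mu``.  The flow-field grid is
    laid out in (l_mu, l_cv) coordinates.
    """

    alpha: float
    beta: float
    # memoized log coordinates; keeps the (alpha, beta) <-> (l_mu, l_cv)
    # round trip exact for states built from grid coordinates
    _l_mu: float | None = field(default=None, compare=False, repr=False)
    _l_cv: float | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"gamma parameters must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def variance(self) -> float:
        return self.alpha / self.beta**2

    @property
    def cv(self) -> float:
        return 1.0 / math.sqrt(self.alpha)

    @property
    def l_mu(self) -> float:
        # np.log10 rather than math.log10: keeps scalar decoding bit-identical
        # to the vectorized cache builder (libm and numpy differ by ~1 ulp)
        if self._l_mu is None:
            object.__setattr__(self, "_l_mu", float(np.log10(self.mean)))
        return self._l_mu

    @property
    def l_cv(self) -> float:
        if self._l_cv is None:
            object.__setattr__(self, "_l_cv", float(np.log10(self.cv)))
        return self._l_cv

    @classmethod
    def from_log_coords(cls, l_mu: float, l_cv: float) -> "GammaState":
        """Build a state from (log10 mean, log10 CV) grid coordinates."""
        alpha = float(np.power(10.0, -2.0 * l_cv))
        beta = alpha / float(np.power(10.0, l_mu))
        return cls(alpha, beta, l_mu, l_cv)

    def log_coords(self) -> Tuple[float, float]:
        return (self.l_mu, self.l_cv)


#: The stationary prior Exp(1) = Gamma(1, 1); (l_mu, l_cv) = (0, 0).
STATIONARY_STATE = GammaState(1.0, 1.0)


@dataclass
class ModelParams:
    """Population-genetic rates and unit conversions.

    Either the scaled rates (``theta`` = 4*Ne*mu per bp, ``rho`` = 4*Ne*r per
    bp) are given directly, or they are derived from the unscaled per-bp
    per-generation rates ``mu_rate``/``r_rate`` together with the diploid
    effective population size ``Ne``.
    """

    mu_rate: float | None = None
    r_rate: float | None = None
    Ne: float | None = None
    theta: float | None = None
    rho: float | None = None
    generation_time: float = 30.0

    def __post_init__(self) -> None:
        if self.theta is None and self.mu_rate is not None and self.Ne is not None:
            self.theta = 4.0 * self.Ne * self.mu_rate
        if self.rho is None and self.r_rate is not None and self.Ne is not None:
            self.rho = 4.0 * self.Ne * self.r_rate
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.rho is not None and self.rho < 0:
            raise ValueError("rho must be non-negative")

    def require_rates(self) -> Tuple[float, float]:
        if self.theta is None or self.rho is None:
            raise ValueError("theta and rho must be set (directly or via mu_rate/r_rate/Ne)")
        return self.theta, self.rho


def transition_atom_weight(s: float, rho: float) -> float:
    """Probability of *no* recombination over one base pair given TMRCA ``s``.

    This is the weight of the atom at t = s in the transition density.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    return math.exp(-rho * s)


def smc_transition_density(t, s: float, rho: float):
    """Continuous part of the per-base SMC transition density p(t | s).

    Conditional on a recombination (probability 1 - e^{-rho*s}), the
    recombination point is uniform on (0, s) and the detached lineage
    re-coalesces at rate 1, giving the conditional kernel

        q(t | s) = (1/s) * (e^{min(s, t)} - 1) * e^{-t}.

    Returns ``(1 - e^{-rho*s}) * q(t | s)``; the atom of weight e^{-rho*s}
    at t = s is exposed separately by :func:`transition_atom_weight`.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    if s <= 0:
        raise ValueError("s must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    q = (np.expm1(np.minimum(s, t))) * np.exp(-t) / s
    out = -math.expm1(-rho * s) * q
    return out if out.ndim else float(out)


def compound_moments(state: GammaState, rho: float) -> Tuple[float, float]:
    """Mean and variance of the one-step compound distribution.

    The compound density is p_{alpha,beta}(t) = int p(t|s) f_{alpha,beta}(s) ds.
    Conditional moments of the transition are

        E[t | s]   = e^{-rho s} s   + (1 - e^{-rho s}) (s/2 + 1)
        E[t^2 | s] = e^{-rho s} s^2 + (1 - e^{-rho s}) (s^2/3 + s + 2)

    and terms of the form e^{-rho s} f_{alpha,beta}(s) integrate via the
    tilting identity e^{-rho s} f_{alpha,beta}(s) =
    (beta/(beta+rho))^alpha f_{alpha,beta+rho}(s), giving closed forms.
    """
    a, b = state.alpha, state.beta
    if rho < 0:
        raise ValueError("rho must be non-negative")
    # log-space for the tilting constant; a*log1p(rho/b) can be huge.
    # The constants are grouped through 1 - c = -expm1(log c) so that the
    # rho -> 0 limit is exact and concentrated low-mean states do not lose
    # their (tiny) variance to cancellation.
    log_c = -a * math.log1p(rho / b)
    c = math.exp(log_c)
    one_minus_c = -math.expm1(log_c)
    m1 = a / b
    m1r = a / (b + rho)
    m2 = a * (a + 1.0) / (b * b)
    m2r = a * (a + 1.0) / ((b + rho) * (b + rho))
    mean = 0.5 * (m1 + c * m1r) + one_minus_c
    raw2 = (m2 + 2.0 * c * m2r) / 3.0 + (m1 - c * m1r) + 2.0 * one_minus_c
    var = raw2 - mean * mean
    return mean, var


_EPS_VAR = np.finfo(float).tiny


def gamma_project(state: GammaState, rho: float, method: str = "moment") -> GammaState:
    """Project the one-step compound distribution back onto the gamma family.

    ``method="moment"`` (default) matches mean and variance:
    alpha' = mean^2/var, beta' = mean/var.  ``method="kl"`` minimises
    KL(compound || gamma) by matching E[T] and E[log T] (quadrature; intended
    for sensitivity checks, not the hot path).
    """
    if method == "moment":
        mean, var = compound_moments(state, rho)
        if var <= 0:
            import warnings

            warnings.warn("degenerate compound variance; clamping", RuntimeWarning)
            var = _EPS_VAR
        return GammaState(mean * mean / var, mean / var)
    if method == "kl":
        return _kl_project(state, rho)
    raise ValueError(f"unknown projection method {method!r}")


def _kl_project(state: GammaState, rho: float) -> GammaState:
    """Match E[T] and E[log T] of the compound distribution (quadrature)."""
    from scipy import integrate, optimize, special, stats

    a, b = state.alpha, state.beta

    def compound_pdf(t):
        # integrate the continuous part over s ~ Gamma(a, b), plus atom at t=s
        def inner(s):
            return smc_transition_density(t, s, rho) * stats.gamma.pdf(s, a, scale=1.0 / b)

        val, _ = integrate.quad(inner, 0, np.inf, limit=200)
        return val + math.exp(-rho * t) * stats.gamma.pdf(t, a, scale=1.0 / b)

    mean, _ = integrate.quad(lambda t: t * compound_pdf(t), 0, np.inf, limit=200)
    elog, _ = integrate.quad(lambda t: math.log(t) * compound_pdf(t), 0, np.inf, limit=200)
    # solve psi(alpha) - log(alpha) = elog - log(mean)
    target = elog - math.log(mean)

    def f(log_alpha):
        al = math.exp(log_alpha)
        return special.digamma(al) - math.log(al) - target

    log_alpha = optimize.brentq(f, -10, 25)
    alpha = math.exp(log_alpha)
    return GammaState(alpha, alpha / mean)


def emission_update(state: GammaState, y, theta: float) -> GammaState:
    """Poisson-gamma conjugate update for one observed site.

    A het site (y=1) contributes likelihood proportional to t*e^{-theta t},
    a hom site (y=0) to e^{-theta t}; against Gamma(alpha, beta) this yields
    Gamma(alpha + y, beta + theta).  Missing sites carry no likelihood and
    must not be passed here.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    y = int(y)
    if y not in (0, 1):
        raise ValueError("emission_update requires y in {0, 1}; missing sites skip emission")
    if y == 0:
        # alpha (hence CV) unchanged: carry over the memoized l_cv
        return GammaState(state.alpha, state.beta + theta, None, state._l_cv)
    return GammaState(state.alpha + 1.0, state.beta + theta)


def combine_forward_backward(fwd: GammaState, bwd: GammaState) -> GammaState:
    """Combine forward and backward gamma densities into the full posterior.

    The product of the two densities divided by the Exp(1) prior is again
    gamma: Gamma(alpha + alpha' - 1, beta + beta' - 1).
    """
    a = fwd.alpha + bwd.alpha - 1.0
    b = fwd.beta + bwd.beta - 1.0
    if a <= 0 or b <= 0:
        raise ValueError(
            f"combined gamma parameters non-positive: alpha={a}, beta={b} "
            f"(fwd={fwd}, bwd={bwd})"
        )
    return GammaState(a, b)


def to_generations(state: GammaState, params: ModelParams) -> Tuple[float, float]:
    """Posterior mean TMRCA in generations and years.

    One coalescent time unit equals 2*Ne generations; years use
    ``params.generation_time`` (default 30).
    """
    if params.Ne is None:
        raise ValueError("Ne must be set to convert coalescent units to generations")
    gens = state.mean * 2.0 * params.Ne
    return gens, gens * params.generation_time
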