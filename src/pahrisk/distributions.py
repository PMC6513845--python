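"""Distribution specifications and seeded sampling.

The Monte-Carlo risk simulations draw from three families only: lognormal
(TEQ and the cancer slope factor), normal (exposure time; children's body
weight), uniform (the truncation-multiplier of the 2-D uncertainty
analysis).  Specs are small frozen dataclasses with closed-form moments and
quantiles; sampling is reproducible from a master seed through named
substreams so that adding one variable to a simulation never perturbs
another's draws.

Truncation is honoured by rejection resampling — the truncated distribution
is the renormalized parent, not a clipped one with atoms at the bounds.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "LognormalSpec",
    "NormalSpec",
    "UniformSpec",
    "lognormal_from_moments",
    "lognormal_from_gm_gsd",
    "fit_lognormal",
    "sample",
    "quantile",
    "lhs_uniform",
    "substream",
    "STREAM_IDS",
]

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal on the natural scale: log(X) ~ N(mu, sigma^2), optionally
    truncated above at ``upper_bound`` (natural scale)."""

    mu: float
    sigma: float
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.upper_bound is not None and self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")

    def _require_untruncated(self, what: str) -> None:
        if self.upper_bound is not None:
            raise NotImplementedError(
                f"closed-form {what} is only defined for the untruncated spec"
            )

    @property
    def mean(self) -> float:
        self._require_untruncated("mean")
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def sd(self) -> float:
        self._require_untruncated("sd")
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    @property
    def gm(self) -> float:
        return math.exp(self.mu)

    @property
    def gsd(self) -> float:
        return math.exp(self.sigma)

    def truncated(self, k: float) -> "LognormalSpec":
        """Truncate at exp(mu + k*sigma): the natural-scale bound k
        log-standard-deviations above the log-mean (the 'max' parameter of
        the 2-D uncertainty analysis)."""
        return LognormalSpec(self.mu, self.sigma, math.exp(self.mu + k * self.sigma))


@dataclass(frozen=True)
class NormalSpec:
    """Normal with optional truncation; exposure time defaults to the
    physical [0, 24] hours/day support at construction sites, body weight to
    (0, inf)."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be strictly below upper bound")
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise ValueError("degenerate spec: mean outside truncation bounds")


@dataclass(frozen=True)
class UniformSpec:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError("lo must be <= hi")

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)


Spec = Union[LognormalSpec, NormalSpec, UniformSpec]


# ---------------------------------------------------------------------------
# Parameterization conversions
# ---------------------------------------------------------------------------

def lognormal_from_moments(arith_mean: float, arith_sd: float) -> LognormalSpec:
    """Moment-match a lognormal to an arithmetic mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2, the standard
    identities; the returned spec's analytic mean/sd reproduce the inputs.
    """
    if arith_mean <= 0:
        raise ValueError("arithmetic mean must be positive")
    if arith_sd < 0:
        raise ValueError("arithmetic sd must be >= 0")
    sigma2 = math.log1p((arith_sd / arith_mean) ** 2)
    return LognormalSpec(mu=math.log(arith_mean) - sigma2 / 2.0, sigma=math.sqrt(sigma2))


def lognormal_from_gm_gsd(gm: float, gsd: float) -> LognormalSpec:
    """Parameterize from geometric mean and geometric SD: mu = ln GM,
    sigma = ln GSD."""
    if gm <= 0:
        raise ValueError("geometric mean must be positive")
    if gsd < 1:
        raise ValueError("geometric standard deviation must be >= 1")
    return LognormalSpec(mu=math.log(gm), sigma=math.log(gsd))


def fit_lognormal(x, method: str = "mle") -> LognormalSpec:
    """Fit a lognormal to positive data.

    method='mle': log-scale maximum likelihood (mu = mean of logs, sigma =
    sample SD of logs, n-1 convention) — used when raw series are available.
    method='moments': moment matching on the arithmetic mean/SD — used when
    only summary statistics exist.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(x <= 0):
        raise ValueError("lognormal fit requires strictly positive data")
    if method == "mle":
        logs = np.log(x)
        return LognormalSpec(mu=float(logs.mean()), sigma=float(logs.std(ddof=1)))
    if method == "moments":
        return lognormal_from_moments(float(x.mean()), float(x.std(ddof=1)))
    raise ValueError(f"unknown fit method: {method!r}")


# ---------------------------------------------------------------------------
# Seeded substreams
# ---------------------------------------------------------------------------

#: Fixed stream indices per simulation variable.  Because each variable owns
#: its index, adding a stochastic variable to a model never changes the draws
#: of the others.
STREAM_IDS: dict[str, int] = {
    "teq": 0,
    "et": 1,
    "csf": 2,
    "bw": 3,
    "outer": 4,
    "survey_et": 5,
    "survey_bw": 6,
    "concentration": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one master seed."""
    sid = STREAM_IDS.get(name)
    if sid is None:
        sid = 1024 + zlib.crc32(name.encode()) % 2**20
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(sid,)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sampling and quantiles
# ---------------------------------------------------------------------------

def _rejection(draw, accept, n: int) -> np.ndarray:
    out = draw(n)
    bad = ~accept(out)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise RuntimeError("rejection resampling failed to converge")
        out[bad] = draw(int(bad.sum()))
        bad = ~accept(out)
    return out


def sample(spec: Spec, n: int, seed) -> np.ndarray:
    """Draw ``n`` values from a spec; ``seed`` is an int or a Generator.

    Truncated specs never emit values outside their bounds (rejection
    resampling).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if isinstance(spec, LognormalSpec):
        if spec.sigma == 0:
            return np.full(n, math.exp(spec.mu))
        draw = lambda m: np.exp(rng.normal(spec.mu, spec.sigma, m))
        if spec.upper_bound is None:
            return draw(n)
        ub = spec.upper_bound
        return _rejection(draw, lambda x: x <= ub, n)
    if isinstance(spec, NormalSpec):
        if spec.sd == 0:
            return np.full(n, spec.mean)
        draw = lambda m: rng.normal(spec.mean, spec.sd, m)
        if math.isinf(spec.lower) and math.isinf(spec.upper):
            return draw(n)
        lo, hi = spec.lower, spec.upper
        return _rejection(draw, lambda x: (x >= lo) & (x <= hi), n)
    if isinstance(spec, UniformSpec):
        return rng.uniform(spec.lo, spec.hi, n)
    raise TypeError(f"unsupported spec type: {type(spec)}")


def quantile(spec: Spec, p) -> np.ndarray | float:
    """Quantile function; truncated specs via renormalized CDF inversion."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if isinstance(spec, LognormalSpec):
        if spec.sigma == 0:
            q = np.full_like(p_arr, math.exp(spec.mu))
        elif spec.upper_bound is None:
            q = np.exp(spec.mu + spec.sigma * stats.norm.ppf(p_arr))
        else:
            zmax = (math.log(spec.upper_bound) - spec.mu) / spec.sigma
            q = np.exp(spec.mu + spec.sigma * stats.norm.ppf(p_arr * stats.norm.cdf(zmax)))
    elif isinstance(spec, NormalSpec):
        if spec.sd == 0:
            q = np.full_like(p_arr, spec.mean)
        elif math.isinf(spec.lower) and math.isinf(spec.upper):
            q = stats.norm.ppf(p_arr, loc=spec.mean, scale=spec.sd)
        else:
            a = (spec.lower - spec.mean) / spec.sd
            b = (spec.upper - spec.mean) / spec.sd
            q = stats.truncnorm.ppf(p_arr, a, b, loc=spec.mean, scale=spec.sd)
    elif isinstance(spec, UniformSpec):
        q = spec.lo + p_arr * (spec.hi - spec.lo)
    else:
        raise TypeError(f"unsupported spec type: {type(spec)}")
    return float(q) if np.isscalar(p) else q


def lhs_uniform(spec: UniformSpec, n: int, seed) -> np.ndarray:
    """Latin hypercube draws from a uniform: exactly one draw in each of the
    ``n`` equal-width strata of [lo, hi], in randomized order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    strata = rng.permutation(n)
    u = rng.uniform(size=n)
    return spec.lo + (strata + u) / n * (spec.hi - spec.lo)
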