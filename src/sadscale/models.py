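"""Candidate species-abundance distributions.

All models are continuous densities supported on [1, x_max] (x_max possibly
infinite); counts being integers, samplers draw by inversion of the continuous
CDF and floor the result (clamped to >= 1), which preserves the tail exponent.
For a floored draw K = floor(X), P(K >= k) = P(X >= k) at every integer k, so
the discretised sampler and the continuous survival function can be compared
exactly.

Families
--------
- ``PowerLawModel``            P(x) ∝ x^(−1−α), x >= x_min
- ``TruncatedPowerLawModel``   P(x) ∝ x^(−1−β) exp(−λx)
- ``LogNormalModel``           lognormal renormalised to [1, ∞)
- ``WeibullModel``             Weibull renormalised to [1, ∞)
- ``DoublePowerLawModel``      head exponent δ below x_c, tail exponent α above,
                               density continuous at x_c
- ``ShiftedPowerLawModel``     P(x) ∝ (x + x0)^(−1−α) on [1, x_max]
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import DivergingMeanError, DomainError, NotNormalizableError
from .otu_io import AbundanceVector
from .utils import as_rng

__all__ = [
    "SADModel",
    "PowerLawModel",
    "TruncatedPowerLawModel",
    "LogNormalModel",
    "WeibullModel",
    "DoublePowerLawModel",
    "ShiftedPowerLawModel",
    "double_pl_constants",
    "shifted_pl_constant",
    "mean_abundance",
    "sample",
    "sample_to_reads",
    "model_from_dict",
]


def upper_gamma(a: float, x) -> np.ndarray:
    """Upper incomplete gamma Γ(a, x) for any real a (x > 0).

    scipy's regularised gammaincc requires a > 0; negative orders are reached
    through the recurrence Γ(a, x) = (Γ(a+1, x) − x^a e^(−x)) / a.
    """
    x = np.asarray(x, dtype=float)
    a = float(a)
    if a > 0:
        return special.gammaincc(a, x) * special.gamma(a)
    if a == 0.0:
        return special.exp1(x)
    return (upper_gamma(a + 1.0, x) - x**a * np.exp(-x)) / a


class SADModel(abc.ABC):
    """Abstract continuous abundance distribution on [x_min, x_max]."""

    family: str = ""
    x_min: float = 1.0
    x_max: float = np.inf

    @abc.abstractmethod
    def params(self) -> dict:
        ...

    @abc.abstractmethod
    def logpdf(self, x) -> np.ndarray:
        ...

    @abc.abstractmethod
    def cdf(self, x) -> np.ndarray:
        ...

    @abc.abstractmethod
    def ppf(self, q) -> np.ndarray:
        ...

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def sf(self, x) -> np.ndarray:
        return 1.0 - self.cdf(x)

    def mean(self) -> float:
        """Mean abundance <x>; raises DivergingMeanError when infinite."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.params())

    def sample(self, n: int, seed=None, discretize: bool = True) -> np.ndarray:
        """Inverse-CDF draws; floored to integers >= 1 when ``discretize``."""
        if n < 1:
            raise DomainError("n must be >= 1")
        rng = as_rng(seed)
        x = self.ppf(rng.random(int(n)))
        if discretize:
            x = np.maximum(np.floor(x), 1.0)
            if np.isfinite(self.x_max):
                x = np.minimum(x, np.floor(self.x_max))
            # int64 guard: for very heavy tails (alpha << 1) the inverse CDF can
            # produce astronomically large values; capping at 2^62 leaves any
            # realistic subsampling computation unchanged.
            return np.minimum(x, 2.0**62).astype(np.int64)
        return x

    def to_dict(self) -> dict:
        return {"family": self.family, "params": self.params()}


def sample(model: SADModel, n: int, seed=None, discretize: bool = True) -> np.ndarray:
    """Draw ``n`` abundances from ``model`` (module-level convenience)."""
    return model.sample(n, seed=seed, discretize=discretize)


def sample_to_reads(model: SADModel, n_target: int, seed=None) -> AbundanceVector:
    """Draw abundances until the cumulative read count reaches ``n_target``.

    The final, overshooting draw is kept.  Returns an AbundanceVector with
    synthetic OTU ids; its S is the number of draws needed.
    """
    if n_target < 1:
        raise DomainError("n_target must be >= 1")
    rng = as_rng(seed)
    chunks: list[np.ndarray] = []
    total = 0
    chunk = 1024
    try:
        m = model.mean()
        chunk = int(np.clip(1.2 * n_target / m, 64, 2_000_000))
    except (DivergingMeanError, NotImplementedError):
        pass
    while total < n_target:
        draw = model.sample(chunk, seed=rng)
        csum = np.cumsum(draw)
        if total + csum[-1] >= n_target:
            stop = int(np.searchsorted(csum, n_target - total))
            draw = draw[: stop + 1]
            csum = csum[: stop + 1]
        chunks.append(draw)
        total += int(csum[-1])
        chunk = min(max(chunk, 1024) * 2, 4_000_000)
    return AbundanceVector.from_counts(np.concatenate(chunks))


# ---------------------------------------------------------------------------
# pure power law


@dataclass(frozen=True)
class PowerLawModel(SADModel):
    """P(x) = α x_min^α x^(−1−α) on [x_min, ∞)."""

    alpha: float
    x_min: float = 1.0
    family: str = field(default="power_law", init=False)

    def __post_init__(self):
        if self.alpha <= 0:
            raise NotNormalizableError("power law requires alpha > 0")
        if self.x_min < 1:
            raise DomainError("x_min must be >= 1")

    def params(self) -> dict:
        return {"alpha": self.alpha, "x_min": self.x_min}

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            x >= self.x_min,
            np.log(self.alpha) + self.alpha * np.log(self.x_min) - (1 + self.alpha) * np.log(x),
            -np.inf,
        )
        return out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x < self.x_min, 0.0, 1.0 - (x / self.x_min) ** (-self.alpha))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        return self.x_min * (1.0 - q) ** (-1.0 / self.alpha)

    def mean(self) -> float:
        if self.alpha <= 1:
            raise DivergingMeanError(f"mean diverges for alpha = {self.alpha} <= 1")
        return self.alpha * self.x_min / (self.alpha - 1.0)


# ---------------------------------------------------------------------------
# exponentially truncated power law


@dataclass(frozen=True)
class TruncatedPowerLawModel(SADModel):
    """P(x) = x^(−1−β) exp(−λx) / Z on [1, ∞); λ = 0 reduces to PowerLawModel(β)."""

    beta: float
    lam: float
    family: str = field(default="truncated_power_law", init=False)

    def __post_init__(self):
        if self.lam < 0:
            raise DomainError("lam must be >= 0")
        if self.lam == 0 and self.beta <= 0:
            raise NotNormalizableError("lam = 0 requires beta > 0")

    def params(self) -> dict:
        return {"beta": self.beta, "lam": self.lam}

    @property
    def _Z(self) -> float:
        return truncated_pl_norm(self.beta, self.lam)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = -np.log(self._Z) - (1 + self.beta) * np.log(x) - self.lam * x
        return np.where(x >= 1.0, out, -np.inf)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.lam == 0:
            return np.where(x < 1, 0.0, 1.0 - x ** (-self.beta))
        tail = self.lam**self.beta * upper_gamma(-self.beta, self.lam * np.maximum(x, 1.0))
        return np.where(x < 1, 0.0, 1.0 - tail / self._Z)

    def _inversion_table(self):
        if not hasattr(self, "_table"):
            # doubling search for the effective upper support, then a dense
            # log-spaced CDF table for interpolation-based inversion
            hi = 10.0
            while self.sf(hi) > 1e-13 and hi < 1e18:
                hi *= 10.0
            grid = np.geomspace(1.0, hi, 8192)
            cdf = np.maximum.accumulate(self.cdf(grid))
            object.__setattr__(self, "_table", (cdf, np.log(grid)))
        return self._table

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.lam == 0:
            return (1.0 - q) ** (-1.0 / self.beta)
        cdf, loggrid = self._inversion_table()
        return np.exp(np.interp(q, cdf, loggrid))

    def mean(self) -> float:
        if self.lam == 0:
            if self.beta <= 1:
                raise DivergingMeanError("mean diverges for beta <= 1 with lam = 0")
            return self.beta / (self.beta - 1.0)
        num = self.lam ** (self.beta - 1.0) * float(upper_gamma(1.0 - self.beta, self.lam))
        return num / self._Z


def truncated_pl_norm(beta: float, lam: float) -> float:
    """Z(β, λ) = ∫_1^∞ x^(−1−β) e^(−λx) dx = λ^β Γ(−β, λ)."""
    if lam < 0:
        raise DomainError("lam must be >= 0")
    if lam == 0:
        if beta <= 0:
            raise NotNormalizableError("beta must be > 0 when lam = 0")
        return 1.0 / beta
    return float(lam**beta * upper_gamma(-beta, lam))


# ---------------------------------------------------------------------------
# lognormal / Weibull, renormalised to [1, inf)


@dataclass(frozen=True)
class LogNormalModel(SADModel):
    """Lognormal(mu, sigma) conditioned on x >= 1."""

    mu: float
    sigma: float
    family: str = field(default="lognormal", init=False)

    def __post_init__(self):
        if not (np.isfinite(self.mu) and self.sigma > 0):
            raise DomainError("require finite mu and sigma > 0")

    def params(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma}

    @property
    def _dist(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    @property
    def _mass(self) -> float:
        # P(X >= 1) of the unconditioned lognormal = Phi(mu / sigma)
        return float(special.ndtr(self.mu / self.sigma))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x >= 1, self._dist.logpdf(x) - np.log(self._mass), -np.inf)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        f1 = 1.0 - self._mass
        return np.where(x < 1, 0.0, (self._dist.cdf(x) - f1) / self._mass)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        f1 = 1.0 - self._mass
        return self._dist.ppf(f1 + q * self._mass)

    def mean(self) -> float:
        s = self.sigma
        full = np.exp(self.mu + s**2 / 2.0) * special.ndtr((self.mu + s**2) / s)
        return float(full / self._mass)


@dataclass(frozen=True)
class WeibullModel(SADModel):
    """Weibull(shape k, scale) conditioned on x >= 1."""

    k: float
    scale: float
    family: str = field(default="weibull", init=False)

    def __post_init__(self):
        if self.k <= 0 or self.scale <= 0:
            raise DomainError("require k > 0 and scale > 0")

    def params(self) -> dict:
        return {"k": self.k, "scale": self.scale}

    @property
    def _q1(self) -> float:
        return (1.0 / self.scale) ** self.k

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        k, s = self.k, self.scale
        out = np.log(k / s) + (k - 1) * np.log(x / s) - (x / s) ** k + self._q1
        return np.where(x >= 1, out, -np.inf)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x < 1, 0.0, 1.0 - np.exp(self._q1 - (x / self.scale) ** self.k))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        return self.scale * (self._q1 - np.log1p(-q)) ** (1.0 / self.k)

    def mean(self) -> float:
        a = 1.0 + 1.0 / self.k
        partial = self.scale * special.gammaincc(a, self._q1) * special.gamma(a)
        return float(partial * np.exp(self._q1))


# ---------------------------------------------------------------------------
# double power law


def double_pl_constants(delta: float, alpha: float, x_c: float) -> tuple[float, float]:
    """Branch constants (A, B) of the continuous double power law.

    Solves the continuity condition A x_c^(−1−δ) = B x_c^(−1−α) together with
    unit total mass on [1, ∞); for δ = α this collapses to A = B = α.
    """
    if alpha <= 0:
        raise NotNormalizableError("tail requires alpha > 0")
    if x_c < 1:
        raise DomainError("x_c must be >= 1")
    xc_md = x_c ** (-delta)
    head = np.log(x_c) if abs(delta) < 1e-12 else (1.0 - xc_md) / delta
    A = 1.0 / (head + xc_md / alpha)
    B = A * x_c ** (alpha - delta)
    return float(A), float(B)


@dataclass(frozen=True)
class DoublePowerLawModel(SADModel):
    """Two power-law regimes joined continuously at x_c.

    P(x) = A x^(−1−δ) for 1 <= x <= x_c and B x^(−1−α) for x > x_c.
    """

    delta: float
    alpha: float
    x_c: float
    family: str = field(default="double_power_law", init=False)

    def __post_init__(self):
        A, B = double_pl_constants(self.delta, self.alpha, self.x_c)
        object.__setattr__(self, "_A", A)
        object.__setattr__(self, "_B", B)

    def params(self) -> dict:
        return {"delta": self.delta, "alpha": self.alpha, "x_c": self.x_c}

    @property
    def constants(self) -> tuple[float, float]:
        return self._A, self._B

    @property
    def head_mass(self) -> float:
        d, xc = self.delta, self.x_c
        head = np.log(xc) if abs(d) < 1e-12 else (1.0 - xc ** (-d)) / d
        return float(self._A * head)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        head = np.log(self._A) - (1 + self.delta) * np.log(x)
        tail = np.log(self._B) - (1 + self.alpha) * np.log(x)
        return np.where(x < 1, -np.inf, np.where(x <= self.x_c, head, tail))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        if abs(d) < 1e-12:
            head = self._A * np.log(np.maximum(x, 1.0))
        else:
            head = self._A * (1.0 - np.maximum(x, 1.0) ** (-d)) / d
        tail = 1.0 - (self._B / self.alpha) * x ** (-self.alpha)
        return np.where(x < 1, 0.0, np.where(x <= self.x_c, head, tail))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        ph = self.head_mass
        d = self.delta
        if abs(d) < 1e-12:
            head = np.exp(q / self._A)
        else:
            head = (1.0 - q * d / self._A) ** (-1.0 / d)
        tail = (self._B / (self.alpha * np.maximum(1.0 - q, 1e-300))) ** (1.0 / self.alpha)
        return np.where(q < ph, head, tail)

    def mean(self) -> float:
        if self.alpha <= 1:
            raise DivergingMeanError(f"mean diverges for tail alpha = {self.alpha} <= 1")
        d, xc = self.delta, self.x_c
        if abs(d - 1.0) < 1e-12:
            head = self._A * np.log(xc)
        else:
            head = self._A * (xc ** (1 - d) - 1.0) / (1.0 - d)
        tail = self._A * xc ** (1 - d) / (self.alpha - 1.0)
        return float(head + tail)


# ---------------------------------------------------------------------------
# shifted power law


def shifted_pl_constant(alpha: float, x0: float, x_max: float = np.inf) -> float:
    """A = α((1 + x0)^−α − (x_max + x0)^−α)^−1 for P(x) = A (x + x0)^(−1−α)."""
    if alpha <= 0:
        raise NotNormalizableError("require alpha > 0")
    if x0 < 0:
        raise DomainError("x0 must be >= 0")
    if x_max <= 1:
        raise DomainError("x_max must exceed 1")
    upper = 0.0 if np.isinf(x_max) else (x_max + x0) ** (-alpha)
    return float(alpha / ((1.0 + x0) ** (-alpha) - upper))


@dataclass(frozen=True)
class ShiftedPowerLawModel(SADModel):
    """P(x) = A (x + x0)^(−1−α) on [1, x_max]; x0 flattens the head."""

    alpha: float
    x0: float
    x_max: float = np.inf
    family: str = field(default="shifted_power_law", init=False)

    def __post_init__(self):
        object.__setattr__(self, "_A", shifted_pl_constant(self.alpha, self.x0, self.x_max))

    def params(self) -> dict:
        return {"alpha": self.alpha, "x0": self.x0, "x_max": self.x_max}

    @property
    def A(self) -> float:
        return self._A

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.log(self._A) - (1 + self.alpha) * np.log(x + self.x0)
        return np.where((x >= 1) & (x <= self.x_max), out, -np.inf)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        a, x0 = self.alpha, self.x0
        val = (self._A / a) * ((1.0 + x0) ** (-a) - (np.clip(x, 1.0, self.x_max) + x0) ** (-a))
        return np.where(x < 1, 0.0, np.minimum(val, 1.0))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        a, x0 = self.alpha, self.x0
        base = (1.0 + x0) ** (-a) - q * a / self._A
        return base ** (-1.0 / a) - x0

    def mean(self) -> float:
        a, x0, xm = self.alpha, self.x0, self.x_max
        if np.isinf(xm):
            if a <= 1:
                raise DivergingMeanError("mean diverges for alpha <= 1 with x_max = inf")
            return float(a / (a - 1.0) * (1.0 + x0) - x0)
        if abs(a - 1.0) < 1e-9:
            # log-limit of the closed form
            num = np.log((xm + x0) / (1.0 + x0))
            den = (1.0 + x0) ** (-1.0) - (xm + x0) ** (-1.0)
            return float(num / den - x0)
        num = (xm + x0) ** (1 - a) - (1.0 + x0) ** (1 - a)
        den = (1.0 + x0) ** (-a) - (xm + x0) ** (-a)
        return float(a / (1.0 - a) * num / den - x0)


def mean_abundance(model: SADModel) -> float:
    """Mean reads per OTU <x> under the model (closed form per family)."""
    return model.mean()


_FAMILIES = {
    "power_law": PowerLawModel,
    "truncated_power_law": TruncatedPowerLawModel,
    "lognormal": LogNormalModel,
    "weibull": WeibullModel,
    "double_power_law": DoublePowerLawModel,
    "shifted_power_law": ShiftedPowerLawModel,
}


def model_from_dict(d: dict) -> SADModel:
    """Inverse of :meth:`SADModel.to_dict`."""
    cls = _FAMILIES[d["family"]]
    return cls(**d["params"])
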