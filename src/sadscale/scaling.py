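"""Richness scaling theory and empirical accumulation-curve machinery.

Theory side: for a community whose number of OTUs at abundance x is
n_x = A x^(−1−α) with A = S/ζ(1+α), the reads-per-species ratio is
N/S = ζ(α)/ζ(1+α) when α > 1, while for α < 1 the continuous limit gives
N = S N_max^(1−α) / ((1−α) ζ(1+α)).  Richness therefore scales with
sampling effort as S ~ N^γ with γ = min(α, 1).

Empirical side: rarefaction proper — uniform subsampling without
replacement from the observed read pool — plus least-squares fitting of the
scaling exponent γ on log10 S vs log10 N, with a t-based confidence
interval, and an exhaustive-breakpoint piecewise variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .errors import DomainError
from .otu_io import AbundanceVector
from .utils import as_rng

__all__ = [
    "AccumulationCurve",
    "GammaFit",
    "reads_per_species",
    "richness_given_effort",
    "theoretical_gamma",
    "n_max_from_richness",
    "accumulation_curve",
    "expected_accumulation",
    "expected_richness",
    "effort_given_richness",
    "fit_gamma",
    "fit_gamma_piecewise",
    "chao1",
]


@dataclass(frozen=True)
class AccumulationCurve:
    """(reads, mean richness, sd over replicates) triples from subsampling."""

    N: np.ndarray
    S_mean: np.ndarray
    S_sd: np.ndarray
    replicates: int
    seed: object = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"N": self.N, "S_mean": self.S_mean, "S_sd": self.S_sd})


@dataclass(frozen=True)
class GammaFit:
    """Fitted scaling exponent of S ~ N^γ with a 95% confidence half-width."""

    gamma: float
    ci95: float
    n_points: int
    intercept: float = 0.0
    breakpoint: float | None = None
    gamma2: float | None = None
    ci95_2: float | None = None


# ---------------------------------------------------------------------------
# zeta-function theory


def reads_per_species(alpha: float) -> float:
    """N/S = ζ(α)/ζ(1+α) for α > 1 (each species needs finitely many reads)."""
    if alpha <= 1:
        raise DomainError(
            "reads_per_species requires alpha > 1; for alpha <= 1 the sum "
            "diverges — use richness_given_effort (continuous regime)"
        )
    return float(special.zeta(alpha) / special.zeta(1.0 + alpha))


def richness_given_effort(alpha: float, N: float, N_max: float) -> float:
    """Expected richness S at total reads N for SAD exponent α.

    α > 1: S = N ζ(1+α)/ζ(α); α < 1: inversion of the continuous-limit
    relation, S = N (1−α) ζ(1+α) N_max^(α−1); α = 1 is handled as the
    logarithmic boundary S = N ζ(2)/ln N_max with a warning.
    """
    if alpha <= 0 or N < 1 or N_max < 1:
        raise DomainError("require alpha > 0 and N, N_max >= 1")
    if alpha > 1:
        return float(N / reads_per_species(alpha))
    if alpha == 1:
        warnings.warn("alpha = 1: logarithmic-correction boundary regime")
        return float(N * special.zeta(2.0) / np.log(N_max))
    if N_max ** (1.0 - alpha) < 10.0:
        warnings.warn("N_max^(1-alpha) is not >> 1; continuous-limit approximation is crude")
    return float(N * (1.0 - alpha) * special.zeta(1.0 + alpha) * N_max ** (alpha - 1.0))


def effort_given_richness(alpha: float, S: float, N_max: float) -> float:
    """Inverse of :func:`richness_given_effort` (total reads N for richness S)."""
    if alpha <= 0 or S < 1 or N_max < 1:
        raise DomainError("require alpha > 0 and S, N_max >= 1")
    if alpha > 1:
        return float(S * reads_per_species(alpha))
    if alpha == 1:
        return float(S * np.log(N_max) / special.zeta(2.0))
    return float(S * N_max ** (1.0 - alpha) / ((1.0 - alpha) * special.zeta(1.0 + alpha)))


def theoretical_gamma(alpha: float) -> float:
    """γ = min(α, 1): richness grows as N^α below α = 1 and linearly above."""
    if alpha <= 0:
        raise DomainError("alpha must be > 0")
    return float(min(alpha, 1.0))


def n_max_from_richness(S: float, alpha: float) -> float:
    """N_max = (S / (α ζ(1+α)))^(1/α): abundance of the single most abundant OTU."""
    if S < 1 or alpha <= 0:
        raise DomainError("require S >= 1 and alpha > 0")
    return float((S / (alpha * special.zeta(1.0 + alpha))) ** (1.0 / alpha))


# ---------------------------------------------------------------------------
# rarefaction


def _default_grid(N: int, n_points: int = 20) -> np.ndarray:
    grid = np.unique(np.round(np.geomspace(1, N, n_points)).astype(np.int64))
    return grid


def accumulation_curve(
    v: AbundanceVector,
    grid=None,
    replicates: int = 10,
    seed=None,
) -> AccumulationCurve:
    """Rarefaction: mean richness of without-replacement subsamples of the pool.

    Subsamples are nested within each replicate (a random accumulation order
    of the read pool), so each replicate's curve — and hence the mean curve —
    is non-decreasing in N.  Deterministic per seed.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    N = v.N
    grid = _default_grid(N) if grid is None else np.asarray(grid, dtype=np.int64)
    if (grid < 1).any() or (grid > N).any():
        raise DomainError("grid points must lie in [1, N]; extrapolation lives elsewhere")
    grid = np.sort(grid)
    rng = as_rng(seed)
    rich = np.zeros((replicates, len(grid)))
    for r in range(replicates):
        remaining = v.x.astype(np.int64).copy()
        current = np.zeros_like(remaining)
        prev = 0
        for j, g in enumerate(grid):
            m = int(g - prev)
            if m > 0:
                total = int(remaining.sum())
                if total < 10**9:
                    draw = rng.multivariate_hypergeometric(remaining, m)
                else:
                    # exact hypergeometric sampling is unavailable beyond 1e9
                    # reads; with-replacement (multinomial) sampling differs by
                    # O(m/N), negligible at that pool size
                    draw = rng.multinomial(m, remaining / total)
                    draw = np.minimum(draw, remaining)
                current += draw
                remaining -= draw
                prev = int(g)
            rich[r, j] = np.count_nonzero(current)
    return AccumulationCurve(
        N=grid.astype(float),
        S_mean=rich.mean(axis=0),
        S_sd=rich.std(axis=0, ddof=0),
        replicates=replicates,
        seed=seed,
    )


def expected_richness(v: AbundanceVector, n) -> np.ndarray:
    """Closed-form rarefaction expectation E[S(n)] = Σ_i (1 − C(N−x_i, n)/C(N, n)).

    For pools beyond ~10^9 reads the gammaln-based hypergeometric terms lose
    precision to cancellation; there the binomial limit
    log P(miss) = x_i log(1 − n/N) is used instead (its relative error is
    O(x n / N^2), negligible exactly in that regime).
    """
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    N = v.N
    if (n < 0).any() or (n > N).any():
        raise DomainError("subsample sizes must lie in [0, N]")
    uniq, counts = np.unique(v.x, return_counts=True)
    out = np.empty(len(n), dtype=float)
    if N > 10**9:
        for j, nn in enumerate(n):
            log_miss = uniq * np.log1p(-nn / N)
            out[j] = float(np.sum(counts * -np.expm1(log_miss)))
        return out
    lgN = special.gammaln(N + 1)
    for j, nn in enumerate(n):
        lg_denom = lgN - special.gammaln(nn + 1) - special.gammaln(N - nn + 1)
        Nm = N - uniq
        valid = Nm >= nn
        log_miss = np.full(len(uniq), -np.inf)
        log_miss[valid] = (
            special.gammaln(Nm[valid] + 1)
            - special.gammaln(nn + 1)
            - special.gammaln(Nm[valid] - nn + 1)
            - lg_denom
        )
        out[j] = float(np.sum(counts * -np.expm1(log_miss)))
    return out


def expected_accumulation(v: AbundanceVector, grid=None) -> AccumulationCurve:
    """Analytic (hypergeometric) rarefaction curve; sd identically 0."""
    grid = _default_grid(v.N) if grid is None else np.asarray(grid, dtype=np.int64)
    grid = np.sort(grid)
    s = expected_richness(v, grid)
    return AccumulationCurve(N=grid.astype(float), S_mean=s, S_sd=np.zeros_like(s), replicates=0)


# ---------------------------------------------------------------------------
# gamma fitting


def _curve_points(curve, window=None):
    if isinstance(curve, AccumulationCurve):
        N, S = curve.N, curve.S_mean
    else:
        N, S = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if window is not None:
        lo, hi = window
        keep = (N >= lo) & (N <= hi)
        N, S = N[keep], S[keep]
    if (N <= 0).any() or (S <= 0).any():
        raise DomainError("N and S must be positive for a log-log fit")
    return N, S


def _ols_loglog(N, S):
    lx, ly = np.log10(N), np.log10(S)
    n = len(lx)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    if n > 2:
        s2 = float(np.sum(resid**2)) / (n - 2)
        se = np.sqrt(s2 / np.sum((lx - lx.mean()) ** 2))
        ci = float(stats.t.ppf(0.975, n - 2) * se)
    else:
        ci = 0.0
    sse = float(np.sum(resid**2))
    return float(slope), float(intercept), ci, sse


def fit_gamma(curve, window=None) -> GammaFit:
    """OLS of log10 S on log10 N; ci95 from the t distribution (n − 2 df)."""
    N, S = _curve_points(curve, window)
    if len(N) < 3:
        raise DomainError("need >= 3 curve points")
    slope, intercept, ci, _ = _ols_loglog(N, S)
    return GammaFit(gamma=slope, ci95=ci, n_points=len(N), intercept=intercept)


def fit_gamma_piecewise(curve, window=None) -> GammaFit:
    """Two-regime fit: exhaustive breakpoint search minimising total squared error."""
    N, S = _curve_points(curve, window)
    n = len(N)
    if n < 6:
        raise DomainError("need >= 6 points (>= 3 per segment)")
    order = np.argsort(N)
    N, S = N[order], S[order]
    best = None
    for k in range(3, n - 2):
        s1 = _ols_loglog(N[:k], S[:k])
        s2 = _ols_loglog(N[k:], S[k:])
        sse = s1[3] + s2[3]
        if best is None or sse < best[0]:
            best = (sse, k, s1, s2)
    _, k, s1, s2 = best
    return GammaFit(
        gamma=s1[0],
        ci95=s1[2],
        n_points=n,
        intercept=s1[1],
        breakpoint=float(N[k]),
        gamma2=s2[0],
        ci95_2=s2[2],
    )


# ---------------------------------------------------------------------------
# Chao1 comparison utility


def chao1(v: AbundanceVector) -> float:
    """Chao1 lower-bound richness: S_obs + f1²/(2 f2), bias-corrected when f2 = 0."""
    f1 = int(np.sum(v.x == 1))
    f2 = int(np.sum(v.x == 2))
    if f2 > 0:
        return float(v.S + f1 * f1 / (2.0 * f2))
    return float(v.S + f1 * (f1 - 1) / 2.0)
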