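"""Maximum-likelihood fitting of abundance models and AIC model selection.

Likelihoods are continuous throughout (each family is normalised by its
integral over [1, ∞) or [1, x_max]); a discrete zeta-normalised power-law
likelihood is available behind ``discrete=True`` for sensitivity checks.
Free-parameter counts: power law V=1; truncated power law, lognormal,
Weibull and shifted power law V=2; double power law V=3 (two exponents and
the cutoff).  For the shifted family x_max is estimated post hoc from the
observed mean abundance and not charged to V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .errors import (
    ComparisonError,
    DomainError,
    FitError,
    InsufficientTailError,
)
from .models import (
    DoublePowerLawModel,
    LogNormalModel,
    PowerLawModel,
    SADModel,
    ShiftedPowerLawModel,
    TruncatedPowerLawModel,
    WeibullModel,
    double_pl_constants,
    truncated_pl_norm,
)
from .otu_io import AbundanceVector

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_power_law",
    "fit_truncated_power_law",
    "fit_lognormal",
    "fit_weibull",
    "fit_candidate_models",
    "fit_double_power_law",
    "fit_shifted_power_law",
    "estimate_x_max",
    "akaike",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, AbundanceVector):
        x = x.x
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise DomainError("abundances must be a non-empty 1-D array")
    if (x < 1).any():
        raise DomainError("abundances must be >= 1")
    return x


@dataclass
class FitResult:
    """One fitted family: model, log-likelihood and bookkeeping."""

    model: SADModel | None
    logL: float
    n: int
    V: int
    converged: bool = True
    iterations: int = 0
    stderr: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    data_signature: tuple = ()

    @property
    def aic(self) -> float:
        return -2.0 * self.logL + 2.0 * self.V

    @property
    def family(self) -> str:
        return self.model.family if self.model is not None else "unconverged"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.model.params() if self.model is not None else None,
            "logL": self.logL,
            "n": self.n,
            "V": self.V,
            "AIC": self.aic,
            "converged": self.converged,
            "iterations": self.iterations,
            "stderr": self.stderr,
        }


@dataclass
class ModelComparison:
    """Converged fits ranked by AIC with ΔAIC and Akaike weights."""

    fits: list
    delta_aic: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.fits[int(np.argmin(self.delta_aic))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "family": [f.family for f in self.fits],
                "logL": [f.logL for f in self.fits],
                "V": [f.V for f in self.fits],
                "AIC": [f.aic for f in self.fits],
                "delta_AIC": self.delta_aic,
                "weight": self.weights,
            }
        )


def _signature(x: np.ndarray) -> tuple:
    return (len(x), float(x.sum()), float(np.sum(np.log(x))))


# ---------------------------------------------------------------------------
# power law


def fit_power_law(x, x_min: float = 1.0, discrete: bool = False) -> FitResult:
    """Continuous MLE α̂ = n / Σ ln(x_i / x_min), stderr α̂/√n.

    ``x_min="auto"`` selects the cutoff by the Kolmogorov–Smirnov scan used
    for the double power law's tail stage.  ``discrete=True`` swaps in the
    zeta-normalised discrete likelihood (sensitivity check).
    """
    x = _as_array(x)
    if x_min == "auto":
        x_min, _, _ = _ks_scan(np.sort(x))
    xs = x[x >= x_min]
    n = len(xs)
    if n < 10:
        raise DomainError(f"need >= 10 abundances >= x_min, got {n}")
    sig = _signature(x)
    if discrete:
        slog = float(np.sum(np.log(xs)))

        def nll(a):
            return n * np.log(special.zeta(1.0 + a, x_min)) + (1.0 + a) * slog

        res = optimize.minimize_scalar(nll, bounds=(1e-6, 20.0), method="bounded")
        alpha = float(res.x)
        return FitResult(
            model=PowerLawModel(alpha, x_min=x_min),
            logL=-float(res.fun),
            n=n,
            V=1,
            converged=bool(res.success),
            stderr={"alpha": alpha / np.sqrt(n)},
            extras={"discrete": True, "x_min": x_min},
            data_signature=sig,
        )
    denom = float(np.sum(np.log(xs / x_min)))
    if denom <= 0:
        return FitResult(
            model=None, logL=-np.inf, n=n, V=1, converged=False,
            extras={"reason": "all abundances equal x_min; alpha diverges"},
            data_signature=sig,
        )
    alpha = n / denom
    logL = n * np.log(alpha) + n * alpha * np.log(x_min) - (1 + alpha) * float(np.sum(np.log(xs)))
    return FitResult(
        model=PowerLawModel(alpha, x_min=x_min),
        logL=logL,
        n=n,
        V=1,
        stderr={"alpha": alpha / np.sqrt(n)},
        extras={"x_min": x_min},
        data_signature=sig,
    )


# ---------------------------------------------------------------------------
# two-parameter families by numeric likelihood maximisation


def _optimize_nll(nll, starts, bounds):
    best = None
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, np.asarray(s, float), method="L-BFGS-B", bounds=bounds)
        if best is None or (res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("likelihood optimisation failed")
    return best


def fit_truncated_power_law(x) -> FitResult:
    x = _as_array(x)
    n = len(x)
    slog = float(np.sum(np.log(x)))
    ssum = float(np.sum(x))
    sig = _signature(x)

    def nll(p):
        beta, lam = p
        try:
            Z = truncated_pl_norm(beta, lam)
        except Exception:
            return np.inf
        if not np.isfinite(Z) or Z <= 0:
            return np.inf
        return n * np.log(Z) + (1 + beta) * slog + lam * ssum

    alpha0 = n / max(slog, 1e-9)
    starts = [(alpha0, 1e-12), (alpha0 * 0.7, 1.0 / max(ssum / n, 2.0)), (0.5, 1e-4)]
    res = _optimize_nll(nll, starts, bounds=[(1e-6, 12.0), (0.0, 2.0)])
    beta, lam = res.x
    return FitResult(
        model=TruncatedPowerLawModel(float(beta), float(lam)),
        logL=-float(res.fun),
        n=n,
        V=2,
        converged=bool(res.success),
        iterations=int(res.nit),
        stderr=_hessian_stderr(nll, res.x, names=("beta", "lam")),
        data_signature=sig,
    )


def fit_lognormal(x) -> FitResult:
    x = _as_array(x)
    n = len(x)
    lx = np.log(x)
    sig = _signature(x)

    def nll(p):
        mu, logsig = p
        sigma = np.exp(logsig)
        m = LogNormalModel(mu, sigma)
        ll = np.sum(m.logpdf(x))
        return np.inf if not np.isfinite(ll) else -ll

    mu0, s0 = float(np.mean(lx)), float(np.std(lx) + 0.1)
    starts = [(mu0, np.log(s0)), (mu0 - 1.0, np.log(s0) + 0.4), (mu0 + 1.0, np.log(s0) - 0.4)]
    res = _optimize_nll(nll, starts, bounds=[(-50.0, 50.0), (-5.0, 5.0)])
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return FitResult(
        model=LogNormalModel(mu, sigma),
        logL=-float(res.fun),
        n=n,
        V=2,
        converged=bool(res.success),
        iterations=int(res.nit),
        data_signature=sig,
    )


def fit_weibull(x) -> FitResult:
    x = _as_array(x)
    n = len(x)
    sig = _signature(x)

    def nll(p):
        logk, logs = p
        m = WeibullModel(float(np.exp(logk)), float(np.exp(logs)))
        ll = np.sum(m.logpdf(x))
        return np.inf if not np.isfinite(ll) else -ll

    s0 = max(float(np.mean(x)), 1.1)
    starts = [(np.log(0.5), np.log(s0)), (np.log(1.0), np.log(s0) * 0.5), (np.log(0.2), np.log(s0) + 1.0)]
    res = _optimize_nll(nll, starts, bounds=[(-4.0, 3.0), (-5.0, 30.0)])
    k, scale = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return FitResult(
        model=WeibullModel(k, scale),
        logL=-float(res.fun),
        n=n,
        V=2,
        converged=bool(res.success),
        iterations=int(res.nit),
        data_signature=sig,
    )


def _hessian_stderr(nll, theta, names, step=1e-4):
    """Approximate standard errors from the observed information (central differences)."""
    theta = np.asarray(theta, float)
    k = len(theta)
    H = np.zeros((k, k))
    h = np.maximum(np.abs(theta) * step, step)
    try:
        with np.errstate(all="ignore"):
            return _hessian_stderr_inner(nll, theta, names, H, h, k)
    except Exception:
        return {}


def _hessian_stderr_inner(nll, theta, names, H, h, k):
    try:
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = nll(theta + ei + ej)
                fpm = nll(theta + ei - ej)
                fmp = nll(theta - ei + ej)
                fmm = nll(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if not np.all(np.isfinite(se)):
            return {}
        return dict(zip(names, se.tolist()))
    except Exception:
        return {}


_FIT_DISPATCH = {
    "pl": fit_power_law,
    "tpl": fit_truncated_power_law,
    "ln": fit_lognormal,
    "weibull": fit_weibull,
}


def fit_candidate_models(x, families=("pl", "tpl", "ln", "weibull")) -> ModelComparison:
    """Fit each candidate family and assemble the ΔAIC / Akaike-weight table."""
    x = _as_array(x)
    fits = []
    for fam in families:
        if fam == "double":
            fits.append(fit_double_power_law(x))
        elif fam == "shifted":
            fits.append(fit_shifted_power_law(x))
        else:
            fits.append(_FIT_DISPATCH[fam](x))
    return akaike(fits)


# ---------------------------------------------------------------------------
# double power law (two-stage, Clauset-style cutoff scan)


def _ks_scan(xs_sorted: np.ndarray, min_tail: int = 10):
    """Scan candidate cutoffs (unique abundances); return (x_c, alpha, KS).

    For each candidate x_m the tail exponent is the closed-form continuous MLE
    on x >= x_m and the Kolmogorov–Smirnov distance is taken between the
    fitted and empirical tail survival functions; the KS-minimising candidate
    wins, ties going to the smallest cutoff.
    """
    uniq, counts = np.unique(xs_sorted, return_counts=True)
    tail_counts = np.cumsum(counts[::-1])[::-1]
    log_u = np.log(uniq)
    suffix_slog = np.cumsum((log_u * counts)[::-1])[::-1]
    ok = tail_counts >= min_tail
    if not ok.any():
        raise InsufficientTailError("fewer than %d points above every candidate cutoff" % min_tail)
    best = None
    for i in np.flatnonzero(ok):
        nt = tail_counts[i]
        denom = suffix_slog[i] - nt * log_u[i]
        if denom <= 0:
            continue
        alpha = nt / denom
        v = uniq[i:]
        emp_sf = tail_counts[i:] / nt
        mod_sf = (v / uniq[i]) ** (-alpha)
        D = float(np.max(np.abs(emp_sf - mod_sf)))
        if best is None or D < best[2]:
            best = (float(uniq[i]), float(alpha), D, int(nt))
    if best is None:
        raise InsufficientTailError("no candidate cutoff admits a tail fit")
    return best[0], best[1], {"ks": best[2], "n_tail": best[3]}


def _head_nll_factory(xh: np.ndarray, x_c: float, interval: bool):
    """Negative log-likelihood in δ for a power law truncated to [1, x_c).

    ``interval=True`` treats the observations as floored integers and uses the
    exact bin probabilities P(k) ∝ k^(−δ) − (k+1)^(−δ) of the continuous
    density; discreteness is only material in the head, so this is the default
    whenever the head data are integral.
    """
    n = len(xh)
    if interval:
        uniq, counts = np.unique(xh, return_counts=True)
        upper = np.minimum(uniq + 1.0, x_c)

        def nll(d):
            d = float(d)
            if abs(d) < 1e-12:
                p = np.log(upper / uniq) / np.log(x_c)
            else:
                p = (uniq ** (-d) - upper ** (-d)) / (1.0 - x_c ** (-d))
            if np.any(p <= 0):
                return np.inf
            return -float(np.sum(counts * np.log(p)))

        return nll
    slog = float(np.sum(np.log(xh)))

    def nll(d):
        d = float(d)
        if abs(d) < 1e-12:
            norm = np.log(x_c)
        else:
            norm = (1.0 - x_c ** (-d)) / d
        if norm <= 0:
            return np.inf
        return n * np.log(norm) + (1 + d) * slog

    return nll


def fit_double_power_law(x, x_c: float | None = None, min_tail: int = 10) -> FitResult:
    """Two-stage fit: KS-scan for (α̂, x̂_c) on the tail, then head δ̂ by MLE on [1, x̂_c].

    Stage 1 scans every unique abundance with at least ``min_tail`` points above
    it, fitting the tail exponent in closed form and minimising the KS distance
    between fitted and empirical tail survival functions.  Stage 2 maximises
    the likelihood of a power law truncated to [1, x̂_c] over the head points.
    """
    x = _as_array(x)
    n = len(x)
    if n < 50:
        raise DomainError("need >= 50 abundances for a double power-law fit")
    sig = _signature(x)
    xs = np.sort(x)
    degenerate = (xs[-1] / xs[0]) < 100.0  # support spans < 2 decades
    extras: dict = {"degenerate_support": bool(degenerate)}
    if x_c is None:
        x_c_hat, alpha, scan = _ks_scan(xs, min_tail=min_tail)
        extras.update(scan)
    else:
        x_c_hat = float(x_c)
        tail = xs[xs >= x_c_hat]
        if len(tail) < min_tail:
            raise InsufficientTailError("fewer than %d points above the forced cutoff" % min_tail)
        alpha = len(tail) / float(np.sum(np.log(tail / x_c_hat)))
        extras["n_tail"] = int(len(tail))
    n_tail = int(np.sum(xs >= x_c_hat))
    head = xs[xs < x_c_hat]
    if len(head) >= 10 and x_c_hat > 1.0:
        interval = bool(np.all(head == np.floor(head)))
        nll = _head_nll_factory(head, x_c_hat, interval)
        res = optimize.minimize_scalar(nll, bounds=(-3.0, 10.0), method="bounded")
        delta = float(res.x)
        # curvature-based stderr for the head exponent
        h = 1e-4 * max(abs(delta), 1.0)
        curv = (nll(delta + h) - 2 * nll(delta) + nll(delta - h)) / h**2
        se_delta = float(1.0 / np.sqrt(curv)) if curv > 0 else np.nan
    else:
        delta = alpha  # no resolvable head: single-regime power law
        se_delta = np.nan
        extras["head_collapsed"] = True
    model = DoublePowerLawModel(delta, alpha, x_c_hat)
    logL = float(np.sum(model.logpdf(x)))
    return FitResult(
        model=model,
        logL=logL,
        n=n,
        V=3,
        stderr={"alpha": alpha / np.sqrt(max(n_tail, 1)), "delta": se_delta},
        extras=extras,
        data_signature=sig,
    )


# ---------------------------------------------------------------------------
# shifted power law (alternating fixed-point iteration)


def fit_shifted_power_law(
    x,
    tolerance: float = 1e-6,
    max_iter: int = 20000,
    alpha0: float = 1.0,
    x0_init: float = 1.0,
    keep_trace: bool = False,
) -> FitResult:
    """Alternating fixed-point iteration of the shifted power-law MLE equations.

    Iterates  α ← S / Σ ln((x_i + x0)/(1 + x0))  and
    1 + x0 ← α S ((1 + α) Σ 1/(x_i + x0))^−1  (the stationarity conditions of
    the likelihood under P(x) = α(1 + x0)^α (x + x0)^(−1−α)), stopping when
    both parameter updates move less than ``tolerance``.
    """
    x = _as_array(x)
    S = len(x)
    if S < 10:
        raise DomainError("need >= 10 abundances")
    sig = _signature(x)
    alpha, x0 = float(alpha0), float(x0_init)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = float(np.sum(np.log((x + x0) / (1.0 + x0))))
        if denom <= 0:
            break
        alpha_new = S / denom
        inv_sum = float(np.sum(1.0 / (x + x0)))
        x0_new = alpha_new * S / ((1.0 + alpha_new) * inv_sum) - 1.0
        x0_new = max(x0_new, 0.0)
        if keep_trace:
            trace.append((alpha_new, x0_new))
        if abs(x0_new - x0) < tolerance and abs(alpha_new - alpha) < tolerance:
            alpha, x0 = alpha_new, x0_new
            converged = True
            break
        alpha, x0 = alpha_new, x0_new
    model = ShiftedPowerLawModel(alpha, x0)
    logL = float(np.sum(model.logpdf(x)))

    def nll(p):
        a, z = p
        if a <= 0 or z < 0:
            return np.inf
        return -(S * (np.log(a) + a * np.log(1.0 + z)) - (1 + a) * np.sum(np.log(x + z)))

    stderr = _hessian_stderr(nll, np.array([alpha, x0]), names=("alpha", "x0"))
    extras = {"tolerance": tolerance}
    if keep_trace:
        extras["trace"] = trace
    return FitResult(
        model=model,
        logL=logL,
        n=S,
        V=2,
        converged=converged,
        iterations=it,
        stderr=stderr,
        extras=extras,
        data_signature=sig,
    )


def estimate_x_max(alpha: float, x0: float, observed_mean: float) -> float:
    """Invert the mean-abundance relation <x>(x_max) for the shifted power law.

    Returns the x_max at which the model mean matches ``observed_mean``;
    returns ``inf`` (unbounded) when no root exists below 10^18.
    """
    if observed_mean <= 1:
        raise DomainError("observed mean must exceed 1 (support starts at 1)")
    if alpha <= 0:
        raise DomainError("alpha must be > 0")

    def g(log_xm):
        m = ShiftedPowerLawModel(alpha, x0, x_max=float(np.exp(log_xm)))
        return m.mean() - observed_mean

    lo = np.log(max(observed_mean, 1.0 + 1e-9) + 1e-9)
    hi = np.log(1e18)
    if g(lo) > 0:
        lo = np.log(1.0 + 1e-9)
    if g(hi) < 0:
        return np.inf
    root = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(np.exp(root))


# ---------------------------------------------------------------------------
# AIC


def akaike(fits) -> ModelComparison:
    """ΔAIC and Akaike weights over converged fits on identical data."""
    fits = list(fits)
    if not fits:
        raise ComparisonError("no fits to compare")
    sigs = {f.data_signature for f in fits if f.data_signature}
    if len(sigs) > 1:
        raise ComparisonError("fits were computed on differing data vectors")
    usable = [f for f in fits if f.converged and np.isfinite(f.logL)]
    if not usable:
        raise ComparisonError("no converged fit to compare")
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} non-converged fit(s) excluded from AIC comparison")
    aics = np.array([f.aic for f in usable])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelComparison(usable, delta, w)
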