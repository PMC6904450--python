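"""Parameter-vs-effort trajectories and in-silico communities at arbitrary depth.

The workflow mirrors the survey-extrapolation procedure: fit the abundance
model to increasingly large random aggregations of samples, fit each model
parameter's dependence on total reads to a simple functional form
(power-plus-constant c1·N^c2 + c3 for scale-like parameters, saturating
exponential c1·(1 + c2·exp(−N/c3)) for exponents), evaluate the curves at a
target read depth, and generate a community from the resulting distribution
by inverse-CDF draws until the cumulative read count reaches the target.
The generated richness S is the number of draws; the richness ratio against
a caller-supplied reference quantifies how far rarefaction-based estimates
undershoot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DomainError, FitError, NotNormalizableError
from .fitting import estimate_x_max, fit_double_power_law, fit_shifted_power_law
from .models import DoublePowerLawModel, ShiftedPowerLawModel, sample_to_reads
from .otu_io import OTUTable, aggregate_counts
from .utils import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryCurve",
    "TrajectoryModel",
    "ExtrapolationResult",
    "parameter_series",
    "fit_trajectories",
    "default_trajectories",
    "generate_at_scale",
]


@dataclass(frozen=True)
class TrajectoryCurve:
    """One parameter's dependence on total reads N.

    form "power_const":  c1 * N^c2 + c3
    form "sat_exp":      c1 * (1 + c2 * exp(−N / c3))   (plateau c1 as N → ∞)
    """

    form: str
    c1: float
    c2: float
    c3: float

    def __call__(self, N) -> np.ndarray:
        N = np.asarray(N, dtype=float)
        if self.form == "power_const":
            return self.c1 * N**self.c2 + self.c3
        if self.form == "sat_exp":
            return self.c1 * (1.0 + self.c2 * np.exp(-N / self.c3))
        raise DomainError(f"unknown trajectory form {self.form!r}")


@dataclass(frozen=True)
class TrajectoryModel:
    """Per-parameter trajectory curves for one ocean regime."""

    region: str  # "upper" (double power law) or "deep" (shifted power law)
    curves: dict  # parameter name -> TrajectoryCurve

    def evaluate(self, N: float) -> dict:
        return {name: float(c(N)) for name, c in self.curves.items()}


@dataclass(frozen=True)
class ExtrapolationResult:
    N_target: int
    params_at_N: dict
    S: int
    seed: object
    ratio: float | None = None
    reference_richness: float | None = None


# ---------------------------------------------------------------------------
# empirical parameter series


def parameter_series(
    table: OTUTable,
    family: str,
    subset_sizes,
    reps: int = 5,
    seed=None,
    n_bins: int = 8,
):
    """Fit the chosen family to random sample aggregations of growing size.

    For each subset size, ``reps`` random sample subsets are aggregated and
    fitted; results are binned by log-spaced total-reads bins and reported as
    (bin centre N, mean params, sd params, count).  Non-converged fits are
    dropped with a logged warning.
    """
    if family not in ("double", "shifted"):
        raise DomainError("family must be 'double' or 'shifted'")
    if reps < 1:
        raise DomainError("reps must be >= 1")
    rng = as_rng(seed)
    samples = list(table.sample_ids)
    records = []
    for size in subset_sizes:
        size = int(size)
        if not 1 <= size <= len(samples):
            raise DomainError(f"subset size {size} outside [1, {len(samples)}]")
        for _ in range(reps):
            if size == len(samples):
                subset = samples
            else:
                subset = list(rng.choice(samples, size=size, replace=False))
            v = aggregate_counts(table, subset)
            try:
                fit = (
                    fit_double_power_law(v)
                    if family == "double"
                    else fit_shifted_power_law(v)
                )
            except DomainError as exc:
                logger.warning("fit skipped for subset of %d samples: %s", size, exc)
                continue
            if not fit.converged and family == "shifted":
                logger.warning("non-converged fit dropped (subset of %d samples)", size)
                continue
            params = dict(fit.model.params())
            params.pop("x_max", None)
            records.append((v.N, params))
    if not records:
        raise FitError("no converged fits in any aggregation")
    reads = np.array([r[0] for r in records], dtype=float)
    edges = np.geomspace(reads.min(), reads.max() + 1, n_bins + 1)
    series = []
    names = sorted(records[0][1])
    for b in range(n_bins):
        sel = (reads >= edges[b]) & (reads < edges[b + 1])
        if b == n_bins - 1:
            sel |= reads == edges[b + 1]
        if not sel.any():
            continue
        vals = {nm: np.array([records[i][1][nm] for i in np.flatnonzero(sel)]) for nm in names}
        series.append(
            {
                "N": float(np.exp(np.mean(np.log(reads[sel])))),
                "params": {nm: float(v.mean()) for nm, v in vals.items()},
                "sd": {nm: float(v.std(ddof=0)) for nm, v in vals.items()},
                "count": int(sel.sum()),
            }
        )
    return series


# ---------------------------------------------------------------------------
# trajectory fitting


def _fit_one_curve(N, y, form: str, name: str) -> TrajectoryCurve:
    N = np.asarray(N, float)
    y = np.asarray(y, float)
    if len(N) < 4:
        raise DomainError(f"need >= 4 series points to fit the {name} trajectory")
    if np.allclose(y, y[0]):
        # constant series: degenerate to the c3 / c1 branch
        if form == "power_const":
            return TrajectoryCurve(form, 0.0, 1.0, float(y[0]))
        return TrajectoryCurve(form, float(y[0]), 0.0, 1.0)
    try:
        if form == "power_const":
            def f(N, c1, c2, c3):
                return c1 * N**c2 + c3

            # slope of log y vs log N as exponent seed
            c2_0 = float(np.polyfit(np.log(N), np.log(np.abs(y) + 1e-9), 1)[0])
            p0 = (max(y[-1], 1e-6) / N[-1] ** c2_0, c2_0, float(np.min(y)))
            popt, _ = optimize.curve_fit(f, N, y, p0=p0, maxfev=20000)
        elif form == "sat_exp":
            def f(N, c1, c2, c3):
                return c1 * (1.0 + c2 * np.exp(-N / c3))

            p0 = (float(y[-1]), float(y[0] / y[-1] - 1.0), float(np.median(N)))
            popt, _ = optimize.curve_fit(f, N, y, p0=p0, maxfev=20000)
        else:
            raise DomainError(f"unknown trajectory form {form!r}")
    except (RuntimeError, TypeError) as exc:
        raise FitError(f"trajectory fit failed for parameter {name!r}: {exc}") from exc
    return TrajectoryCurve(form, *map(float, popt))


def fit_trajectories(series, forms: dict, region: str = "custom") -> TrajectoryModel:
    """Nonlinear least squares of each parameter's series to its stated form.

    ``series`` is the output of :func:`parameter_series`; ``forms`` maps
    parameter name -> "power_const" | "sat_exp".
    """
    N = [pt["N"] for pt in series]
    curves = {}
    for name, form in forms.items():
        y = [pt["params"][name] for pt in series]
        curves[name] = _fit_one_curve(N, y, form, name)
    return TrajectoryModel(region=region, curves=curves)


def default_trajectories(region: str) -> TrajectoryModel:
    """The survey-derived trajectory coefficients used for extrapolation.

    upper:  x_c = 0.0002 N^1.1 + 52.6,  δ = 0.32 (1 + 0.71 e^(−N/570007)),
            α = 1.42 (1 − 0.2 e^(−N/110185))
    deep:   x_0 = 0.000003 N^1.1 − 1,   α = 0.88 (1 − 0.45 e^(−N/363263)),
            <x> = 0.00042 N^0.97 + 23.6
    """
    if region == "upper":
        return TrajectoryModel(
            region="upper",
            curves={
                "x_c": TrajectoryCurve("power_const", 0.0002, 1.1, 52.6),
                "delta": TrajectoryCurve("sat_exp", 0.32, 0.71, 570007.0),
                "alpha": TrajectoryCurve("sat_exp", 1.42, -0.2, 110185.0),
            },
        )
    if region == "deep":
        return TrajectoryModel(
            region="deep",
            curves={
                "x0": TrajectoryCurve("power_const", 0.000003, 1.1, -1.0),
                "alpha": TrajectoryCurve("sat_exp", 0.88, -0.45, 363263.0),
                "mean_x": TrajectoryCurve("power_const", 0.00042, 0.97, 23.6),
            },
        )
    raise DomainError(f"unknown region {region!r} (expected 'upper' or 'deep')")


# ---------------------------------------------------------------------------
# generation at scale


def generate_at_scale(
    trajectory: TrajectoryModel,
    N_target: int,
    seed=None,
    reference_richness: float | None = None,
) -> ExtrapolationResult:
    """Generate a community at ``N_target`` reads from extrapolated parameters.

    Evaluates the trajectory at N_target, builds the corresponding model
    (double power law for "upper"; shifted power law with the finite x_max
    implied by the extrapolated mean abundance for "deep") and draws
    abundances by inverse-CDF until the cumulative reads reach the target,
    keeping the final overshooting draw.  S is the number of draws.
    """
    if N_target < 1:
        raise DomainError("N_target must be >= 1")
    params = trajectory.evaluate(float(N_target))
    if trajectory.region == "upper":
        try:
            model = DoublePowerLawModel(params["delta"], params["alpha"], params["x_c"])
        except (NotNormalizableError, DomainError) as exc:
            raise NotNormalizableError(f"evaluated parameters not usable: {params}") from exc
    elif trajectory.region == "deep":
        # the fitted x0 curve crosses zero near N ~ 1e5; below that the shift
        # is physically zero
        params["x0"] = max(params["x0"], 0.0)
        x_max = estimate_x_max(params["alpha"], params["x0"], params["mean_x"])
        params = dict(params, x_max=x_max)
        try:
            model = ShiftedPowerLawModel(params["alpha"], params["x0"], x_max=x_max)
        except (NotNormalizableError, DomainError) as exc:
            raise NotNormalizableError(f"evaluated parameters not usable: {params}") from exc
    else:
        raise DomainError(f"trajectory region {trajectory.region!r} has no generator")
    v = sample_to_reads(model, int(N_target), seed=seed)
    ratio = None
    if reference_richness is not None:
        if reference_richness <= 0:
            raise DomainError("reference richness must be positive")
        ratio = v.S / reference_richness
    return ExtrapolationResult(
        N_target=int(N_target),
        params_at_N=params,
        S=v.S,
        seed=seed,
        ratio=ratio,
        reference_richness=reference_richness,
    )
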