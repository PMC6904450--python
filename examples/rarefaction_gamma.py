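"""Rarefaction curve and scaling exponent for a deep-ocean-like survey.

Subsamples the aggregated read pool without replacement on a log grid,
fits S ~ N^gamma by least squares in log-log space, and compares the fitted
exponent with the theoretical prediction gamma = min(alpha, 1) for the
generating tail exponent alpha = 0.89.
"""

import numpy as np

from sadscale import (
    accumulation_curve,
    aggregate_counts,
    chao1,
    deep_ocean_spec,
    fit_gamma,
    synth_survey,
    theoretical_gamma,
)

table, truth = synth_survey(deep_ocean_spec(seed=2))
v = aggregate_counts(table)
print(f"deep-ocean-like survey: {v.S:,} OTUs, {v.N:,} reads")

grid = np.unique(np.geomspace(100, v.N, 15).astype(int))
curve = accumulation_curve(v, grid=grid, replicates=10, seed=7)
for n, s in zip(curve.N[::3], curve.S_mean[::3]):
    print(f"  N = {int(n):>9,}  ->  S = {s:,.0f}")

g = fit_gamma(curve, window=(1e2, 1e5))
alpha = truth["model"]["params"]["alpha"]
print(f"\nfitted gamma = {g.gamma:.3f} (ci95 {g.ci95:.3f}) over N in [1e2, 1e5]; "
      f"asymptotic theory gamma = min(alpha, 1) = {theoretical_gamma(alpha):.2f}")
print("(the fitted slope sits below the asymptotic value: the shifted head "
      "flattens the curve at small N, and the pool nears exhaustion at large N)")
print(f"Chao1 estimate {chao1(v):,.0f} vs latent community richness "
      f"{truth['S_true']:,} — the lower-bound estimator sits below the truth")
print("\ngamma < 1 means the rarefaction curve never flattens: every extra "
      "read batch keeps revealing new OTUs from the rare biosphere.")
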