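"""Synthetic OTU tables with known ground truth.

Three generators cover the dataset shapes the analysis pipeline targets:

- :func:`synth_survey`: a multi-site survey.  A latent community is drawn
  from any abundance model; each sample is an independent multinomial draw
  of reads from the community's relative abundances (an optional Dirichlet
  dispersion knob perturbs per-sample compositions, default off).
- :func:`synth_mesocosm`: a daily time series from one fixed latent
  community (default a truncated power law with exponent 0.53 and
  characteristic abundance 10^4), with per-day read depths scattered
  around a configurable mean.
- :func:`yule_community`: a preferential-attachment (Yule) growth process —
  new OTUs appear at rate g per existing OTU, reads accrue at rate s per
  existing read — whose stationary abundance tail is a power law with
  exponent g/s.

Every generator takes an explicit seed and returns ground truth alongside
the table so tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .models import SADModel, sample_to_reads
from .otu_io import AbundanceVector, OTUTable, aggregate_counts
from .utils import as_rng

__all__ = [
    "CommunitySpec",
    "SurveySpec",
    "synth_survey",
    "synth_mesocosm",
    "yule_community",
    "upper_ocean_spec",
    "deep_ocean_spec",
    "cumulative_aggregate",
]


@dataclass(frozen=True)
class CommunitySpec:
    """A latent community: an abundance model plus a size (OTUs or reads)."""

    model: SADModel
    n_otus: int | None = None
    target_reads: int | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.n_otus is None) == (self.target_reads is None):
            raise DomainError("set exactly one of n_otus / target_reads")

    def draw(self) -> AbundanceVector:
        if self.n_otus is not None:
            x = self.model.sample(self.n_otus, seed=self.seed)
            return AbundanceVector.from_counts(x)
        return sample_to_reads(self.model, self.target_reads, seed=self.seed)


@dataclass(frozen=True)
class SurveySpec:
    """A survey layout: community, number of samples, per-sample depths."""

    community: CommunitySpec
    n_samples: int
    reads_per_sample: object  # scalar or per-sample schedule
    dispersion: float = 0.0  # Dirichlet perturbation strength; 0 = identical compositions

    def __post_init__(self):
        if self.n_samples < 1:
            raise DomainError("n_samples must be >= 1")
        depths = self.depths
        if (depths < 1).any():
            raise DomainError("reads_per_sample must be >= 1")

    @property
    def depths(self) -> np.ndarray:
        d = np.asarray(self.reads_per_sample)
        if d.ndim == 0:
            d = np.full(self.n_samples, int(d))
        if len(d) != self.n_samples:
            raise DomainError("reads_per_sample schedule length must equal n_samples")
        return d.astype(np.int64)


def _multinomial_table(latent: AbundanceVector, depths, dispersion, rng) -> OTUTable:
    p = latent.x / latent.N
    counts = np.zeros((latent.S, len(depths)), dtype=np.int64)
    for j, depth in enumerate(depths):
        pj = p
        if dispersion > 0:
            conc = np.maximum(p / dispersion, 1e-12)
            pj = rng.dirichlet(conc)
        counts[:, j] = rng.multinomial(int(depth), pj)
    sample_ids = tuple(f"sample_{j + 1:03d}" for j in range(len(depths)))
    return OTUTable(latent.otu_ids, sample_ids, counts)


def synth_survey(spec: SurveySpec, seed=None) -> tuple[OTUTable, dict]:
    """Draw a latent community, then multinomial reads per sample.

    Returns (table, truth); truth records the generating model parameters,
    the latent richness and the latent abundances' total.
    """
    rng = as_rng(spec.community.seed if seed is None else seed)
    latent = spec.community.draw()
    table = _multinomial_table(latent, spec.depths, spec.dispersion, rng)
    truth = {
        "model": spec.community.model.to_dict(),
        "S_true": latent.S,
        "latent_reads": latent.N,
        "dispersion": spec.dispersion,
    }
    return table, truth


def synth_mesocosm(
    model: SADModel | None = None,
    days: int = 20,
    mean_depth: float = 1e4,
    depth_sd_frac: float = 0.4,
    n_otus: int = 4000,
    seed=0,
) -> tuple[OTUTable, dict]:
    """Daily sampling of one fixed latent community over ``days`` days.

    Defaults emulate an enclosed-water-body experiment: one sample per day
    at roughly 10^4 reads with day-to-day depth scatter, so the 20-day
    aggregate holds roughly an order of magnitude more reads than any single
    day.  The latent community is a truncated power law with exponent 0.53
    and characteristic abundance 1/λ = 10^4: the power-law decay carries the
    mesocosm's scaling behaviour, while the exponential cutoff — the form
    such experiments' abundance tables actually select under AIC — keeps a
    finite enclosure from being dominated by a single astronomically
    abundant OTU.
    """
    from .models import TruncatedPowerLawModel

    if days < 2:
        raise DomainError("days must be >= 2")
    rng = as_rng(seed)
    if model is None:
        model = TruncatedPowerLawModel(beta=0.53, lam=1e-4)
    latent = AbundanceVector.from_counts(model.sample(n_otus, seed=rng))
    depths = np.maximum(
        rng.normal(mean_depth, depth_sd_frac * mean_depth, size=days), mean_depth * 0.1
    ).astype(np.int64)
    table = _multinomial_table(latent, depths, 0.0, rng)
    table = OTUTable(
        table.otu_ids,
        tuple(f"day_{d + 1:02d}" for d in range(days)),
        table.counts,
    )
    truth = {"model": model.to_dict(), "S_true": latent.S, "depths": depths.tolist()}
    return table, truth


def cumulative_aggregate(table: OTUTable):
    """Cumulative (N, S) after each successive sample (time-ordered columns)."""
    csum = np.cumsum(table.counts, axis=1)
    N = csum.sum(axis=0)
    S = (csum > 0).sum(axis=0)
    return N.astype(np.int64), S.astype(np.int64)


def yule_community(g_over_s: float, n_events: int, seed=None) -> AbundanceVector:
    """Yule/preferential-attachment growth; returns final OTU abundances.

    Each event adds one read: a new OTU of abundance 1 with probability
    g·S / (g·S + s·N) (S current richness, N current reads), otherwise an
    existing OTU chosen proportionally to its abundance gains a read.  The
    abundance distribution develops a power-law tail with exponent g/s.
    """
    if g_over_s <= 0:
        raise DomainError("g_over_s must be > 0")
    if n_events < 1:
        raise DomainError("n_events must be >= 1")
    rng = as_rng(seed)
    n_events = int(n_events)
    u_new = rng.random(n_events)
    u_pick = rng.random(n_events)
    token_otu = np.empty(n_events, dtype=np.int64)
    g = float(g_over_s)  # only the ratio g/s matters; set s = 1
    n_otus = 0
    for t in range(n_events):
        p_new = 1.0 if t == 0 else (g * n_otus) / (g * n_otus + t)
        if u_new[t] < p_new:
            token_otu[t] = n_otus
            n_otus += 1
        else:
            token_otu[t] = token_otu[int(u_pick[t] * t)]
    counts = np.bincount(token_otu, minlength=n_otus)
    return AbundanceVector.from_counts(counts)


# ---------------------------------------------------------------------------
# survey presets emulating the two global-ocean dataset shapes


def upper_ocean_spec(seed: int = 0) -> SurveySpec:
    """An upper-ocean-like survey: ~10^2 samples, ~3x10^6 total reads,
    double power-law community (head 0.36, tail 1.54, break 2313)."""
    from .models import DoublePowerLawModel

    return SurveySpec(
        community=CommunitySpec(
            model=DoublePowerLawModel(delta=0.36, alpha=1.54, x_c=2313.0),
            n_otus=18022,
            seed=seed,
        ),
        n_samples=109,
        reads_per_sample=30000,
    )


def deep_ocean_spec(seed: int = 0) -> SurveySpec:
    """A deep-ocean-like survey: 30 samples, ~1.8x10^6 total reads,
    shifted power-law community (alpha 0.89, x0 20.34)."""
    from .models import ShiftedPowerLawModel

    return SurveySpec(
        community=CommunitySpec(
            model=ShiftedPowerLawModel(alpha=0.89, x0=20.34),
            n_otus=3695,
            seed=seed,
        ),
        n_samples=30,
        reads_per_sample=60000,
    )
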