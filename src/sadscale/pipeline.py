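"""Orchestrate fit → compare → rarefy → gamma → extrapolate as one run.

The configuration is a single dict (typically loaded from YAML/JSON).  All
stage seeds are derived from one master seed, so identical configs produce
byte-identical numeric outputs.  Outputs land in the configured directory:
``fits.json``, ``comparison.tsv``, ``curve.tsv``, ``gamma.tsv``,
``extrap.json`` and ``run.log``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .errors import PipelineConfigError, SadscaleError
from .extrapolation import default_trajectories, generate_at_scale
from .fitting import fit_candidate_models
from .otu_io import aggregate_counts, read_otu_table
from .scaling import accumulation_curve, fit_gamma, fit_gamma_piecewise
from .synthetic import (
    CommunitySpec,
    SurveySpec,
    deep_ocean_spec,
    synth_mesocosm,
    synth_survey,
    upper_ocean_spec,
    yule_community,
)
from .utils import spawn_seeds

__all__ = ["PipelineConfig", "run_pipeline", "validate_config"]

_ALL_STAGES = ("fit", "rarefy", "gamma", "extrapolate")


class PipelineConfig(dict):
    """A validated pipeline configuration (plain dict with defaults applied)."""


def validate_config(config: dict) -> PipelineConfig:
    cfg = PipelineConfig(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(_ALL_STAGES))
    cfg.setdefault("families", ["pl", "tpl", "ln", "weibull"])
    cfg.setdefault("grid_points", 20)
    cfg.setdefault("replicates", 10)
    cfg.setdefault("outdir", "sadscale_out")
    if ("input" in cfg) == ("simulate" in cfg):
        raise PipelineConfigError("config must set exactly one of 'input' / 'simulate'")
    if "input" in cfg and not Path(cfg["input"]).exists():
        raise PipelineConfigError(f"input file not found: {cfg['input']}")
    unknown = set(cfg["stages"]) - set(_ALL_STAGES)
    if unknown:
        raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")
    if "extrapolate" in cfg["stages"] and "extrapolate" not in cfg:
        raise PipelineConfigError("the extrapolate stage needs an 'extrapolate' section")
    return cfg


def _simulate(cfg: dict, seed: int):
    sim = dict(cfg["simulate"])
    kind = sim.pop("kind", "survey")
    if kind == "survey":
        preset = sim.pop("preset", None)
        if preset == "upper":
            spec = upper_ocean_spec(seed)
        elif preset == "deep":
            spec = deep_ocean_spec(seed)
        else:
            from .models import model_from_dict

            spec = SurveySpec(
                community=CommunitySpec(
                    model=model_from_dict(sim["model"]),
                    n_otus=sim.get("n_otus"),
                    target_reads=sim.get("target_reads"),
                    seed=seed,
                ),
                n_samples=sim["n_samples"],
                reads_per_sample=sim["reads_per_sample"],
                dispersion=sim.get("dispersion", 0.0),
            )
        table, _ = synth_survey(spec)
        return table
    if kind == "mesocosm":
        table, _ = synth_mesocosm(seed=seed, **sim)
        return table
    raise PipelineConfigError(f"unknown simulation kind {kind!r}")


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns a report dict of per-stage results."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    logger = logging.getLogger("sadscale.pipeline")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"version": __version__, "config": dict(cfg)}
    try:
        seeds = spawn_seeds(int(cfg["seed"]), 4)
        logger.info("sadscale %s; master seed %s; stage seeds %s", __version__, cfg["seed"], seeds)
        if "input" in cfg:
            table = read_otu_table(cfg["input"])
        else:
            table = _simulate(cfg, seeds[0])
        v = aggregate_counts(table)
        logger.info("aggregated abundance vector: S=%d, N=%d", v.S, v.N)
        report["S_observed"], report["N_reads"] = v.S, v.N

        if "fit" in cfg["stages"]:
            comparison = fit_candidate_models(v, families=cfg["families"])
            for f in comparison.fits:
                logger.info("fit %s: params=%s logL=%.3f AIC=%.3f", f.family,
                            f.model.params(), f.logL, f.aic)
            (outdir / "fits.json").write_text(
                json.dumps([f.to_dict() for f in comparison.fits], indent=2)
            )
            comparison.to_frame().to_csv(outdir / "comparison.tsv", sep="\t", index=False)
            report["comparison"] = comparison.to_frame().to_dict("records")

        curve = None
        if "rarefy" in cfg["stages"]:
            grid = np.unique(
                np.round(np.geomspace(1, v.N, int(cfg["grid_points"]))).astype(np.int64)
            )
            curve = accumulation_curve(
                v, grid=grid, replicates=int(cfg["replicates"]), seed=seeds[1]
            )
            curve.to_frame().to_csv(outdir / "curve.tsv", sep="\t", index=False)
            report["curve_points"] = len(curve.N)
            logger.info("rarefaction curve with %d points, %d replicates",
                        len(curve.N), cfg["replicates"])

        if "gamma" in cfg["stages"]:
            if curve is None:
                raise PipelineConfigError("gamma stage requires the rarefy stage")
            gf = fit_gamma(curve)
            rows = [{"segment": "single", "gamma": gf.gamma, "ci95": gf.ci95,
                     "n_points": gf.n_points, "breakpoint": ""}]
            if len(curve.N) >= 6:
                pw = fit_gamma_piecewise(curve)
                rows.append({"segment": "piece1", "gamma": pw.gamma, "ci95": pw.ci95,
                             "n_points": pw.n_points, "breakpoint": pw.breakpoint})
                rows.append({"segment": "piece2", "gamma": pw.gamma2, "ci95": pw.ci95_2,
                             "n_points": pw.n_points, "breakpoint": pw.breakpoint})
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "gamma.tsv", sep="\t", index=False)
            report["gamma"] = gf.gamma
            logger.info("gamma = %.4f (ci95 %.4f)", gf.gamma, gf.ci95)

        if "extrapolate" in cfg["stages"]:
            ex = dict(cfg["extrapolate"])
            traj = default_trajectories(ex["region"])
            result = generate_at_scale(
                traj,
                int(float(ex["reads"])),
                seed=seeds[3],
                reference_richness=ex.get("reference"),
            )
            payload = {
                "region": ex["region"],
                "N_target": result.N_target,
                "params_at_N": result.params_at_N,
                "S": result.S,
                "ratio": result.ratio,
            }
            (outdir / "extrap.json").write_text(json.dumps(payload, indent=2))
            report["extrapolation"] = payload
            logger.info("extrapolated S=%d at N=%d (ratio %s)", result.S,
                        result.N_target, result.ratio)
    except SadscaleError:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
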