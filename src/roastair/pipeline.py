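"""End-to-end orchestration: generate/fit -> summarize -> simulate -> MC.

The pipeline is configuration-driven and fully deterministic under a fixed
config and seed: the manifest it writes records input paths, seeds, and a
SHA-256 hash of every artifact, so two runs of the same config can be
compared hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chamber import fit_emission_curve
from .errors import ConfigError
from .io import read_chamber_trials, write_fits, write_profile_csv
from .montecarlo import MCSpec, run_mc
from .scenario import build_schedule, default_system, exceedance, simulate_schedule
from .summary import ParticleSample, SERGroup, geometric_summary, summarize_sers
from .synthetic_data import (
    TrueEmissionParams,
    gen_chamber_series,
    reference_design,
    write_trials_csv,
    write_truth_sidecar,
)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_gen(cfg: dict, outdir: Path, seed: int) -> Path:
    """Generate synthetic chamber trials from configured ground truths."""
    design = reference_design()
    trials, truths = [], {}
    for i, spec in enumerate(cfg.get("trials", [])):
        tid = spec.get("trial_id", f"trial_{i:03d}")
        truth = TrueEmissionParams(
            ef0=spec["ef0"], ef_ss=spec.get("ef_ss", 0.0), k=spec.get("k", 1.0),
            seed=seed + i, noise_cv=spec.get("noise_cv", 0.0),
        )
        trials.append(gen_chamber_series(
            design, truth, trial_id=tid,
            analyte=spec.get("analyte", "diacetyl"),
            roast_level=spec.get("roast_level"),
            physical_form=spec.get("physical_form"),
        ))
        truths[tid] = truth
    path = outdir / "trials.csv"
    write_trials_csv(trials, path)
    write_truth_sidecar(truths, outdir / "trials_truth.json")
    return path


def _stage_fit(trials_path: Path, outdir: Path) -> tuple[Path, Path]:
    trials = read_chamber_trials(trials_path)
    fits = [fit_emission_curve(t) for t in trials]
    fits_path = outdir / "fits.json"
    write_fits(fits, fits_path)
    # Replicate summary grouped like the SER table (analyte x roast x form).
    rows = []
    groups: dict[tuple, list[float]] = {}
    for f in fits:
        if f.converged and f.roast_level and f.physical_form:
            groups.setdefault((f.analyte, f.roast_level, f.physical_form), []).append(f.ef_buildup)
    for (analyte, roast, form), values in groups.items():
        s = summarize_sers(SERGroup(analyte, roast, form, tuple(values)))
        rows.append({
            "analyte": analyte, "roast_level": roast, "physical_form": form,
            "mean": s.mean, "sd": s.sd, "cv_percent": s.cv_percent,
            "minimum": s.minimum, "maximum": s.maximum, "n": s.n,
        })
    summary_path = outdir / "ser_summary.csv"
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    return fits_path, summary_path


def _stage_particles(particles_path: Path, outdir: Path) -> Path:
    from .io import read_particles_csv

    df = read_particles_csv(particles_path)
    rows = []
    for form, grp in df.groupby("physical_form"):
        g = geometric_summary(ParticleSample(str(form), tuple(grp["diameter_cm"])))
        rows.append({"physical_form": form, "gm": g.gm, "gsd": g.gsd,
                     "minimum": g.minimum, "maximum": g.maximum, "n": g.n})
    path = outdir / "particle_summary.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    paths = []
    for name in cfg.get("scenarios", ["scenario_A"]):
        schedule = build_schedule(name)
        system = default_system(name)
        profile = simulate_schedule(schedule, system)
        prof_path = outdir / f"profile_{name}.csv"
        write_profile_csv(profile, prof_path)
        report = exceedance(profile)
        rep_path = outdir / f"exceedance_{name}.json"
        rep_path.write_text(json.dumps(report.as_dict(), indent=2))
        paths += [prof_path, rep_path]
    return paths


def _stage_mc(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    paths = []
    mc_cfg = cfg.get("monte_carlo")
    if not mc_cfg:
        return paths
    for name in cfg.get("scenarios", ["scenario_A"]):
        spec = MCSpec(
            n_iterations=int(mc_cfg.get("n_iterations", 10_000)),
            seed=seed,
            distributions=mc_cfg.get("distributions", {}),
        )
        summary = run_mc(build_schedule(name), default_system(name), spec,
                         dt_min=float(mc_cfg.get("dt_min", 0.1)))
        path = outdir / f"mc_summary_{name}.json"
        path.write_text(json.dumps(summary.as_dict(), indent=2))
        paths.append(path)
    return paths


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages and return (and write) the manifest.

    Config keys: ``seed`` (required when any stage is stochastic),
    ``generate`` (synthetic-trial ground truths), ``trials`` (path to a
    measured/fixture CSV; mutually exclusive with ``generate``),
    ``particles`` (optional diameter CSV), ``scenarios`` (preset names),
    ``monte_carlo`` (n_iterations/distributions/dt_min).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    if seed is None and (config.get("generate") or config.get("monte_carlo")):
        raise ConfigError("a seed is mandatory for stochastic stages")
    artifacts: list[Path] = []

    if config.get("generate"):
        trials_path = _stage_gen(config["generate"], outdir, int(seed))
        artifacts += [trials_path, outdir / "trials_truth.json"]
    elif config.get("trials"):
        trials_path = Path(config["trials"])
        if not trials_path.exists():
            raise ConfigError(f"trials file not found: {trials_path}")
    else:
        trials_path = None

    if trials_path is not None:
        fits_path, summary_path = _stage_fit(trials_path, outdir)
        artifacts += [fits_path, summary_path]

    if config.get("particles"):
        artifacts.append(_stage_particles(Path(config["particles"]), outdir))

    artifacts += _stage_simulate(config, outdir)
    artifacts += _stage_mc(config, outdir, int(seed) if seed is not None else 0)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
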