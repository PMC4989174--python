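"""Canned experiment recipes: the analytic scan, long traces, and sweeps.

Each recipe bundles the parameter values of one baseline experiment:

* ``fig2``  — analytic stationary distribution of the embedded chain as a
  function of the returns-to-scale exponent (weak selection, rare mutation).
* ``fig3a`` / ``fig3b`` — one long agent-based trace at constant returns
  (alpha = 1.0, rock-paper-scissors-like turnover) and at strongly
  increasing returns (alpha = 1.8, sustained punisher majority).
* ``fig4_a`` ... ``fig4_i`` — replicated parameter sweeps: alpha from three
  monomorphic initial compositions (a-c), then r, c, delta, gamma, omega
  and mu around the baseline settings (d-i).

Every run writes its CSV output(s) plus a JSON manifest holding the full
flat configuration, so re-feeding the manifest as ``--config`` reproduces
the run exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import __version__
from .analytic import alpha_scan
from .params import GameParameters
from .simulate import PopulationState, SimulationConfig, parameter_sweep, run_simulation

__all__ = ["ExperimentRecipe", "RECIPES", "run_recipe", "write_manifest"]

log = logging.getLogger("scalepgg")

#: Baseline game parameters shared by all experiments.
BASELINE = dict(M=100, N=5, c=1.0, r=3.0, delta=1.0, gamma=0.3)

#: Simulation-side defaults (strong selection, small finite mutation).
SIM_BASELINE = dict(omega=0.5, mu=0.001)

FIG3_INITIAL = (30, 40, 30)
FIG4_PERIODS = 100_000
FIG4_REPLICATES = 20
ALPHA_GRID_FULL = [round(a, 1) for a in np.arange(1.0, 2.0001, 0.1)]
ALPHA_GRID_SWEEP = [round(a, 1) for a in np.arange(1.0, 1.5001, 0.1)]


@dataclass
class ExperimentRecipe:
    """A named, parameter-complete experiment."""

    name: str
    runner: Callable[..., dict] = field(repr=False)
    description: str = ""


def write_manifest(path: Path, settings: dict[str, Any], extras: dict[str, Any]) -> None:
    """Write a JSON run manifest: flat settings plus provenance fields."""
    doc = dict(settings)
    doc.update(extras)
    doc["code_version"] = __version__
    path.write_text(json.dumps(doc, indent=2, default=str) + "\n")


def _scaled(value: int, scale: float, floor: int = 1) -> int:
    return max(floor, int(round(value / scale)))


def _run_fig2(outdir: Path, seed: int, scale: float, overrides: dict) -> dict:
    params = GameParameters(**{**BASELINE, "omega": 0.1, "mu": 0.0, "alpha": 1.0,
                               **{k: v for k, v in overrides.items() if k != "alpha_grid"}})
    grid = overrides.get("alpha_grid", ALPHA_GRID_FULL)
    t0 = time.perf_counter()
    out_csv = outdir / "fig2_alpha_scan.csv"
    table = alpha_scan(params, grid, out=out_csv)
    wall = time.perf_counter() - t0
    settings = params.to_dict() | {"alpha_grid": list(grid), "seed": seed}
    write_manifest(outdir / "fig2_manifest.json", settings,
                   {"recipe": "fig2", "wall_time_s": wall, "outputs": [out_csv.name]})
    return {"table": table, "outputs": [out_csv]}


def _run_fig3(alpha: float, tag: str, outdir: Path, seed: int, scale: float,
              overrides: dict) -> dict:
    params = GameParameters(**{**BASELINE, **SIM_BASELINE, "alpha": alpha, **overrides})
    periods = _scaled(overrides.get("periods", 100_000), scale)
    config = SimulationConfig(
        periods=periods,
        seed=seed,
        initial_state=PopulationState(*overrides.get("initial_state", FIG3_INITIAL)),
        burn_in=overrides.get("burn_in", 0),
        record_every=overrides.get("record_every", 10),
    )
    t0 = time.perf_counter()
    trace = run_simulation(config, params)
    wall = time.perf_counter() - t0
    out_csv = outdir / f"{tag}_trace.csv"
    trace.write_csv(out_csv)
    settings = params.to_dict() | {
        "periods": config.periods, "seed": seed, "burn_in": config.burn_in,
        "record_every": config.record_every,
        "initial_state": list(config.initial_state.as_tuple()),
    }
    write_manifest(outdir / f"{tag}_manifest.json", settings,
                   {"recipe": tag, "wall_time_s": wall, "outputs": [out_csv.name],
                    "mean_frequencies": trace.mean_frequencies.tolist()})
    log.info("%s: mean frequencies C=%.3f D=%.3f P=%.3f", tag, *trace.mean_frequencies)
    return {"trace": trace, "outputs": [out_csv]}


def _run_fig4(panel: str, param_name: str, grid: list, alpha: float,
              initial: tuple[int, int, int], outdir: Path, seed: int, scale: float,
              overrides: dict) -> dict:
    params = GameParameters(**{**BASELINE, **SIM_BASELINE, "alpha": alpha,
                               **{k: v for k, v in overrides.items()
                                  if k in GameParameters.__dataclass_fields__}})
    periods = _scaled(overrides.get("periods", FIG4_PERIODS), scale)
    replicates = _scaled(overrides.get("replicates", FIG4_REPLICATES), scale)
    config = SimulationConfig(
        periods=periods, seed=seed,
        initial_state=PopulationState(*overrides.get("initial_state", initial)),
        burn_in=overrides.get("burn_in", 0),
        record_every=overrides.get("record_every", 1),
    )
    grid = overrides.get("grid", grid)
    t0 = time.perf_counter()
    table = parameter_sweep(params, param_name, grid, config, replicates)
    wall = time.perf_counter() - t0
    tag = f"fig4_{panel}"
    out_csv = outdir / f"{tag}_sweep.csv"
    table.to_csv(out_csv, index=False)
    settings = params.to_dict() | {
        "periods": config.periods, "seed": seed, "replicates": replicates,
        "burn_in": config.burn_in, "record_every": config.record_every,
        "initial_state": list(config.initial_state.as_tuple()),
        "param_name": param_name, "grid": [list(g) if isinstance(g, (tuple, list)) else g
                                           for g in grid],
    }
    write_manifest(outdir / f"{tag}_manifest.json", settings,
                   {"recipe": tag, "wall_time_s": wall, "outputs": [out_csv.name]})
    return {"table": table, "outputs": [out_csv]}


def _fig4_recipe(panel: str, param_name: str, grid: list, alpha: float,
                 initial: tuple[int, int, int]):
    def runner(outdir: Path, seed: int, scale: float, overrides: dict) -> dict:
        return _run_fig4(panel, param_name, grid, alpha, initial, outdir, seed,
                         scale, overrides)
    return runner


RECIPES: dict[str, ExperimentRecipe] = {
    "fig2": ExperimentRecipe(
        "fig2", _run_fig2,
        "analytic stationary distribution vs alpha (rare-mutation limit)"),
    "fig3a": ExperimentRecipe(
        "fig3a", lambda outdir, seed, scale, overrides:
            _run_fig3(1.0, "fig3a", outdir, seed, scale, overrides),
        "long trace at constant returns (alpha = 1.0)"),
    "fig3b": ExperimentRecipe(
        "fig3b", lambda outdir, seed, scale, overrides:
            _run_fig3(1.8, "fig3b", outdir, seed, scale, overrides),
        "long trace at increasing returns (alpha = 1.8)"),
    "fig4_a": ExperimentRecipe(
        "fig4_a", _fig4_recipe("a", "alpha", ALPHA_GRID_SWEEP, 1.0, (100, 0, 0)),
        "alpha sweep from an all-cooperator start"),
    "fig4_b": ExperimentRecipe(
        "fig4_b", _fig4_recipe("b", "alpha", ALPHA_GRID_SWEEP, 1.0, (0, 100, 0)),
        "alpha sweep from an all-defector start"),
    "fig4_c": ExperimentRecipe(
        "fig4_c", _fig4_recipe("c", "alpha", ALPHA_GRID_SWEEP, 1.0, (0, 0, 100)),
        "alpha sweep from an all-punisher start"),
    "fig4_d": ExperimentRecipe(
        "fig4_d", _fig4_recipe("d", "r", [1.5, 2.0, 2.5, 3.0, 3.5, 4.0], 1.0,
                               FIG3_INITIAL),
        "return-multiplier sweep at constant returns"),
    "fig4_e": ExperimentRecipe(
        "fig4_e", _fig4_recipe("e", "c", [0.5, 0.75, 1.0, 1.25, 1.5, 2.0], 1.8,
                               FIG3_INITIAL),
        "contribution-cost sweep at increasing returns"),
    "fig4_f": ExperimentRecipe(
        "fig4_f", _fig4_recipe("f", "delta", [0.0, 0.25, 0.5, 1.0, 1.5, 2.0], 1.8,
                               FIG3_INITIAL),
        "punishment-strength sweep at increasing returns"),
    "fig4_g": ExperimentRecipe(
        "fig4_g", _fig4_recipe("g", "gamma", [0.0, 0.15, 0.3, 0.5, 0.75, 1.0], 1.8,
                               FIG3_INITIAL),
        "punishment-cost sweep at increasing returns"),
    "fig4_h": ExperimentRecipe(
        "fig4_h", _fig4_recipe("h", "omega", [0.05, 0.1, 0.25, 0.5, 0.75, 1.0], 1.8,
                               FIG3_INITIAL),
        "selection-strength sweep at increasing returns"),
    "fig4_i": ExperimentRecipe(
        "fig4_i", _fig4_recipe("i", "mu", [1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2], 1.8,
                               FIG3_INITIAL),
        "mutation-rate sweep at increasing returns"),
}


def run_recipe(name: str, outdir: str | Path, seed: int = 1, scale: float = 1.0,
               overrides: dict | None = None) -> dict:
    """Execute a registered recipe, writing CSV outputs and a JSON manifest.

    ``scale > 1`` divides period and replicate counts for quick runs; the
    scaled values are recorded in the manifest.
    """
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; choose from {sorted(RECIPES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return RECIPES[name].runner(outdir, seed, scale, dict(overrides or {}))
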