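"""Sweep runner and command-line interface.

Reproduces the figure-level experiments as machine-readable tables: gain
sweeps, disturbance/sensor time-scale sweeps, and SSA-vs-analytics
overlays, driven by the named figure fixtures or by user YAML configs.
Outputs are tables (CSV) and comparison reports (JSON); plotting is left
to downstream tools.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuits import (
    CircuitModel,
    CircuitTopology,
    DisturbanceMode,
    circuit_from_dict,
    feedback_gain,
    load_fixture,
    list_fixtures,
    solve_steady_means,
)
from .exceptions import PidNoiseError
from .formulas import (
    NoiseInputs,
    cv2_for_topology,
    cv2_open_loop,
    noise_inputs_from_circuit,
)
from .lna import decompose_noise
from .ssa import default_burn_in, simulate_stats, validate_against_lna

__all__ = ["SweepConfig", "run_sweep", "reproduce_fig5", "cli"]

_CIRCUIT_VARIABLES = ("h", "z_c", "k_z", "gamma_x", "gamma_z")


@dataclass
class SweepConfig:
    """One sweep: a circuit and/or abstract noise inputs, the swept
    variable, the grid, the engines, and the normalization convention.

    ``gain`` sweeps require ``noise_inputs`` (formulas engine); circuit
    engines sweep the physical knobs (``h``, ``z_c``, ``k_z``,
    ``gamma_x``, ``gamma_z``) with the means re-solved per point — the
    primary gain knob being the Hill coefficient at fixed repression
    strength.  ``couple_kz_to_gamma_z`` ties ``k_z = γ_z`` during a
    ``gamma_z`` sweep (the derivative-validation convention, which keeps
    ``z̄ = ȳ``).
    """

    variable: str
    grid: Sequence[float]
    circuit: Optional[CircuitModel] = None
    noise_inputs: Optional[NoiseInputs] = None
    engines: Sequence[str] = ("formulas",)
    normalization: str = "none"  # none | open_loop_total | zero_gain_total
    couple_kz_to_gamma_z: bool = False
    n_reps: int = 8
    t_end: Optional[float] = None
    burn_in: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        grid = list(self.grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sweep grid must be non-empty, strictly increasing")
        if self.variable == "gain":
            if self.noise_inputs is None:
                raise ValueError("a gain sweep needs noise_inputs")
        elif self.variable in _CIRCUIT_VARIABLES:
            if self.circuit is None:
                raise ValueError(
                    f"sweeping {self.variable!r} needs a circuit")
        else:
            raise ValueError(f"unknown sweep variable {self.variable!r}")
        for e in self.engines:
            if e not in ("formulas", "lna", "ssa"):
                raise ValueError(f"unknown engine {e!r}")

    @classmethod
    def from_fixture(cls, name: str, **overrides) -> "SweepConfig":
        doc = load_fixture(name)
        return cls.from_dict(doc, **overrides)

    @classmethod
    def from_dict(cls, doc: dict, **overrides) -> "SweepConfig":
        sweep = dict(doc.get("sweep", {}))
        sweep.update(overrides)
        circuit = (circuit_from_dict(doc["circuit"])
                   if "circuit" in doc else None)
        inputs = None
        if "noise_inputs" in doc:
            ni = {k: float(v) for k, v in doc["noise_inputs"].items()
                  if not k.endswith("_alt")}
            inputs = NoiseInputs(**ni)
        return cls(circuit=circuit, noise_inputs=inputs, **sweep)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SweepConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()),
                             **overrides)


def _apply_variable(circuit: CircuitModel, variable: str, value: float,
                    couple_kz: bool) -> CircuitModel:
    if variable == "h":
        return replace(circuit,
                       regulation=replace(circuit.regulation,
                                          hill_coeff=value))
    if variable == "z_c":
        return replace(circuit,
                       regulation=replace(circuit.regulation,
                                          half_max=value))
    if variable == "k_z":
        return replace(circuit, sensor=replace(circuit.sensor,
                                               burst_rate=value))
    if variable == "gamma_x":
        if circuit.disturbance.mode is not DisturbanceMode.BURSTY:
            raise ValueError("gamma_x sweep needs a bursty disturbance")
        params = replace(circuit.disturbance.params, decay_rate=value)
        return replace(circuit,
                       disturbance=replace(circuit.disturbance, params=params))
    # gamma_z
    sensor = replace(circuit.sensor, decay_rate=value)
    if couple_kz:
        sensor = replace(sensor, burst_rate=value)
    return replace(circuit, sensor=sensor)


def _reference(config: SweepConfig) -> float:
    """Open-loop / zero-gain total noise used for normalization (the two
    conventions coincide: every controller's split reduces to the
    open-loop one at zero gain)."""
    if config.noise_inputs is not None:
        return cv2_open_loop(config.noise_inputs).total
    c = config.circuit
    open_circuit = CircuitModel(
        topology=CircuitTopology.OPEN, disturbance=c.disturbance,
        target=c.target)
    return decompose_noise(open_circuit).total


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """One row per (grid point × engine): components, total, gain, SE for
    the stochastic engine.  A failed grid point is flagged (NaNs,
    ``flagged=True``) and the sweep continues."""
    ref = 1.0
    if config.normalization != "none":
        ref = _reference(config)
    rows = []
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.grid) * len(list(config.engines)))
    k = 0
    for v in config.grid:
        for engine in config.engines:
            row = {"value": float(v), "engine": engine, "flagged": False,
                   "intrinsic": np.nan, "external": np.nan,
                   "controller": np.nan, "total": np.nan, "se": np.nan,
                   "gain": np.nan}
            try:
                if engine == "formulas" and config.variable == "gain":
                    inputs = replace(config.noise_inputs, gain=float(v))
                    topo = (config.circuit.topology if config.circuit
                            else CircuitTopology.PROPORTIONAL)
                    dec = cv2_for_topology(topo, inputs)
                    row["gain"] = float(v)
                else:
                    circ = _apply_variable(config.circuit, config.variable,
                                           float(v),
                                           config.couple_kz_to_gamma_z)
                    means = solve_steady_means(circ)
                    row["gain"] = feedback_gain(circ, means)
                    if engine == "formulas":
                        dec = cv2_for_topology(
                            circ.topology, noise_inputs_from_circuit(circ,
                                                                     means))
                    elif engine == "lna":
                        dec = decompose_noise(circ, means=means)
                    else:  # ssa
                        t_end = config.t_end or (
                            default_burn_in(circ) + 400.0)
                        stats = simulate_stats(
                            circ, n_reps=config.n_reps, t_end=t_end,
                            seed=int(seeds[k]), burn_in=config.burn_in)
                        row["total"] = stats.cv2_y / ref
                        row["se"] = stats.se_cv2 / ref
                        rows.append(row)
                        continue
                row.update(intrinsic=dec.intrinsic / ref,
                           external=dec.external / ref,
                           controller=dec.controller / ref,
                           total=dec.total / ref)
            except PidNoiseError as exc:
                row["flagged"] = True
                row["error"] = str(exc)
            finally:
                k += 1
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["normalization"] = config.normalization
    df.attrs["reference_total"] = ref
    df.attrs["variable"] = config.variable
    df.attrs["seed"] = config.seed
    df.attrs["version"] = __version__
    return df


def reproduce_fig5(*, gamma_z_grid: Sequence[float] | None = None,
                   n_reps: int = 12, t_end: float | None = None,
                   burn_in: float | None = None, seed: int = 0
                   ) -> tuple[pd.DataFrame, dict]:
    """SSA validation of the derivative controller at the printed
    parameters: ``k_y=2, γ_y=0.2, ⟨B_y⟩=20, ⟨B_z⟩=1, k_z=γ_z, h=1``, no
    external disturbance.  ``γ_z`` is swept (``f_d = γ_y/γ_z``); each point
    compares the simulated ``CV²_Y ± SE`` with the closed-form derivative
    noise at ``CV²_X = 0`` and reports the z-score."""
    base = circuit_from_dict(load_fixture("fig5")["circuit"])
    if gamma_z_grid is None:
        gamma_z_grid = load_fixture("fig5")["sweep"]["grid"]
    seeds = np.random.SeedSequence(seed).generate_state(len(gamma_z_grid))
    rows = []
    for gz, s in zip(gamma_z_grid, seeds):
        circ = _apply_variable(base, "gamma_z", float(gz), True)
        te = t_end if t_end is not None else default_burn_in(circ) + 2000.0
        stats = simulate_stats(circ, n_reps=n_reps, t_end=te,
                               seed=int(s), burn_in=burn_in)
        predicted = cv2_for_topology(
            CircuitTopology.DERIVATIVE, noise_inputs_from_circuit(circ))
        z = (stats.cv2_y - predicted.total) / stats.se_cv2
        rows.append({
            "gamma_z": float(gz),
            "f_d": circuit_gain_fd(circ),
            "cv2_sim": stats.cv2_y, "se": stats.se_cv2,
            "cv2_predicted": predicted.total,
            "z_score": z, "flagged": bool(abs(z) > 3.0),
            "mean_y_sim": stats.mean_y, "n_replicates": n_reps,
            "t_end": te,
        })
    df = pd.DataFrame(rows)
    report = {
        "n_points": len(df),
        "n_flagged": int(df["flagged"].sum()),
        "max_abs_z": float(df["z_score"].abs().max()),
        "seed": seed,
        "version": __version__,
    }
    return df, report


def circuit_gain_fd(circuit: CircuitModel) -> float:
    return feedback_gain(circuit)


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

def _log(msg: str) -> None:
    click.echo(f"pidnoise {__version__} | {msg}", err=True)


def _write_table(df: pd.DataFrame, out: Optional[str], seed: int) -> None:
    header = f"# pidnoise {__version__} seed={seed}\n"
    text = header + df.to_csv(index=False)
    if out:
        Path(out).write_text(text)
        _log(f"wrote {out}")
    else:
        click.echo(text, nl=False)


@click.group()
@click.version_option(__version__, prog_name="pidnoise")
def cli() -> None:
    """Noise analysis of P/I/D biochemical controllers in bursty gene
    circuits."""


@cli.command()
@click.argument("config")
@click.option("--out", "-o", default=None, help="Output CSV path (stdout "
              "if omitted).")
@click.option("--seed", default=0, show_default=True, type=int)
def sweep(config: str, out: Optional[str], seed: int) -> None:
    """Run a sweep from a fixture name or a YAML config path."""
    if Path(config).exists():
        cfg = SweepConfig.from_yaml(config, seed=seed)
    else:
        cfg = SweepConfig.from_fixture(config, seed=seed)
    _log(f"sweep variable={cfg.variable} engines={list(cfg.engines)} "
         f"seed={seed}")
    df = run_sweep(cfg)
    _write_table(df, out, seed)
    if df["flagged"].any():
        _log(f"{int(df['flagged'].sum())} flagged grid points")
        sys.exit(1)


@cli.command()
@click.option("--out", "-o", default=None, help="Output CSV path.")
@click.option("--report", default=None, help="JSON comparison-report path.")
@click.option("--n-reps", default=8, show_default=True, type=int)
@click.option("--t-end", default=None, type=float)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--grid", default=None,
              help="Comma-separated gamma_z grid (defaults to the fixture).")
def fig5(out, report, n_reps, t_end, seed, grid) -> None:
    """Derivative-controller SSA validation against the closed form."""
    gz = [float(v) for v in grid.split(",")] if grid else None
    _log(f"derivative validation n_reps={n_reps} seed={seed}")
    df, rep = reproduce_fig5(gamma_z_grid=gz, n_reps=n_reps, t_end=t_end,
                             seed=seed)
    _write_table(df, out, seed)
    if report:
        Path(report).write_text(json.dumps(rep, indent=2))
        _log(f"wrote {report}")
    _log(f"max |z| = {rep['max_abs_z']:.2f}, flagged {rep['n_flagged']}")
    if rep["n_flagged"]:
        sys.exit(1)


@cli.command()
@click.argument("fixture")
@click.option("--n-reps", default=8, show_default=True, type=int)
@click.option("--t-end", default=500.0, show_default=True, type=float)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", "-o", default=None, help="JSON output path.")
def validate(fixture, n_reps, t_end, seed, out) -> None:
    """Simulate a fixture circuit and compare CV² with the moment solver."""
    circ = circuit_from_dict(load_fixture(fixture)["circuit"])
    rec = validate_against_lna(circ, n_reps=n_reps, t_end=t_end, seed=seed)
    text = json.dumps(rec, indent=2)
    if out:
        Path(out).write_text(text)
        _log(f"wrote {out}")
    else:
        click.echo(text)
    if rec["flagged"]:
        _log(f"|z| = {abs(rec['z_score']):.2f} > 3")
        sys.exit(1)


@cli.command("show-fixture")
@click.argument("name", required=False)
def show_fixture(name: Optional[str]) -> None:
    """Print a named fixture (or list the available ones)."""
    if name is None:
        for n in list_fixtures():
            click.echo(n)
        return
    click.echo(yaml.safe_dump(load_fixture(name), sort_keys=False))
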