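"""Run configuration, validation and the framework dispatcher.

A run is described by a small YAML document (all keys optional):

.. code-block:: yaml

    framework: ode          # ode | reduced | scalar | rdme
    lattice: {rows: 20, cols: 20, bc: zero}
    t_end: 3000.0           # minutes
    output_dt: 1.0
    seed: 0
    s: 1.0                  # feedback-weakening scaling alpha_N -> alpha_N/s
    volume: 50.0            # um^3, required for the rdme framework
    replicates: 1           # rdme only
    reduction_pair: [M, n]  # reduced framework only
    parameters: {alpha_N: 6.0, ...}   # overrides of the shipped defaults

Unspecified parameters fall back to the shipped central values.  The
dispatcher writes a tidy trajectory CSV, a population-summary CSV and a
machine-readable manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from . import __version__ as _pkg_version
from .lattice import build_hex_lattice
from .params import SPECIES, ModelParameters, default_parameters
from . import ode_grid, rdme, reduction, patterning

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "run"]

_FRAMEWORKS = ("ode", "reduced", "scalar", "rdme")
_PARAM_FIELDS = {
    f.name for f in dataclasses.fields(ModelParameters) if f.name != "intervals"
}
_KNOWN_KEYS = {
    "framework", "lattice", "t_end", "output_dt", "seed", "s", "volume",
    "replicates", "reduction_pair", "parameters", "out",
}


class ConfigError(ValueError):
    """Validation failure; ``problems`` lists every offending field."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class RunConfig:
    framework: str = "ode"
    rows: int = 20
    cols: int = 20
    bc: str = "zero"
    t_end: float = 3000.0
    output_dt: float = 1.0
    seed: int = 0
    s: float = 1.0
    volume: float | None = None
    replicates: int = 1
    reduction_pair: tuple[str, str] = ("M", "n")
    parameter_overrides: dict = field(default_factory=dict)
    out: str = "."

    def parameters(self) -> ModelParameters:
        params = default_parameters()
        if self.parameter_overrides:
            params = params.replace(**self.parameter_overrides)
        if self.s != 1.0:
            params = params.scale_alpha_N(self.s)
        return params

    def to_dict(self) -> dict:
        return {
            "framework": self.framework,
            "lattice": {"rows": self.rows, "cols": self.cols, "bc": self.bc},
            "t_end": self.t_end,
            "output_dt": self.output_dt,
            "seed": self.seed,
            "s": self.s,
            "volume": self.volume,
            "replicates": self.replicates,
            "reduction_pair": list(self.reduction_pair),
            "parameters": dict(self.parameter_overrides),
            "out": self.out,
        }


def _validate(raw: dict) -> RunConfig:
    problems: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")

    cfg = RunConfig()
    cfg.framework = raw.get("framework", cfg.framework)
    if cfg.framework not in _FRAMEWORKS:
        problems.append(f"framework must be one of {_FRAMEWORKS}, got {cfg.framework!r}")

    lat = raw.get("lattice", {}) or {}
    cfg.rows = int(lat.get("rows", cfg.rows))
    cfg.cols = int(lat.get("cols", cfg.cols))
    cfg.bc = lat.get("bc", cfg.bc)
    if cfg.rows < 1 or cfg.cols < 1:
        problems.append("lattice rows and cols must be >= 1")
    if cfg.bc not in ("zero", "periodic"):
        problems.append(f"lattice bc must be 'zero' or 'periodic', got {cfg.bc!r}")

    for key, cast in (("t_end", float), ("output_dt", float), ("s", float)):
        try:
            setattr(cfg, key, cast(raw.get(key, getattr(cfg, key))))
            if getattr(cfg, key) <= 0:
                problems.append(f"{key} must be positive")
        except (TypeError, ValueError):
            problems.append(f"{key} must be a number")
    try:
        cfg.seed = int(raw.get("seed", cfg.seed))
    except (TypeError, ValueError):
        problems.append("seed must be an integer")
    cfg.replicates = int(raw.get("replicates", cfg.replicates))
    if cfg.replicates < 1:
        problems.append("replicates must be >= 1")
    if raw.get("volume") is not None:
        cfg.volume = float(raw["volume"])
        if cfg.volume <= 0:
            problems.append("volume must be positive")
    if cfg.framework == "rdme" and cfg.volume is None:
        problems.append("framework 'rdme' requires a voxel volume")
    pair = raw.get("reduction_pair", list(cfg.reduction_pair))
    cfg.reduction_pair = tuple(pair)
    if cfg.framework == "reduced" and cfg.reduction_pair not in {
        (x, y) for _, x, y in reduction.ADMISSIBLE_PAIRS
    }:
        problems.append(f"reduction_pair {pair!r} is not an admissible reduction")

    overrides = raw.get("parameters", {}) or {}
    for name, value in overrides.items():
        if name not in _PARAM_FIELDS:
            problems.append(f"unknown parameter {name!r}")
        elif not isinstance(value, (int, float)) or value <= 0:
            problems.append(f"parameter {name!r} must be a positive number, got {value!r}")
    cfg.parameter_overrides = dict(overrides)
    cfg.out = str(raw.get("out", cfg.out))

    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    return _validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# -- dispatch ------------------------------------------------------------------

def _simulate_reduced(cfg: RunConfig, lattice, params):
    rp = reduction.reduce_model(params, cfg.reduction_pair)
    mu_x = params.mu(cfg.reduction_pair[0])
    K = lattice.n_nodes
    rng = np.random.default_rng(cfg.seed)
    x0 = rng.random(K)
    y0 = rng.random(K)

    def fun(tau, z):
        x, y = z[:K], z[K:]
        dx, dy = reduction.rhs_reduced(rp.reduction_type, lattice, x, y, rp)
        return np.concatenate([dx, dy])

    tau_end = cfg.t_end * mu_x
    tau_eval = np.arange(0.0, cfg.t_end + 0.5 * cfg.output_dt, cfg.output_dt) * mu_x
    sol = solve_ivp(fun, (0.0, tau_end), np.concatenate([x0, y0]),
                    t_eval=np.clip(tau_eval, 0, tau_end), rtol=1e-8, atol=1e-10,
                    method="LSODA")
    if not sol.success:
        raise RuntimeError(f"reduced-model integration failed: {sol.message}")
    x = sol.y[:K].T
    times = sol.t / mu_x
    df = pd.DataFrame(
        {
            "time": np.repeat(times, K),
            "cell_id": np.tile(np.arange(K), times.size),
            "species": "x",
            "value": x.ravel(),
        }
    )
    P = reduction.map_x_to_P(x, params)
    dfP = df.copy()
    dfP["species"] = "P_mapped"
    dfP["value"] = P.ravel()
    return pd.concat([df, dfP], ignore_index=True), reduction.reduction_table(params)


def _simulate_scalar(cfg: RunConfig, lattice, params):
    a, b = reduction.compute_ab(params)
    mu_x = params.mu(cfg.reduction_pair[0])
    K = lattice.n_nodes
    rng = np.random.default_rng(cfg.seed)
    x0 = rng.random(K)

    def fun(tau, x):
        return reduction.rhs_scalar(lattice, x, a, b, params.k, params.h)

    tau_end = cfg.t_end * mu_x
    tau_eval = np.arange(0.0, cfg.t_end + 0.5 * cfg.output_dt, cfg.output_dt) * mu_x
    sol = solve_ivp(fun, (0.0, tau_end), x0, t_eval=np.clip(tau_eval, 0, tau_end),
                    rtol=1e-8, atol=1e-10, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"scalar-model integration failed: {sol.message}")
    times = sol.t / mu_x
    return pd.DataFrame(
        {
            "time": np.repeat(times, K),
            "cell_id": np.tile(np.arange(K), times.size),
            "species": "x",
            "value": sol.y.T.ravel(),
        }
    )


def run(cfg: RunConfig, verbose: bool = False) -> dict:
    """Execute the configured framework and write artifacts to ``cfg.out``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    t_start = time.time()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    lattice = build_hex_lattice(cfg.rows, cfg.cols, cfg.bc)
    params = cfg.parameters()
    artifacts: dict[str, str] = {}

    def _log(msg):
        if verbose:
            print(msg)

    if cfg.framework == "ode":
        init = ode_grid.synthetic_initial_conditions(lattice, None, cfg.seed, params=params)
        _log(f"integrating ODE on {cfg.rows}x{cfg.cols} ({cfg.bc}) to t={cfg.t_end} min")
        traj = ode_grid.simulate_ode(lattice, params, init, cfg.t_end,
                                     output_dt=cfg.output_dt, seed=cfg.seed)
        fates = ode_grid.classify_fates(traj)
        summary = ode_grid.population_summary(traj, fates)
        traj.to_dataframe().to_csv(out / "trajectory.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        artifacts = {"trajectory": "trajectory.csv", "summary": "summary.csv"}
    elif cfg.framework == "reduced":
        _log("integrating reduced model")
        df, table = _simulate_reduced(cfg, lattice, params)
        df.to_csv(out / "trajectory.csv", index=False)
        table.to_csv(out / "reductions.csv", index=False)
        artifacts = {"trajectory": "trajectory.csv", "reductions": "reductions.csv"}
    elif cfg.framework == "scalar":
        _log("integrating scalar model")
        df = _simulate_scalar(cfg, lattice, params)
        df.to_csv(out / "trajectory.csv", index=False)
        artifacts = {"trajectory": "trajectory.csv"}
    elif cfg.framework == "rdme":
        _log(f"running {cfg.replicates} SSA replicate(s) at V={cfg.volume} um^3")
        net = rdme.build_network(params, cfg.volume, lattice)
        ss = np.random.SeedSequence(cfg.seed)
        frames = []
        states = []
        for rep, child in enumerate(ss.spawn(cfg.replicates)):
            s_init, s_run = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in child.spawn(2))
            init = rdme.synthetic_initial_counts(lattice, cfg.volume, s_init, params=params)
            traj = rdme.ssa_simulate(lattice, net, init, cfg.t_end, s_run,
                                     output_dt=max(cfg.output_dt, 1.0))
            states.append(traj.stationary_mean("P"))
            df = pd.DataFrame(
                {
                    "time": np.repeat(traj.t, lattice.n_nodes * 6),
                    "voxel_id": np.tile(np.repeat(np.arange(lattice.n_nodes), 6), traj.t.size),
                    "species": np.tile(np.array(rdme.COUNT_SPECIES), traj.t.size * lattice.n_nodes),
                    "count": traj.X.ravel(),
                    "replicate": rep,
                }
            )
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(out / "trajectory.csv", index=False)
        estimate = patterning.estimate_pattern_quality(states, lattice)
        pd.DataFrame(
            [
                {
                    "p_hat": estimate.p_hat,
                    "ci_lower": estimate.lower,
                    "ci_upper": estimate.upper,
                    "n_couplings": estimate.denominator,
                    "n_replicates": estimate.replicates,
                }
            ]
        ).to_csv(out / "patterning.csv", index=False)
        artifacts = {"trajectory": "trajectory.csv", "patterning": "patterning.csv"}
    else:  # pragma: no cover - guarded by validation
        raise ConfigError([f"unknown framework {cfg.framework!r}"])

    manifest = {
        "package_version": _pkg_version,
        "config": cfg.to_dict(),
        "artifacts": artifacts,
        "wall_clock_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
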