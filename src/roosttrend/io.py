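"""File formats, run configuration and pipeline entry points.

Formats (all plain text, comma-separated with headers, UTF-8):

* camp count table: rows of ``date`` (ISO year-month), ``camp_id``,
  ``count`` and optionally ``method`` and ``surveyed``; one row per
  camp-month.  Months with no surveyed rows are *missing*, not zero.
* cyclone schedule: a ``date`` column of ISO year-months (optional ``name``).
* posterior run directory: ``draws.csv`` (chain, iteration, one column per
  parameter), ``states_total.csv`` / ``states_camp.csv`` (thinned state
  draws, one column per month), ``meta.json`` (axis, counts, schedule,
  config, seed) and ``diagnostics.txt``.

Every stochastic artifact records its seed; re-running with the same seed
and configuration reproduces it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import CycloneSchedule, Params
from .inference import McmcConfig, PosteriorDraws, fit
from .series import CountSeries, TimeAxis
from .synthetic_data import Scenario, SimulatedDataset, default_params, \
    default_scenario, simulate

__all__ = ["read_counts", "write_counts", "read_schedule", "write_schedule",
           "write_posterior", "read_posterior", "write_truth",
           "RunConfig", "run_command"]


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _parse_periods(dates) -> pd.PeriodIndex:
    try:
        return pd.PeriodIndex(pd.to_datetime(dates, format="mixed"), freq="M")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date(s) in count table: {exc}") from exc


def read_counts(path) -> CountSeries:
    """Read a per-camp count table and aggregate to monthly totals.

    The month axis runs contiguously from the earliest to the latest date in
    the table; months with no surveyed rows are marked missing.  Rows with
    ``surveyed`` false flag a month as surveyed-but-empty only if no other
    row covers it with a count.
    """
    df = pd.read_csv(path)
    required = {"date", "camp_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    periods = _parse_periods(df["date"])
    df = df.assign(_period=periods)
    if "surveyed" not in df.columns:
        df["surveyed"] = True
    df["surveyed"] = df["surveyed"].fillna(True).astype(bool)

    dup = df.duplicated(subset=["_period", "camp_id"])
    if dup.any():
        bad = df.loc[dup, ["date", "camp_id"]]
        raise ValueError(f"duplicate camp-month rows: {bad.values.tolist()[:5]}")
    if (df.loc[df.surveyed, "count"] < 0).any():
        raise ValueError("negative counts are not admissible")

    start, end = periods.min(), periods.max()
    axis = TimeAxis(n_months=(end - start).n + 1, start_month=start.month,
                    start_year=start.year)
    y = np.full(axis.n_months, np.nan)
    surveyed = df[df.surveyed]
    for period, grp in surveyed.groupby("_period"):
        y[(period - start).n] = grp["count"].sum()
    return CountSeries(y=y, axis=axis)


def write_counts(per_camp: pd.DataFrame, path) -> None:
    """Write a per-camp count table (columns date, camp_id, count, ...)."""
    per_camp.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cyclone schedules
# ---------------------------------------------------------------------------

def read_schedule(path, axis: TimeAxis, ramp_length: int = 12,
                  indicator: str = "ramp") -> CycloneSchedule:
    """Read cyclone event dates (a ``date`` column of year-months) and map
    them to month indices on ``axis``."""
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValueError("schedule file must have a 'date' column")
    periods = _parse_periods(df["date"])
    events = sorted(axis.index_of(p.year, p.month) for p in periods)
    return CycloneSchedule(tuple(events), ramp_length, indicator)


def write_schedule(schedule: CycloneSchedule, axis: TimeAxis, path) -> None:
    dates = [f"{axis.year_of(e)}-{int(axis.calendar_month(e)):02d}"
             for e in schedule.events]
    pd.DataFrame({"date": dates}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Posterior artifacts
# ---------------------------------------------------------------------------

def write_truth(dataset: SimulatedDataset, path) -> None:
    """Sidecar with the generating parameters and latent states (for
    recovery tests against a simulated dataset)."""
    truth = {
        "params": dataclasses.asdict(dataset.params),
        "schedule": {"events": list(dataset.schedule.events),
                     "ramp_length": dataset.schedule.ramp_length,
                     "indicator": dataset.schedule.indicator},
        "total": dataset.truth.total.tolist(),
        "in_camp": dataset.truth.in_camp.tolist(),
    }
    Path(path).write_text(json.dumps(truth, indent=1))


def write_posterior(draws: PosteriorDraws, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws.param_draws().to_csv(out / "draws.csv", index=False)
    if draws.states_total is not None:
        for name, arr in (("states_total", draws.states_total),
                          ("states_camp", draws.states_camp)):
            n_c, n_k, T = arr.shape
            df = pd.DataFrame(arr.reshape(n_c * n_k, T),
                              columns=[f"m{t}" for t in range(T)])
            df.insert(0, "iteration", np.tile(draws.state_iters, n_c))
            df.insert(0, "chain", np.repeat(np.arange(n_c), n_k))
            df.to_csv(out / f"{name}.csv", index=False)
    meta = {
        "version": __version__,
        "config": dataclasses.asdict(draws.config) if draws.config else None,
        "schedule": ({"events": list(draws.schedule.events),
                      "ramp_length": draws.schedule.ramp_length,
                      "indicator": draws.schedule.indicator}
                     if draws.schedule else None),
        "axis": ({"n_months": draws.data.axis.n_months,
                  "start_month": draws.data.axis.start_month,
                  "start_year": draws.data.axis.start_year}
                 if draws.data is not None else None),
        "y": ([None if np.isnan(v) else v for v in draws.data.y]
              if draws.data is not None else None),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    rh = draws.rhat()
    lines = ["parameter rhat mean_acceptance"]
    for j, name in enumerate(draws.param_names):
        accs = [draws.acceptance[c][draws.move_names.index(name)]
                for c in range(draws.n_chains)
                if name in draws.move_names]
        acc = float(np.mean(accs)) if accs else float("nan")
        lines.append(f"{name} {rh[name]:.4f} {acc:.3f}")
    (out / "diagnostics.txt").write_text("\n".join(lines) + "\n")


def read_posterior(run_dir) -> PosteriorDraws:
    run = Path(run_dir)
    meta = json.loads((run / "meta.json").read_text())
    df = pd.read_csv(run / "draws.csv")
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    n_chains = df["chain"].nunique()
    params = df[names].to_numpy().reshape(n_chains, -1, len(names))

    data = schedule = config = None
    if meta.get("axis"):
        axis = TimeAxis(**meta["axis"])
        y = np.array([np.nan if v is None else v for v in meta["y"]])
        data = CountSeries(y=y, axis=axis)
    if meta.get("schedule"):
        s = meta["schedule"]
        schedule = CycloneSchedule(tuple(s["events"]), s["ramp_length"],
                                   s["indicator"])
    if meta.get("config"):
        config = McmcConfig(**meta["config"])

    states_total = states_camp = state_iters = None
    if (run / "states_total.csv").exists():
        def load(name):
            sdf = pd.read_csv(run / name)
            cols = [c for c in sdf.columns if c.startswith("m")]
            n_k = sdf[sdf.chain == 0].shape[0]
            return (sdf[cols].to_numpy().reshape(n_chains, n_k, len(cols)),
                    sdf.loc[sdf.chain == 0, "iteration"].to_numpy())
        states_total, state_iters = load("states_total.csv")
        states_camp, _ = load("states_camp.csv")
    return PosteriorDraws(params=params, param_names=tuple(names),
                          acceptance=np.full((n_chains, len(names)), np.nan),
                          move_names=tuple(names),
                          states_total=states_total, states_camp=states_camp,
                          state_iters=state_iters, data=data,
                          schedule=schedule, config=config)


# ---------------------------------------------------------------------------
# Run configuration and pipeline commands
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for the pipeline commands (loadable from YAML)."""

    seed: int = 0
    out_dir: str = "."
    data: str | None = None            # count-table path (fit, ddj)
    cyclones: str | None = None        # schedule path (fit)
    draws: str | None = None           # posterior run directory
    scenario: dict = field(default_factory=dict)   # simulate overrides
    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 10_000
    thin_states: int = 10
    bandwidth: float = 6.0
    deseasonalize: bool = False
    horizon: int = 24
    cyclone_frequency: float = 3.0 / (154.0 / 12.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, command: str) -> None:
        problems = []
        needs = {"fit": ["data"], "ddj": ["data"],
                 "summarize": ["draws"], "project": ["draws"]}
        for key in needs.get(command, []):
            val = getattr(self, key)
            if val is None:
                problems.append(f"'{key}' is required for {command}")
            elif not Path(val).exists():
                problems.append(f"path does not exist: {val}")
        if self.cyclones is not None and not Path(self.cyclones).exists():
            problems.append(f"path does not exist: {self.cyclones}")
        if problems:
            raise ValueError("; ".join(problems))


def _write_log(out: Path, command: str, config: RunConfig) -> None:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True)
    log = {"command": command, "seed": config.seed,
           "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
           "version": __version__}
    (out / "run_log.json").write_text(json.dumps(log, indent=1))


def _build_scenario(config: RunConfig) -> Scenario:
    over = dict(config.scenario)
    params = default_params()
    if "params" in over:
        params = params.replace(**over.pop("params"))
    if "events" in over:
        over["schedule"] = CycloneSchedule(tuple(over.pop("events")))
    if "missing_months" in over:
        over["missing_months"] = frozenset(over["missing_months"])
    return default_scenario(seed=config.seed, **over).replace(params=params)


def run_command(command: str, config: RunConfig) -> int:
    """Execute one pipeline stage end-to-end; returns the exit status."""
    commands = {"simulate": _cmd_simulate, "fit": _cmd_fit,
                "summarize": _cmd_summarize, "ddj": _cmd_ddj,
                "project": _cmd_project}
    if command not in commands:
        raise ValueError(f"unknown command {command!r}; "
                         f"choose from {sorted(commands)}")
    config.validate(command)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    commands[command](config, out)
    _write_log(out, command, config)
    return 0


def _cmd_simulate(config: RunConfig, out: Path) -> None:
    sc = _build_scenario(config)
    ds = simulate(sc)
    write_counts(ds.per_camp, out / "counts.csv")
    write_schedule(ds.schedule, sc.axis, out / "cyclones.csv")
    write_truth(ds, out / "truth.json")


def _cmd_fit(config: RunConfig, out: Path) -> None:
    data = read_counts(config.data)
    schedule = (read_schedule(config.cyclones, data.axis)
                if config.cyclones else CycloneSchedule(()))
    mcmc = McmcConfig(n_chains=config.n_chains, n_iter=config.n_iter,
                      n_burnin=config.n_burnin,
                      thin_states=config.thin_states, seed=config.seed)
    draws = fit(data, schedule, mcmc)
    write_posterior(draws, out)


def _cmd_summarize(config: RunConfig, out: Path) -> None:
    from .derived import prob_decline, rate_of_increase
    draws = read_posterior(config.draws)
    draws.summary().to_csv(out / "parameter_summary.csv", index=False)
    rates = rate_of_increase(draws, config.cyclone_frequency)
    qs = np.quantile(rates.r_with_cyclone, (0.025, 0.5, 0.975))
    report = {
        "cyclone_frequency_per_year": config.cyclone_frequency,
        "r_mean": float(rates.r_with_cyclone.mean()),
        "r_q0.025": qs[0], "r_q0.5": qs[1], "r_q0.975": qs[2],
        "r_no_cyclone_mean": float(rates.r_no_cyclone.mean()),
        "p_decline": rates.p_decline,
    }
    (out / "trend_report.json").write_text(json.dumps(report, indent=1))
    if draws.states_total is not None and draws.data is not None:
        from .derived import november_summary
        november_summary(draws).to_csv(out / "november_summary.csv",
                                       index=False)


def _cmd_ddj(config: RunConfig, out: Path) -> None:
    from .early_warning import ddj
    data = read_counts(config.data)
    res = ddj(data, bandwidth=config.bandwidth,
              deseasonalize=config.deseasonalize)
    pd.DataFrame({
        "time": res.time,
        "conditional_variance": res.conditional_variance,
        "total_variance": res.total_variance,
        "diffusion": res.diffusion,
        "jump_intensity": res.jump_intensity,
    }).to_csv(out / "ddj.csv", index=False)


def _cmd_project(config: RunConfig, out: Path) -> None:
    from .derived import project
    draws = read_posterior(config.draws)
    proj = project(draws, config.horizon, seed=config.seed)
    proj.to_csv(out / "projection.csv", index=False)
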