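"""Experiment orchestration: the headline scenario comparison.

One experiment = generate an ensemble of hyperbolic contact networks, run
the unrestrained and endogenous-distancing SEIR scenarios plus uniform and
immobilization sweeps on them with common random numbers, and report the
minimal uniform contact-rate reduction and the minimal immobilized fraction
whose peak infected fraction matches the endogenous scenario's.

Everything is driven by an :class:`ExperimentConfig` that round-trips
losslessly through YAML; outputs (curve CSVs, sweep summaries, thresholds
JSON, resolved config, log) carry the schema version and master seed for
provenance.
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

from . import network, seir

__all__ = [
    "ExperimentConfig",
    "NetworkConfig",
    "SEIRConfig",
    "EndogenousConfig",
    "SweepConfig",
    "ExperimentResult",
    "run_experiment",
    "threshold_sensitivity",
    "load_config",
    "save_config",
]

SCHEMA_VERSION = "1"


def _strict_from_dict(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data}
    return cls(**kwargs)


@dataclass(frozen=True)
class NetworkConfig:
    n_nodes: int = 20_000
    zeta: float = 1.0
    alpha: float = 0.75
    target_mean_degree: float = 6.0


@dataclass(frozen=True)
class SEIRConfig:
    beta_trans: float = 0.15
    sigma: float = 0.2
    gamma: float = 1.0 / 7.0
    initial_infected_frac: float = 0.002
    horizon: int = 300
    n_realizations: int = 25


@dataclass(frozen=True)
class EndogenousConfig:
    fold: float = 3.0
    incidence_scale: float = 0.1
    incidence_scale_ill: float | None = None


@dataclass(frozen=True)
class SweepConfig:
    # q from 1.0 down to 0.1 in steps of 0.05; p from 0.0 to 1.0 in steps of 0.05
    uniform_q: tuple = tuple(np.round(np.arange(1.0, 0.0999, -0.05), 2))
    immobilization_p: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class ExperimentConfig:
    schema_version: str = SCHEMA_VERSION
    master_seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seir: SEIRConfig = field(default_factory=SEIRConfig)
    scenario: EndogenousConfig = field(default_factory=EndogenousConfig)
    sweeps: SweepConfig = field(default_factory=SweepConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweeps"]["uniform_q"] = [float(q) for q in d["sweeps"]["uniform_q"]]
        d["sweeps"]["immobilization_p"] = [
            float(p) for p in d["sweeps"]["immobilization_p"]
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        sections = {
            "network": NetworkConfig,
            "seir": SEIRConfig,
            "scenario": EndogenousConfig,
            "sweeps": SweepConfig,
        }
        for key, section_cls in sections.items():
            if key in data:
                sub = dict(data[key])
                for tup_key in ("uniform_q", "immobilization_p"):
                    if key == "sweeps" and tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                data[key] = _strict_from_dict(section_cls, sub)
        return _strict_from_dict(cls, data)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    curve_none: seir.EpidemicCurve
    curve_endogenous: seir.EpidemicCurve
    sweep_uniform: list
    sweep_immobilization: list
    threshold_uniform: float | None
    threshold_immobilization: float | None
    outdir: Path | None = None

    def thresholds_dict(self) -> dict:
        return {
            "schema_version": self.config.schema_version,
            "master_seed": self.config.master_seed,
            "criterion": "peak",
            "uniform_reduction_threshold": self.threshold_uniform,
            "immobilization_threshold": self.threshold_immobilization,
            "endogenous_peak": self.curve_endogenous.peak_infected_fraction,
            "unrestrained_peak": self.curve_none.peak_infected_fraction,
            "endogenous_attack_rate": self.curve_endogenous.attack_rate,
            "unrestrained_attack_rate": self.curve_none.attack_rate,
        }


def _generate_ensemble(config: ExperimentConfig, log) -> list[network.HyperbolicGraph]:
    net = config.network
    seeds = np.random.SeedSequence([config.master_seed, 7]).spawn(
        config.seir.n_realizations
    )
    graphs = []
    for k, s in enumerate(seeds):
        t0 = time.perf_counter()
        g = network.generate_graph(
            n_nodes=net.n_nodes,
            zeta=net.zeta,
            target_mean_degree=net.target_mean_degree,
            alpha=net.alpha,
            seed=s,
        )
        log(
            f"graph {k}: n={g.n_nodes} mean_degree={g.mean_degree:.2f} "
            f"R={g.disk_radius:.3f} ({time.perf_counter() - t0:.1f}s)"
        )
        graphs.append(g)
    return graphs


def _log_curve(log, curve: seir.EpidemicCurve, master_seed: int) -> None:
    runtimes = (
        curve.realization_runtimes
        if curve.realization_runtimes is not None
        else np.zeros(curve.n_realizations)
    )
    for k, (pk, ar, rt) in enumerate(
        zip(curve.realization_peaks, curve.realization_attacks, runtimes)
    ):
        log(
            f"scenario={curve.scenario.label()} seed={master_seed}.{k} "
            f"peak={pk:.4f} attack_rate={ar:.4f} runtime={rt:.2f}s"
        )
    log(
        f"scenario={curve.scenario.label()} mean_peak="
        f"{curve.peak_infected_fraction:.4f} mean_attack={curve.attack_rate:.4f}"
    )


def run_experiment(
    config: ExperimentConfig,
    outdir=None,
    graphs=None,
    verbose: bool = False,
) -> ExperimentResult:
    """Execute the full scenario comparison and optionally write artifacts.

    Stages: network-ensemble generation, the unrestrained and endogenous
    scenarios, the uniform and immobilization sweeps, and peak-matching
    thresholds.  All scenarios share the master seed so realization streams
    use common random numbers.  When ``outdir`` is given, five artifact
    groups are written: per-scenario curve CSVs, sweep summary CSVs, a
    thresholds JSON, the resolved config, and a per-realization log.
    """
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        if verbose:
            print(msg, flush=True)

    stage = "network generation"
    try:
        if graphs is None:
            graphs = _generate_ensemble(config, log)
        params = seir.SEIRParams(
            beta_trans=config.seir.beta_trans,
            sigma=config.seir.sigma,
            gamma=config.seir.gamma,
            initial_infected_frac=config.seir.initial_infected_frac,
            horizon=config.seir.horizon,
            n_realizations=config.seir.n_realizations,
            seed=config.master_seed,
        )
        stage = "baseline scenarios"
        curve_none = seir.run(graphs, params, seir.Scenario(kind="none"))
        _log_curve(log, curve_none, config.master_seed)
        endo = seir.Scenario(
            kind="endogenous",
            fold=config.scenario.fold,
            incidence_scale=config.scenario.incidence_scale,
            incidence_scale_ill=config.scenario.incidence_scale_ill,
        )
        curve_endo = seir.run(graphs, params, endo)
        _log_curve(log, curve_endo, config.master_seed)

        stage = "uniform sweep"
        sw_uniform = []
        for q in config.sweeps.uniform_q:
            c = seir.run(graphs, params, seir.Scenario(kind="uniform", q_uniform=q))
            _log_curve(log, c, config.master_seed)
            sw_uniform.append(c)

        stage = "immobilization sweep"
        sw_immob = []
        for p in config.sweeps.immobilization_p:
            c = seir.run(
                graphs, params, seir.Scenario(kind="random_immobilization", p=p)
            )
            _log_curve(log, c, config.master_seed)
            sw_immob.append(c)

        stage = "threshold matching"
        thr_u = seir.match_threshold(curve_endo, sw_uniform, criterion="peak")
        thr_p = seir.match_threshold(curve_endo, sw_immob, criterion="peak")
        log(f"threshold uniform_reduction={thr_u} immobilization={thr_p}")
    except Exception as exc:
        raise RuntimeError(f"experiment failed during stage: {stage}") from exc

    result = ExperimentResult(
        config=config,
        curve_none=curve_none,
        curve_endogenous=curve_endo,
        sweep_uniform=sw_uniform,
        sweep_immobilization=sw_immob,
        threshold_uniform=thr_u,
        threshold_immobilization=thr_p,
    )
    if outdir is not None:
        result.outdir = _write_artifacts(result, Path(outdir), log_lines)
    return result


def _stamp(frame: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    frame = frame.copy()
    frame["schema_version"] = config.schema_version
    frame["master_seed"] = config.master_seed
    return frame


def _write_artifacts(
    result: ExperimentResult, outdir: Path, log_lines: list[str]
) -> Path:
    cfg = result.config
    for sub in ("curves", "sweeps", "config", "logs"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    _stamp(seir.curve_to_frame(result.curve_none), cfg).to_csv(
        outdir / "curves" / "none.csv", index=False
    )
    _stamp(seir.curve_to_frame(result.curve_endogenous), cfg).to_csv(
        outdir / "curves" / "endogenous.csv", index=False
    )
    _stamp(seir.sweep_summary_frame(result.sweep_uniform), cfg).to_csv(
        outdir / "sweeps" / "uniform.csv", index=False
    )
    _stamp(seir.sweep_summary_frame(result.sweep_immobilization), cfg).to_csv(
        outdir / "sweeps" / "immobilization.csv", index=False
    )
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(result.thresholds_dict(), fh, indent=2)
    save_config(cfg, outdir / "config" / "resolved.yaml")
    with open(outdir / "logs" / "experiment.log", "w") as fh:
        fh.write(
            f"schema_version={cfg.schema_version} master_seed={cfg.master_seed}\n"
        )
        fh.write("\n".join(log_lines) + "\n")
    return outdir


def threshold_sensitivity(
    config: ExperimentConfig,
    beta_factors: tuple[float, ...] = (0.75, 1.0, 1.25),
    n_nodes: int = 4000,
    n_realizations: int = 10,
    q_step: float = 0.1,
    p_step: float = 0.1,
) -> pd.DataFrame:
    """Matching thresholds across a small transmission-rate grid.

    Runs a scaled-down version of the experiment (fewer nodes and
    realizations, coarser sweeps) at several multiples of the configured
    ``beta_trans``, to show how the matching thresholds move with the
    transmissibility assumption.
    """
    rows = []
    for factor in beta_factors:
        scaled = ExperimentConfig.from_dict(
            {
                "master_seed": config.master_seed,
                "network": {
                    **dataclasses.asdict(config.network),
                    "n_nodes": n_nodes,
                },
                "seir": {
                    **dataclasses.asdict(config.seir),
                    "beta_trans": round(config.seir.beta_trans * factor, 6),
                    "n_realizations": n_realizations,
                },
                "scenario": dataclasses.asdict(config.scenario),
                "sweeps": {
                    "uniform_q": [
                        float(q) for q in np.round(np.arange(1.0, 0.0999, -q_step), 2)
                    ],
                    "immobilization_p": [
                        float(p) for p in np.round(np.arange(0.0, 1.0001, p_step), 2)
                    ],
                },
            }
        )
        res = run_experiment(scaled)
        rows.append(
            {
                "beta_trans": scaled.seir.beta_trans,
                "uniform_reduction_threshold": res.threshold_uniform,
                "immobilization_threshold": res.threshold_immobilization,
                "endogenous_peak": res.curve_endogenous.peak_infected_fraction,
                "unrestrained_peak": res.curve_none.peak_infected_fraction,
            }
        )
    return pd.DataFrame(rows)
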