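"""Experiment configuration, dispatch, result records, and fixture builders.

This module ties the model families together behind a single
``run_experiment`` entry point driven by a plain-data configuration that
round-trips through YAML, so that every numeric result is reproducible
from the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .genetics import Architecture, DriveParams, FitnessMode, ToxinRule, get_system
from .ibm import (
    IBMConfig,
    SpatialIBMConfig,
    establishment_rate,
    initial_population,
    run_spatial_wave,
)
from .panmictic import (
    EcologyParams,
    InfluxConfig,
    ReleaseSpec,
    TwoDemeConfig,
    find_critical_influx,
    find_discrete_threshold,
    find_threshold,
    influx_integrate,
    integrate,
    iterate_discrete,
    trajectory_metrics,
    two_deme_integrate,
)
from .selflimiting import SelfLimitingRelease, persistence_metrics, run_self_limiting
from .spatial import (
    ExpansionCriterion,
    ReleaseMode,
    critical_radius_uniform,
    wave_speed,
)

__all__ = ["ExperimentConfig", "ResultRecord", "run_experiment", "build_fixture"]

_MODELS = (
    "threshold", "discrete-threshold", "trajectory", "two-deme", "influx",
    "critical-influx", "self-limiting", "wave-speed", "critical-release",
    "ibm-establish", "ibm-wave",
)


@dataclass
class ExperimentConfig:
    """Plain-data description of one experiment.

    ``model`` selects the dispatch target; drive/ecology parameters apply
    to every model, the remaining fields only where meaningful.
    """

    model: str = "threshold"
    fitness: float = 1.0
    fitness_mode: str = "multiplicative"
    dominance: float = 0.5
    toxin_efficiency: float = 1.0
    antidote_efficiency: float = 1.0
    toxin_rule: str = "ab-required"
    low_density_growth: float = 9.0
    introduction_frequency: float = 0.5
    t_end: float = 1000.0
    migration_rate: float = 0.01
    introduction_frequency_deme2: float = 0.0
    influx: float = 0.04
    architecture: str = "sl-two-locus"
    composition: str = "double-homozygote"
    dispersion: float = 0.05
    release_radius: float = 0.3
    release_mode: str = "additive"
    criterion: str = "expansion-10-15"
    capacity: int = 1000
    replicates: int = 200
    seed: int = 1
    out: str | None = None

    def drive_params(self) -> DriveParams:
        return DriveParams(
            fitness=self.fitness,
            fitness_mode=FitnessMode(self.fitness_mode),
            dominance=self.dominance,
            toxin_efficiency=self.toxin_efficiency,
            antidote_efficiency=self.antidote_efficiency,
            toxin_rule=ToxinRule(self.toxin_rule),
        )

    def ecology(self) -> EcologyParams:
        return EcologyParams(low_density_growth=self.low_density_growth)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ResultRecord:
    """A numeric result plus the configuration and provenance behind it."""

    model: str
    metrics: dict
    config: dict
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_experiment(config: ExperimentConfig) -> ResultRecord:
    """Dispatch a configuration to the matching model and collect metrics."""
    if config.model not in _MODELS:
        raise ValueError(f"unknown model {config.model!r}; expected one of {_MODELS}")
    params = config.drive_params()
    eco = config.ecology()
    metrics: dict = {}

    if config.model == "threshold":
        metrics["threshold"] = find_threshold(params, eco)
    elif config.model == "discrete-threshold":
        metrics["threshold"] = find_discrete_threshold(params)
    elif config.model == "trajectory":
        traj = integrate(ReleaseSpec(config.introduction_frequency), params, eco,
                         t_end=config.t_end)
        metrics = trajectory_metrics(traj).to_dict()
        if config.out:
            traj.to_csv(config.out)
    elif config.model == "two-deme":
        cfg = TwoDemeConfig(
            migration_rate=config.migration_rate,
            release_deme1=ReleaseSpec(config.introduction_frequency),
            release_deme2=ReleaseSpec(config.introduction_frequency_deme2),
        )
        tr1, tr2 = two_deme_integrate(cfg, params, eco, t_end=config.t_end)
        metrics = {
            "deme1": trajectory_metrics(tr1).to_dict(),
            "deme2": trajectory_metrics(tr2).to_dict(),
        }
        if config.out:
            tr1.to_csv(str(config.out).replace(".csv", "_deme1.csv"))
            tr2.to_csv(str(config.out).replace(".csv", "_deme2.csv"))
    elif config.model == "influx":
        traj = influx_integrate(InfluxConfig(config.influx), params, eco,
                                t_end=config.t_end)
        metrics = trajectory_metrics(traj).to_dict()
        metrics["max_allele_frequency"] = float(traj.allele_frequency("d").max())
        if config.out:
            traj.to_csv(config.out)
    elif config.model == "critical-influx":
        metrics["critical_influx"] = find_critical_influx(params, eco)
    elif config.model == "self-limiting":
        release = SelfLimitingRelease(
            architecture=Architecture(config.architecture),
            composition=config.composition,
            I=config.introduction_frequency,
        )
        traj = run_self_limiting(release, params, eco, t_end=config.t_end)
        metrics = persistence_metrics(traj).to_dict()
        if config.out:
            traj.to_csv(config.out)
    elif config.model == "wave-speed":
        metrics["wave_speed"] = wave_speed(params, config.dispersion)
    elif config.model == "critical-release":
        res = critical_radius_uniform(
            params,
            dispersion=config.dispersion,
            criterion=ExpansionCriterion(config.criterion),
            mode=ReleaseMode(config.release_mode),
        )
        metrics = {
            "critical_radius": res.critical_parameter,
            "release_size": res.release_size,
            "applicable": res.applicable,
        }
    elif config.model == "ibm-establish":
        cfg = IBMConfig(capacity=config.capacity,
                        low_density_growth=config.low_density_growth)
        rate, se = establishment_rate(
            config.introduction_frequency, params, cfg,
            replicates=config.replicates, seed=config.seed,
        )
        metrics = {"establishment_rate": rate, "standard_error": se}
    elif config.model == "ibm-wave":
        cfg = IBMConfig(capacity=config.capacity,
                        low_density_growth=config.low_density_growth)
        sp = SpatialIBMConfig(dispersion=config.dispersion)
        rng = np.random.default_rng(config.seed)
        metrics = {"wave_speed": run_spatial_wave(params, cfg, sp, rng)}

    record = ResultRecord(config.model, metrics, dataclasses.asdict(config))
    if config.out and config.model not in ("trajectory", "two-deme", "influx", "self-limiting"):
        record.to_json(config.out)
    return record


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def build_fixture(name: str):
    """Deterministic small inputs used across the test-suite and examples."""
    if name == "small-ibm":
        cfg = IBMConfig(capacity=200)
        rng = np.random.default_rng(1)
        return initial_population(0.5, cfg, rng)
    if name == "slab-wave":
        x = np.linspace(0.0, 1.0, 512)
        u = np.zeros((3, 512))
        u[0, x <= 0.3] = 1.0
        u[2, x > 0.3] = 1.0
        return x, u
    if name == "two-deme-low-m":
        return TwoDemeConfig(migration_rate=0.01, release_deme1=ReleaseSpec(0.6))
    if name == "threshold-bracket":
        # straddles the continuous-generation threshold of the ideal drive
        return ReleaseSpec(0.3605), ReleaseSpec(0.36051)
    if name == "ring-release":
        from .spatial import RingRelease

        return RingRelease(r0=0.104, width=0.172, density=0.774)
    raise KeyError(f"unknown fixture {name!r}")
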