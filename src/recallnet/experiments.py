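"""Multi-trial experiment orchestration with reproducible seeding.

Every experiment draws a fresh pattern set per trial (the "word list" of
that trial), runs the population-reduced simulator from a randomly chosen
initial memory, and applies the matching analysis.  Per-trial seeds derive
deterministically from the master seed, so every output bundle can be
re-derived from its stored configuration alone.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import recall as recall_analysis
from .dynamics import (
    GainSpec,
    NoiseSpec,
    OscillationSchedule,
    SimConfig,
    Trajectory,
    export_trajectory,
    simulate_full,
    simulate_reduced,
)
from .errors import ParameterError
from .meanfield import phase_diagram_scan
from .patterns import (
    CouplingParams,
    PatternSet,
    PopulationPartition,
    generate_patterns,
    intersection_matrix,
    partition_populations,
)

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "run_trial",
    "run_ensemble",
    "run_experiment",
    "validate_reduction",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = (
    "phase_diagram",
    "sample_epoch",
    "time_course",
    "size_effects",
    "transition_stats",
    "contiguity_sweep",
    "noise_sweep",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """All simulation parameters by name; defaults are the reference values.

    ``scale_factor`` (optional) divides ``n_neurons``, ``n_trials`` and
    ``t_total`` for cheaper runs; :meth:`scaled_profile` is the documented
    desk-scale profile used by the test-suite and acceptance runs.
    """

    n_neurons: int = 100_000
    n_memories: int = 16
    sparsity: float = 0.1
    tau: float = 0.01
    kappa: float = 13_000.0
    phi_max: float = 1.06
    phi_min: float = 0.7
    gamma: float = 0.4  # 2/5
    theta: float = 0.0
    tau_osc: float = 1.0
    t_total: float = 450.0
    dt: float = 0.001
    j_plus: float = 1500.0
    j_minus: float = 400.0
    xi0: float = 65.0
    r_thresh: float = 15.0
    n_trials: int = 10_000
    r_ini: float = 1.0
    scale_factor: float | None = None
    master_seed: int = 0
    record_dt: float | None = None

    @classmethod
    def reference(cls, **overrides) -> "ExperimentConfig":
        return cls(**overrides)

    @classmethod
    def scaled_profile(cls, **overrides) -> "ExperimentConfig":
        """Desk-scale profile: N=2e4, 50 trials, T=100 cycles, dt=2e-3."""
        base = dict(n_neurons=20_000, n_trials=50, t_total=100.0, dt=0.002)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "ExperimentConfig":
        return dataclasses.replace(self, **changes)

    def resolve(self) -> "ExperimentConfig":
        """Apply ``scale_factor`` (if any) to N, N_trials and T_tot."""
        if self.scale_factor is None or self.scale_factor == 1:
            return self
        s = self.scale_factor
        if s <= 0:
            raise ParameterError("scale_factor must be positive")
        return self.replace(
            n_neurons=max(1, int(round(self.n_neurons / s))),
            n_trials=max(1, int(round(self.n_trials / s))),
            t_total=self.t_total / s,
            scale_factor=None,
        )

    # --- component views -------------------------------------------------
    def coupling(self) -> CouplingParams:
        return CouplingParams(
            kappa=self.kappa, phi=self.phi_min, j_plus=self.j_plus, j_minus=self.j_minus
        )

    def gain(self) -> GainSpec:
        return GainSpec(gamma=self.gamma, theta=self.theta)

    def schedule(self) -> OscillationSchedule:
        return OscillationSchedule(
            phi_min=self.phi_min, phi_max=self.phi_max, period=self.tau_osc
        )

    def noise(self) -> NoiseSpec:
        return NoiseSpec(xi0=self.xi0)

    def sim_config(self, seed: int, record_currents: bool = False) -> SimConfig:
        return SimConfig(
            tau=self.tau,
            dt=self.dt,
            t_total=self.t_total,
            r_ini=self.r_ini,
            r_thresh=self.r_thresh,
            seed=seed,
            record_dt=self.record_dt,
            record_currents=record_currents,
        )

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    """Deterministic per-trial seeds (below 2^31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_trials)])


@dataclass
class TrialResult:
    """Per-trial outputs kept for analysis (trajectories only on request)."""

    trial_id: int
    seed: int
    initial_memory: int
    log: recall_analysis.RecallLog
    sizes: np.ndarray
    intersections: np.ndarray
    n_populations: int
    trajectory: Trajectory | None = None


def run_trial(
    config: ExperimentConfig,
    seed: int,
    trial_id: int = 0,
    keep_trajectory: bool = False,
) -> TrialResult:
    """Generate patterns, simulate the reduced network, detect recalls."""
    config = config.resolve()
    rng = np.random.default_rng(seed)
    pattern_seed = int(rng.integers(2**31))
    sim_seed = int(rng.integers(2**31))
    initial_memory = int(rng.integers(config.n_memories))
    patterns = generate_patterns(
        config.n_neurons, config.n_memories, config.sparsity, seed=pattern_seed
    )
    partition = partition_populations(patterns)
    trajectory = simulate_reduced(
        partition,
        config.coupling(),
        config.gain(),
        config.schedule(),
        config.noise(),
        config.sim_config(sim_seed),
        initial_memory=initial_memory,
    )
    log = recall_analysis.detect_recalls(trajectory, partition, trial_id=trial_id)
    return TrialResult(
        trial_id=trial_id,
        seed=seed,
        initial_memory=initial_memory,
        log=log,
        sizes=patterns.representation_sizes,
        intersections=intersection_matrix(patterns),
        n_populations=partition.n_populations,
        trajectory=trajectory if keep_trajectory else None,
    )


def run_ensemble(
    config: ExperimentConfig, keep_trajectories: bool = False
) -> list[TrialResult]:
    """Run ``n_trials`` independent trials with derived seeds."""
    config = config.resolve()
    seeds = trial_seeds(config.master_seed, config.n_trials)
    return [
        run_trial(config, int(seed), trial_id=i, keep_trajectory=keep_trajectories)
        for i, seed in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# named experiments


def _similarity_offdiag(results: list[TrialResult]) -> list[np.ndarray]:
    """Intersection matrices with the diagonal neutralised for ranking."""
    sims = []
    for res in results:
        sim = res.intersections.astype(np.float64)
        np.fill_diagonal(sim, 0.0)
        sims.append(sim)
    return sims


def run_experiment(name: str, config: ExperimentConfig, out_dir) -> dict:
    """Run a named experiment and write its tables + manifest to ``out_dir``.

    Returns a summary dict (also stored as ``manifest.json``).  Reruns with
    the same configuration are byte-identical.
    """
    if name not in EXPERIMENT_NAMES:
        raise ParameterError(
            f"unknown experiment {name!r}; choose one of {EXPERIMENT_NAMES}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config.resolve()
    t0 = _time.perf_counter()
    summary: dict = {"experiment": name, "config": dataclasses.asdict(config)}

    if name == "phase_diagram":
        diagram = phase_diagram_scan(
            kappa_range=np.linspace(1000.0, 26000.0, 26),
            phi_range=np.linspace(0.05, 2.0, 79),
            f=config.sparsity,
            theta=config.theta,
            q_max=3,
        )
        diagram.to_frame().to_csv(out / "phase_diagram.tsv", sep="\t", index=False)
        summary["n_cells"] = int(diagram.labels.size)

    elif name == "sample_epoch":
        epoch = config.replace(t_total=15.0 * config.tau_osc, n_trials=1)
        res = run_trial(epoch, int(trial_seeds(epoch.master_seed, 1)[0]), keep_trajectory=True)
        export_trajectory(out / "sample_epoch.tsv", res.trajectory)
        recall_analysis.save_logs(out / "recall_log.tsv", [res.log])
        summary["n_events"] = res.log.n_events
        summary["n_distinct"] = res.log.n_distinct
        summary["n_populations"] = res.n_populations

    elif name in ("time_course", "size_effects", "transition_stats"):
        results = run_ensemble(config)
        logs = [r.log for r in results]
        recall_analysis.save_logs(out / "recall_logs.tsv", logs)
        summary["n_trials"] = len(results)
        summary["mean_recalled"] = float(np.mean([log.n_distinct for log in logs]))
        summary["n_populations_mean"] = float(np.mean([r.n_populations for r in results]))
        if name == "time_course":
            grid = np.linspace(0.0, config.t_total, 201)
            acc = recall_analysis.accumulation_curve(logs, grid)
            pd.DataFrame({"time": grid, "mean_distinct": acc}).to_csv(
                out / "accumulation.tsv", sep="\t", index=False
            )
            stats = recall_analysis.irt_statistics(logs)
            pd.DataFrame({"irt": stats.pooled}).to_csv(
                out / "irt_pooled.tsv", sep="\t", index=False
            )
            stats.by_total.to_csv(out / "irt_by_total.tsv", sep="\t", index=False)
        elif name == "size_effects":
            curve = recall_analysis.recall_probability_by_size(
                logs, [r.sizes for r in results]
            )
            curve.to_csv(out / "recall_probability_by_size.tsv", sep="\t", index=False)
        else:  # transition_stats
            sims = _similarity_offdiag(results)
            ranks = recall_analysis.transition_rank_distribution(logs, sims)
            ranks.to_frame().to_csv(out / "transition_ranks.tsv", sep="\t")
            speed = recall_analysis.irt_vs_similarity(logs, sims)
            speed.to_csv(out / "irt_vs_intersection.tsv", sep="\t", index=False)
            summary["rank_top_probability"] = float(ranks.iloc[-1])

    elif name == "contiguity_sweep":
        values = np.linspace(config.j_minus, 2500.0, 6)
        sweep = recall_analysis.performance_sweep(
            "j_plus", values, config, n_trials=config.n_trials, seed=config.master_seed
        )
        sweep.to_csv(out / "contiguity_sweep.tsv", sep="\t", index=False)
        summary["values"] = values.tolist()

    elif name == "noise_sweep":
        values = np.array([0.0, 10.0, 30.0, 65.0, 120.0, 200.0])
        sweep = recall_analysis.performance_sweep(
            "xi0", values, config, n_trials=config.n_trials, seed=config.master_seed
        )
        sweep.to_csv(out / "noise_sweep.tsv", sep="\t", index=False)
        summary["values"] = values.tolist()

    summary["runtime_s"] = round(_time.perf_counter() - t0, 3)
    summary["seeds"] = trial_seeds(config.master_seed, min(config.n_trials, 10_000)).tolist()[
        : config.n_trials
    ]
    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def validate_reduction(
    n_neurons: int,
    config: ExperimentConfig | None = None,
    threshold: float = 1e-6,
    t_total: float = 0.5,
    dt: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Compare full and reduced simulators on one noiseless instance.

    Runs both systems from the same initial condition with ``xi0 = 0`` and
    reports the sup-norm deviation of population-mean currents.  Stochastic
    paths are not comparable pathwise, so a noisy configuration is refused.
    """
    if n_neurons > 500:
        raise ParameterError("validate_reduction is restricted to n_neurons <= 500")
    config = config or ExperimentConfig.scaled_profile()
    if config.xi0 != 0.0:
        raise ParameterError(
            "reduction validation requires xi0 = 0 (stochastic paths are not "
            "pathwise comparable; compare moments instead)"
        )
    config = config.replace(n_neurons=n_neurons, t_total=t_total, dt=dt)
    patterns = generate_patterns(
        config.n_neurons, config.n_memories, config.sparsity, seed=seed
    )
    partition = partition_populations(patterns)
    sim = config.sim_config(seed=seed, record_currents=True)
    kwargs = dict(
        coupling=config.coupling(),
        gain_spec=config.gain(),
        schedule=config.schedule(),
        noise=config.noise(),
        config=sim,
        initial_memory=0,
    )
    full = simulate_full(patterns, **kwargs)
    reduced = simulate_reduced(partition, **kwargs)
    # population means of the neuron-level currents
    idx = partition.neuron_to_population
    pop_full = np.vstack(
        [np.bincount(idx, weights=row, minlength=partition.n_populations) for row in full.currents]
    ) / partition.counts
    deviation = float(np.abs(pop_full - reduced.currents).max())
    return {
        "n_neurons": n_neurons,
        "n_populations": partition.n_populations,
        "deviation": deviation,
        "threshold": threshold,
        "passed": deviation <= threshold,
        "dt": dt,
        "t_total": t_total,
    }
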