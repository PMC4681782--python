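"""Stochastic rate dynamics of the memory network.

Two integrators are provided:

* :func:`simulate_full` — the neuron-level system
  ``tau dc_i/dt = -c_i + sum_j J_ij g(c_j) + xi_i`` with the materialised
  ``N x N`` connectivity; used for validation at small ``N``.
* :func:`simulate_reduced` — the exact population reduction
  ``tau dc_v/dt = -c_v + sum_w Jt_vw S_w g(c_w) + xi_v`` used for all
  experiments; one equation per distinct membership vector.

Retrieval is driven by a sinusoidal modulation of the relative inhibition
``phi(t)`` between a low value (single-memory attractors exist) and a high
value (only intersection states survive), plus noise that selects which
memory is reactivated when inhibition falls again.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels
from .errors import DegeneracyError, DivergenceError, ParameterError, StabilityError
from .patterns import CouplingParams, PatternSet, PopulationPartition, full_connectivity

__all__ = [
    "GainSpec",
    "OscillationSchedule",
    "NoiseSpec",
    "uniform_scaling",
    "clt_scaling",
    "SimConfig",
    "Trajectory",
    "gain",
    "phi_schedule",
    "simulate_full",
    "simulate_reduced",
    "memory_mean_rates",
    "export_trajectory",
]


@dataclass(frozen=True)
class GainSpec:
    """Threshold power-law transfer function ``g(x) = (x + theta)^gamma``.

    ``g`` is zero for ``x + theta <= 0`` and continuous at the threshold;
    ``gamma <= 1`` keeps it sublinear.  ``theta = 0`` is allowed (the
    reference parameter set uses it), in which case ``g(x) = x^gamma`` for
    positive input.
    """

    gamma: float = 0.4
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ParameterError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.theta < 0.0:
            raise ParameterError(f"theta must be >= 0, got {self.theta}")

    def __call__(self, current):
        x = np.asarray(current, dtype=np.float64) + self.theta
        return np.where(x > 0.0, np.maximum(x, 0.0) ** self.gamma, 0.0)

    def inverse(self, rate):
        """Current producing a given positive rate: ``r^(1/gamma) - theta``."""
        r = np.asarray(rate, dtype=np.float64)
        return r ** (1.0 / self.gamma) - self.theta


def gain(current, spec: GainSpec):
    """Firing rate for a synaptic current under a gain specification."""
    return spec(current)


@dataclass(frozen=True)
class OscillationSchedule:
    """Sinusoidal inhibition schedule ``phi(t)``.

    ``phi(t) = mean - amplitude * cos(2 pi t / period + phase)`` with
    ``mean = (phi_max + phi_min)/2`` and ``amplitude = (phi_max - phi_min)/2``;
    the default ``phase = 0`` starts at the trough ``phi(0) = phi_min`` so the
    initialised memory sits inside the single-attractor regime at ``t = 0``.
    """

    phi_min: float = 0.7
    phi_max: float = 1.06
    period: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_min > self.phi_max:
            raise ParameterError("phi_min must be <= phi_max")
        if self.period <= 0:
            raise ParameterError("oscillation period must be positive")

    @property
    def mean(self) -> float:
        return 0.5 * (self.phi_max + self.phi_min)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.phi_max - self.phi_min)

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        return self.mean - self.amplitude * np.cos(
            2.0 * np.pi * t / self.period + self.phase
        )

    @classmethod
    def constant(cls, phi: float) -> "OscillationSchedule":
        return cls(phi_min=phi, phi_max=phi, period=1.0)


def phi_schedule(t, schedule: OscillationSchedule):
    """Inhibition value at time(s) ``t``."""
    if np.any(np.asarray(t) < 0):
        raise ParameterError("time must be nonnegative")
    return schedule(t)


def uniform_scaling(xi0: float, fractions: np.ndarray, n_neurons: int) -> np.ndarray:
    """Per-unit noise: every population receives the same amplitude ``xi0``.

    This is the literal reading of the reduced rate equation, whose noise
    term occupies the same place as the single-neuron noise in the full
    system — each population unit is driven by one noise process of scale
    ``xi0``, regardless of how many neurons it lumps together.
    """
    return np.full(np.asarray(fractions).shape, float(xi0))


def clt_scaling(xi0: float, fractions: np.ndarray, n_neurons: int) -> np.ndarray:
    """Central-limit noise scaling: SD of the mean of ``S_v * N`` i.i.d. noises."""
    return xi0 / np.sqrt(fractions * n_neurons)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white noise on the currents.

    ``xi0`` is the noise scale (SD).  For the reduced system the
    per-population SD follows ``population_scaling(xi0, S_v, N)``.  The
    default is :func:`uniform_scaling` — one noise process of amplitude
    ``xi0`` per population unit, which is what the reduced rate equation
    states and the convention under which the reference noise level
    ``xi0 = 65`` sits at the interior optimum of recall performance.
    :func:`clt_scaling` (``xi0 / sqrt(S_v * N)``, the averaged noise of the
    population's neurons) is provided for exact moment-matching against the
    neuron-level simulator.
    """

    xi0: float = 65.0
    population_scaling: Callable[[float, np.ndarray, int], np.ndarray] = field(
        default=uniform_scaling, repr=False
    )

    def __post_init__(self) -> None:
        if self.xi0 < 0:
            raise ParameterError(f"xi0 must be >= 0, got {self.xi0}")

    def population_sd(self, fractions: np.ndarray, n_neurons: int) -> np.ndarray:
        if self.xi0 == 0.0:
            return np.zeros_like(np.asarray(fractions, dtype=np.float64))
        return np.asarray(
            self.population_scaling(self.xi0, np.asarray(fractions, float), n_neurons),
            dtype=np.float64,
        )


@dataclass(frozen=True)
class SimConfig:
    """Integration parameters (reference values: tau=0.01, dt=0.001)."""

    tau: float = 0.01
    dt: float = 0.001
    t_total: float = 450.0
    r_ini: float = 1.0
    r_thresh: float = 15.0
    seed: int = 0
    record_dt: float | None = None  # sampling interval; defaults to 10 * dt
    record_currents: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0 or self.t_total <= 0:
            raise ParameterError("tau, dt and t_total must be positive")
        if self.dt >= self.tau:
            raise StabilityError(
                f"dt={self.dt} >= tau={self.tau}: Euler integration unstable"
            )
        if self.dt > self.tau / 5 * (1 + 1e-12):
            warnings.warn(
                f"dt={self.dt} exceeds tau/5={self.tau / 5}; accuracy may suffer",
                stacklevel=2,
            )
        if self.r_thresh <= 0:
            raise ParameterError("r_thresh must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def stride(self) -> int:
        rd = self.record_dt if self.record_dt is not None else 10 * self.dt
        return max(1, int(round(rd / self.dt)))


@dataclass
class Trajectory:
    """Sampled time course of a simulation.

    ``memory_rates[k, mu]`` is the mean firing rate of neurons belonging to
    memory ``mu`` at ``times[k]``; ``overlaps`` are the centered projections
    ``m^mu`` and ``m0`` the network-mean rate.  ``currents`` (per unit:
    population or neuron) are stored only on request.
    """

    times: np.ndarray
    phi: np.ndarray
    memory_rates: np.ndarray  # (n_samples, P)
    overlaps: np.ndarray  # (n_samples, P)
    m0: np.ndarray
    currents: np.ndarray | None = None
    unit: str = "population"  # what `currents` rows refer to
    period: float = 1.0  # oscillation period, for cycle bookkeeping
    meta: dict = field(default_factory=dict)

    @property
    def n_memories(self) -> int:
        return self.memory_rates.shape[1]


def _initial_currents(
    membership: np.ndarray, gain_spec: GainSpec, r_ini: float
) -> np.ndarray:
    """Units inside the initialised memory start at rate ``r_ini``, others at 0."""
    c0 = np.full(membership.shape[0], -gain_spec.theta, dtype=np.float64)
    c0[membership.astype(bool)] = gain_spec.inverse(r_ini)
    return c0


def simulate_reduced(
    partition: PopulationPartition,
    coupling: CouplingParams,
    gain_spec: GainSpec,
    schedule: OscillationSchedule,
    noise: NoiseSpec,
    config: SimConfig,
    initial_memory: int = 0,
) -> Trajectory:
    """Integrate the population-reduced dynamics (one unit per population).

    ``initial_memory`` is a 0-based memory index; all populations belonging
    to it start at rate ``r_ini``, the rest at zero rate.
    """
    P = partition.n_memories
    if not 0 <= initial_memory < P:
        raise ParameterError(f"initial_memory must be in [0, {P}), got {initial_memory}")
    V = partition.vectors.astype(np.float64)
    S = partition.fractions
    fmem = partition.memory_fractions
    if (fmem == 0).any():
        raise DegeneracyError("some memory has no neurons in this partition")
    c = _initial_currents(partition.vectors[:, initial_memory], gain_spec, config.r_ini)

    n_steps = config.n_steps
    stride = config.stride
    n_samples = n_steps // stride + 1
    times = np.empty(n_samples)
    phi = np.empty(n_samples)
    rates = np.empty((n_samples, P))
    overlaps = np.empty((n_samples, P))
    m0 = np.empty(n_samples)
    if config.record_currents:
        currents = np.empty((n_samples, partition.n_populations))
    else:
        currents = np.empty((1, 1))

    noise_sd = noise.population_sd(S, partition.n_neurons)
    use_noise = bool(noise.xi0 > 0)
    status, step, magnitude = _kernels.integrate_reduced(
        c,
        np.ascontiguousarray(V),
        S,
        fmem,
        partition.sparsity,
        coupling.kappa,
        schedule.mean,
        schedule.amplitude,
        2.0 * np.pi / schedule.period,
        schedule.phase,
        coupling.j_plus,
        coupling.j_minus,
        gain_spec.gamma,
        gain_spec.theta,
        noise_sd,
        use_noise,
        int(config.seed) % 2**31,
        config.tau,
        config.dt,
        n_steps,
        stride,
        times,
        phi,
        rates,
        overlaps,
        m0,
        currents,
        config.record_currents,
    )
    if status != _kernels.STATUS_OK:
        raise DivergenceError(
            f"reduced integration diverged at step {step} (max |c| = {magnitude:g})"
        )
    return Trajectory(
        times=times,
        phi=phi,
        memory_rates=rates,
        overlaps=overlaps,
        m0=m0,
        currents=currents if config.record_currents else None,
        unit="population",
        period=schedule.period,
        meta={
            "kind": "reduced",
            "initial_memory": initial_memory,
            "seed": config.seed,
            "gamma": gain_spec.gamma,
            "theta": gain_spec.theta,
            "r_thresh": config.r_thresh,
            "n_populations": partition.n_populations,
        },
    )


def simulate_full(
    patterns: PatternSet,
    coupling: CouplingParams,
    gain_spec: GainSpec,
    schedule: OscillationSchedule,
    noise: NoiseSpec,
    config: SimConfig,
    initial_memory: int = 0,
    max_neurons: int = 2000,
) -> Trajectory:
    """Integrate the neuron-level system with the explicit connectivity.

    Validation-scale only (guarded at ``max_neurons``); neurons of the
    initialised memory start at rate ``r_ini``.
    """
    P = patterns.n_memories
    if not 0 <= initial_memory < P:
        raise ParameterError(f"initial_memory must be in [0, {P}), got {initial_memory}")
    N = patterns.n_neurons
    J = full_connectivity(patterns, coupling, max_neurons=max_neurons)
    eta = patterns.eta.astype(np.float64)
    f = patterns.sparsity
    sizes = patterns.representation_sizes.astype(np.float64)

    c = _initial_currents(patterns.eta[:, initial_memory], gain_spec, config.r_ini)
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_steps
    stride = config.stride
    n_samples = n_steps // stride + 1
    times = np.empty(n_samples)
    phi_arr = np.empty(n_samples)
    rates = np.empty((n_samples, P))
    overlaps = np.empty((n_samples, P))
    m0_arr = np.empty(n_samples)
    currents = np.empty((n_samples, N)) if config.record_currents else None

    a = config.dt / config.tau
    noise_scale = noise.xi0 * math.sqrt(config.dt) / config.tau
    sample = 0
    for k in range(n_steps + 1):
        t = k * config.dt
        r = gain_spec(c)
        if k % stride == 0:
            times[sample] = t
            phi_arr[sample] = schedule(t)
            m0_arr[sample] = r.mean()
            overlaps[sample] = (eta - f).T @ r / N
            rates[sample] = (eta.T @ r) / sizes
            if currents is not None:
                currents[sample] = c
            if not np.isfinite(c).all() or np.abs(c).max() > 1e12:
                raise DivergenceError(
                    f"full integration diverged at step {k} "
                    f"(max |c| = {np.abs(c).max():g})"
                )
            sample += 1
        if k == n_steps:
            break
        drive = J @ r - coupling.kappa * (schedule(t) - coupling.phi) / N * r.sum()
        c += a * (drive - c)
        if noise.xi0 > 0:
            c += noise_scale * rng.standard_normal(N)
    return Trajectory(
        times=times,
        phi=phi_arr,
        memory_rates=rates,
        overlaps=overlaps,
        m0=m0_arr,
        currents=currents,
        unit="neuron",
        period=schedule.period,
        meta={
            "kind": "full",
            "initial_memory": initial_memory,
            "seed": config.seed,
            "gamma": gain_spec.gamma,
            "theta": gain_spec.theta,
            "r_thresh": config.r_thresh,
        },
    )


def memory_mean_rates(
    trajectory: Trajectory, partition: PopulationPartition, gain_spec: GainSpec | None = None
) -> np.ndarray:
    """Per-memory mean rates recomputed from stored currents.

    Requires a trajectory recorded with ``record_currents=True``; the result
    equals the ``memory_rates`` the simulators store directly (cross-check).
    """
    if trajectory.currents is None:
        raise ParameterError("trajectory was recorded without currents")
    if gain_spec is None:
        gain_spec = GainSpec(
            gamma=trajectory.meta.get("gamma", 0.4), theta=trajectory.meta.get("theta", 0.0)
        )
    r = gain_spec(trajectory.currents)
    if trajectory.unit == "population":
        V = partition.vectors.astype(np.float64)
        S = partition.fractions
        fmem = partition.memory_fractions
        if (fmem == 0).any():
            raise DegeneracyError("some memory has no neurons in this partition")
        return (r * S) @ V / fmem
    weights = partition.neuron_to_population
    if weights is None or r.shape[1] != partition.n_neurons:
        raise ParameterError("neuron-level trajectory requires a matching partition")
    eta = partition.vectors[weights].astype(np.float64)  # (N, P) reconstruction
    sizes = eta.sum(axis=0)
    return r @ eta / sizes


def export_trajectory(path, trajectory: Trajectory) -> pd.DataFrame:
    """Write (time, phi, per-memory mean rates) as a TSV table (1-based labels)."""
    P = trajectory.n_memories
    frame = pd.DataFrame(
        {"time": trajectory.times, "phi": trajectory.phi}
        | {f"rate_memory_{mu + 1}": trajectory.memory_rates[:, mu] for mu in range(P)}
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
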