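"""Recall statistics: event detection, accumulation, IRTs, similarity effects.

A memory counts as *recalled* whenever the mean firing rate of its neurons
crosses the threshold ``r_thresh`` from below; the threshold is calibrated so
that two memories are never simultaneously above it.  The ordered recall
events of a trial form a :class:`RecallLog`, from which every statistic in
this module derives:

* accumulation of distinct items over time,
* inter-retrieval times (IRTs) between new items, pooled and conditioned on
  the trial's total recall,
* recall probability as a function of representation size,
* transition probability and speed as a function of the similarity
  (intersection size) between consecutively recalled items.

The analysis layer is generic: logs and similarity matrices may come from
the simulator or from external behavioural tables with the same shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError, SimultaneityError
from .dynamics import Trajectory
from .patterns import PatternSet, PopulationPartition

__all__ = [
    "RecallEvent",
    "RecallLog",
    "detect_recalls",
    "accumulation_curve",
    "irt_statistics",
    "IRTStatistics",
    "recall_probability_by_size",
    "transition_table",
    "transition_rank_distribution",
    "irt_vs_similarity",
    "performance_sweep",
    "save_logs",
    "load_logs",
]


@dataclass(frozen=True)
class RecallEvent:
    """One above-threshold activation of a memory."""

    time: float
    memory: int  # 0-based item index
    cycle: int  # oscillation-cycle index floor(time / period)
    first_time: bool  # first retrieval of this item in the trial


@dataclass
class RecallLog:
    """Ordered recall events of one trial plus derived quantities."""

    events: list[RecallEvent]
    n_memories: int
    window: float  # analysed time window [0, T]
    trial_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("recall events must be time-ordered")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def distinct_items(self) -> list[int]:
        """Items in order of first retrieval."""
        return [e.memory for e in self.events if e.first_time]

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_items)

    @property
    def first_retrieval_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events if e.first_time])

    @property
    def irts(self) -> np.ndarray:
        """Inter-retrieval times between successive *new* items."""
        return np.diff(self.first_retrieval_times)

    @property
    def transitions(self) -> list[tuple[int, int, float, float]]:
        """Consecutive distinct-item pairs ``(src, dst, t_src, t_dst)``.

        Repeated activations of the current item are not transitions; the
        inter-recall time of a transition is ``t_dst - t_src`` between the
        adjacent events on either side of the item change.
        """
        out = []
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.memory != prev.memory:
                out.append((prev.memory, cur.memory, prev.time, cur.time))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy event table (1-based item indices for export)."""
        return pd.DataFrame(
            {
                "trial": self.trial_id,
                "event_index": np.arange(1, self.n_events + 1),
                "time": [e.time for e in self.events],
                "item": [e.memory + 1 for e in self.events],
                "cycle": [e.cycle for e in self.events],
                "first_time": [int(e.first_time) for e in self.events],
            }
        )


def detect_recalls(
    trajectory: Trajectory,
    partition: PopulationPartition | None = None,
    r_thresh: float | None = None,
    trial_id: int = 0,
) -> RecallLog:
    """Extract the ordered recall sequence from a trajectory.

    An event is an upward crossing of ``r_thresh`` by a memory's mean rate,
    with the crossing time linearly interpolated between samples; repeated
    crossings of the same item within one oscillation cycle are merged.  Two
    memories above threshold at the same sample indicate a miscalibrated
    threshold and raise :class:`SimultaneityError`.
    """
    if r_thresh is None:
        r_thresh = trajectory.meta.get("r_thresh")
        if r_thresh is None:
            raise ParameterError("r_thresh not given and absent from trajectory meta")
    rates = trajectory.memory_rates
    times = trajectory.times
    if rates.size == 0 or len(times) < 2:
        raise ParameterError("trajectory too short for recall detection")
    above = rates > r_thresh
    multi = above.sum(axis=1) > 1
    if multi.any():
        k = int(np.argmax(multi))
        raise SimultaneityError(
            f"memories {np.flatnonzero(above[k]) + 1} simultaneously above "
            f"threshold at t={times[k]:.4f}: r_thresh={r_thresh} is miscalibrated"
        )
    period = trajectory.period
    raw_events: list[tuple[float, int]] = []
    for mu in range(rates.shape[1]):
        up = np.flatnonzero(above[1:, mu] & ~above[:-1, mu]) + 1
        for k in up:
            r0, r1 = rates[k - 1, mu], rates[k, mu]
            frac = (r_thresh - r0) / (r1 - r0)
            raw_events.append((times[k - 1] + frac * (times[k] - times[k - 1]), mu))
        if above[0, mu]:
            raw_events.append((times[0], mu))
    raw_events.sort()
    events: list[RecallEvent] = []
    seen: set[int] = set()
    for t, mu in raw_events:
        cycle = int(t // period)
        if events and events[-1].memory == mu and events[-1].cycle == cycle:
            continue  # same item re-crossing within the cycle: merged
        events.append(RecallEvent(time=t, memory=mu, cycle=cycle, first_time=mu not in seen))
        seen.add(mu)
    return RecallLog(
        events=events,
        n_memories=rates.shape[1],
        window=float(times[-1]),
        trial_id=trial_id,
        seed=trajectory.meta.get("seed"),
    )


def accumulation_curve(
    logs: Iterable[RecallLog], time_grid: np.ndarray
) -> np.ndarray:
    """Mean number of distinct items retrieved by each grid time."""
    logs = list(logs)
    if not logs:
        raise ParameterError("at least one recall log is required")
    grid = np.asarray(time_grid, dtype=np.float64)
    counts = np.zeros((len(logs), grid.size))
    for i, log in enumerate(logs):
        ft = log.first_retrieval_times
        counts[i] = np.searchsorted(ft, grid, side="right")
    return counts.mean(axis=0)


@dataclass
class IRTStatistics:
    """Pooled IRT sample and conditional mean-IRT curves.

    ``by_total`` has one row per (trial recall total, transition index):
    trials are grouped by how many distinct items they eventually retrieved,
    and the IRT of the j-th new-item transition is averaged within a group.
    """

    pooled: np.ndarray
    by_total: pd.DataFrame
    per_trial: list[np.ndarray] = field(repr=False, default_factory=list)


def irt_statistics(logs: Iterable[RecallLog]) -> IRTStatistics:
    logs = list(logs)
    sequences = [log.irts for log in logs]
    pooled = (
        np.concatenate([s for s in sequences if s.size]) if any(s.size for s in sequences) else np.empty(0)
    )
    rows = []
    totals = np.array([log.n_distinct for log in logs])
    for total in np.unique(totals):
        group = [s for s, n in zip(sequences, totals) if n == total and s.size]
        if not group:
            continue
        stacked = np.vstack(group)  # all sequences in a group share length total-1
        for j in range(stacked.shape[1]):
            rows.append(
                {
                    "n_recalled": int(total),
                    "transition_index": j + 1,
                    "mean_irt": stacked[:, j].mean(),
                    "n_trials": stacked.shape[0],
                }
            )
    return IRTStatistics(pooled=pooled, by_total=pd.DataFrame(rows), per_trial=sequences)


def _sizes_per_log(
    logs: Sequence[RecallLog],
    patterns: PatternSet | Sequence[PatternSet] | Sequence[np.ndarray],
) -> list[np.ndarray]:
    if isinstance(patterns, PatternSet):
        return [patterns.representation_sizes] * len(logs)
    sizes = [
        p.representation_sizes if isinstance(p, PatternSet) else np.asarray(p)
        for p in patterns
    ]
    if len(sizes) != len(logs):
        raise ParameterError("one PatternSet (or size vector) per log is required")
    return sizes


def recall_probability_by_size(
    logs: Sequence[RecallLog],
    patterns: PatternSet | Sequence[PatternSet] | Sequence[np.ndarray],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Probability of recall vs representation size (equal-count bins).

    Pools (trial, item) pairs across the ensemble; bins item sizes into
    ``n_bins`` quantile bins and reports the fraction recalled per bin.
    """
    logs = list(logs)
    sizes = _sizes_per_log(logs, patterns)
    all_sizes, recalled = [], []
    for log, sz in zip(logs, sizes):
        if len(sz) != log.n_memories:
            raise ParameterError("size vector length must equal the log's item count")
        hit = np.zeros(log.n_memories, dtype=bool)
        hit[log.distinct_items] = True
        all_sizes.append(np.asarray(sz, dtype=np.float64))
        recalled.append(hit)
    table = pd.DataFrame(
        {"size": np.concatenate(all_sizes), "recalled": np.concatenate(recalled)}
    )
    try:
        table["bin"] = pd.qcut(table["size"], q=n_bins, duplicates="drop")
    except ValueError as exc:
        raise ParameterError(f"cannot form size bins: {exc}") from exc
    grouped = table.groupby("bin", observed=True).agg(
        size_mean=("size", "mean"),
        probability=("recalled", "mean"),
        n_items=("recalled", "size"),
    )
    if len(grouped) < n_bins:
        warnings.warn(
            f"only {len(grouped)} of {n_bins} size bins are nonempty", stacklevel=2
        )
    return grouped.reset_index(drop=True)


def _similarity_per_log(
    logs: Sequence[RecallLog], similarity
) -> list[np.ndarray]:
    if isinstance(similarity, np.ndarray) and similarity.ndim == 2:
        sims = [np.asarray(similarity, dtype=np.float64)] * len(logs)
    elif isinstance(similarity, (list, tuple)):
        sims = [np.asarray(s, dtype=np.float64) for s in similarity]
    else:
        sims = [np.asarray(similarity, dtype=np.float64)] * len(logs)
    if len(sims) != len(logs):
        raise ParameterError("one similarity matrix per log is required")
    for sim, log in zip(sims, logs):
        if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
            raise ParameterError("similarity must be a square matrix")
        if sim.shape[0] != log.n_memories:
            raise ParameterError("similarity size must match the log's item count")
        if not np.allclose(sim, sim.T):
            raise ParameterError("similarity matrix must be symmetric")
    return sims


def transition_table(logs: Sequence[RecallLog], similarity) -> pd.DataFrame:
    """One row per transition: source, destination, IRT, pair similarity."""
    logs = list(logs)
    sims = _similarity_per_log(logs, similarity)
    rows = []
    for log, sim in zip(logs, sims):
        for src, dst, t_src, t_dst in log.transitions:
            rows.append(
                {
                    "trial": log.trial_id,
                    "src": src,
                    "dst": dst,
                    "irt": t_dst - t_src,
                    "similarity": sim[src, dst],
                }
            )
    return pd.DataFrame(rows, columns=["trial", "src", "dst", "irt", "similarity"])


def transition_rank_distribution(
    logs: Sequence[RecallLog], similarity
) -> pd.Series:
    """Probability of transitions by similarity rank (1 = least, P-1 = most).

    For each transition ``a -> b`` the similarity ``sim(a, b)`` is ranked
    (ascending) among ``{sim(a, x): x != a}``; ties receive mean fractional
    ranks, whose mass is split between the adjacent integer ranks so the
    distribution stays normalised.
    """
    logs = list(logs)
    sims = _similarity_per_log(logs, similarity)
    P = logs[0].n_memories if logs else 0
    mass = np.zeros(P - 1)
    total = 0
    for log, sim in zip(logs, sims):
        for src, dst, _, _ in log.transitions:
            others = np.delete(np.arange(log.n_memories), src)
            ranks = rankdata(sim[src, others], method="average")
            rho = ranks[np.flatnonzero(others == dst)[0]]
            lo = int(np.floor(rho))
            hi = int(np.ceil(rho))
            if lo == hi:
                mass[lo - 1] += 1.0
            else:
                mass[lo - 1] += hi - rho
                mass[hi - 1] += rho - lo
            total += 1
    probs = mass / total if total else mass
    return pd.Series(probs, index=pd.RangeIndex(1, P, name="rank"), name="probability")


def irt_vs_similarity(
    logs: Sequence[RecallLog], similarity, n_bins: int = 8
) -> pd.DataFrame:
    """Mean inter-recall time of transitions binned by pair similarity."""
    table = transition_table(logs, similarity)
    if table.empty:
        raise ParameterError("no transitions found in the supplied logs")
    if table["similarity"].nunique() == 1:
        return pd.DataFrame(
            {
                "similarity_mean": [table["similarity"].iloc[0]],
                "mean_irt": [table["irt"].mean()],
                "n_transitions": [len(table)],
            }
        )
    table["bin"] = pd.qcut(table["similarity"], q=n_bins, duplicates="drop")
    grouped = table.groupby("bin", observed=True).agg(
        similarity_mean=("similarity", "mean"),
        mean_irt=("irt", "mean"),
        n_transitions=("irt", "size"),
    )
    return grouped.reset_index(drop=True)


def performance_sweep(
    parameter: str,
    values: Sequence[float],
    base_config,
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- SE of distinct items retrieved as a parameter is swept.

    ``parameter`` is ``"j_plus"`` (contiguity sweep, with ``j_minus`` held at
    its configured value) or ``"xi0"`` (noise sweep).  Each value runs
    ``n_trials`` independent trials with seeds derived from ``seed``.
    """
    from . import experiments  # local import: experiments builds on this module

    if parameter not in ("j_plus", "xi0"):
        raise ParameterError(f"unknown sweep parameter: {parameter!r}")
    values = list(values)
    if not values:
        raise ParameterError("sweep values must be nonempty")
    children = np.random.SeedSequence(seed).spawn(len(values))
    rows = []
    for value, child in zip(values, children):
        config = base_config.replace(
            **{parameter: float(value)},
            n_trials=n_trials,
            master_seed=int(child.generate_state(1)[0] % 2**31),
        )
        try:
            results = experiments.run_ensemble(config)
        except Exception as exc:  # annotate failures with the sweep context
            raise type(exc)(f"{parameter}={value}: {exc}") from exc
        counts = np.array([res.log.n_distinct for res in results], dtype=np.float64)
        rows.append(
            {
                "value": value,
                "mean_recalled": counts.mean(),
                "se": counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else 0.0,
                "n_trials": len(counts),
            }
        )
    return pd.DataFrame(rows)


def save_logs(path, logs: Sequence[RecallLog]) -> pd.DataFrame:
    """Write recall logs as a delimited text table (items 1-based)."""
    frame = pd.concat([log.to_frame() for log in logs], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def load_logs(path, n_memories: int, window: float | None = None) -> list[RecallLog]:
    """Read recall logs written by :func:`save_logs` (or external tables)."""
    frame = pd.read_csv(path, sep="\t")
    logs = []
    for trial, group in frame.groupby("trial"):
        group = group.sort_values("time")
        events = [
            RecallEvent(
                time=float(row.time),
                memory=int(row.item) - 1,
                cycle=int(getattr(row, "cycle", 0)),
                first_time=bool(row.first_time),
            )
            for row in group.itertuples()
        ]
        logs.append(
            RecallLog(
                events=events,
                n_memories=n_memories,
                window=window if window is not None else (events[-1].time if events else 0.0),
                trial_id=int(trial),
            )
        )
    return logs
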