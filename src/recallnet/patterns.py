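"""Sparse binary memory patterns, population partitions, and Hebbian couplings.

Each of the ``P`` items held in long-term memory is encoded by a random binary
vector over ``N`` neurons: neuron ``i`` belongs to memory ``mu`` with
probability ``f`` (the coding sparsity), independently across neurons and
memories.  The recurrent weights follow a covariance ("Hebbian") rule with a
uniform inhibitory offset, optionally augmented by asymmetric couplings that
chain items adjacent in presentation order (temporal contiguity).

Because every neuron is fully characterised by its membership vector
``eta_i in {0,1}^P``, neurons sharing a membership vector receive identical
recurrent input and can be lumped into a single *population*; the partition
into populations is the exact dimensionality reduction used by the fast
simulator and the mean-field analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneracyError, ParameterError, SizeError

__all__ = [
    "PatternSet",
    "PopulationPartition",
    "CouplingParams",
    "generate_patterns",
    "partition_populations",
    "full_connectivity",
    "reduced_coupling",
    "intersection_matrix",
    "population_probabilities",
    "save_patterns",
    "load_patterns",
    "export_intersections",
]


@dataclass(frozen=True)
class PatternSet:
    """The ``N x P`` binary memory code and its generating parameters.

    Attributes
    ----------
    eta:
        uint8 array of shape ``(n_neurons, n_memories)``; ``eta[i, mu] = 1``
        iff neuron ``i`` participates in memory ``mu``.
    sparsity:
        Bernoulli probability ``f`` of membership.
    seed:
        Seed used to generate ``eta`` (``None`` for externally supplied codes).
    """

    eta: np.ndarray
    sparsity: float
    seed: int | None = None

    def __post_init__(self) -> None:
        eta = np.ascontiguousarray(np.asarray(self.eta, dtype=np.uint8))
        object.__setattr__(self, "eta", eta)
        if eta.ndim != 2 or eta.size == 0:
            raise ParameterError("eta must be a nonempty 2-D (neuron x memory) array")
        if not np.isin(eta, (0, 1)).all():
            raise ParameterError("eta entries must be 0 or 1")
        if not 0.0 < self.sparsity < 1.0:
            raise ParameterError(f"sparsity must lie in (0, 1), got {self.sparsity}")
        if (eta.sum(axis=0) == 0).any():
            empty = np.flatnonzero(eta.sum(axis=0) == 0)
            raise DegeneracyError(f"memories with empty representation: {empty.tolist()}")

    @property
    def n_neurons(self) -> int:
        return self.eta.shape[0]

    @property
    def n_memories(self) -> int:
        return self.eta.shape[1]

    @property
    def representation_sizes(self) -> np.ndarray:
        """Number of neurons encoding each memory (column sums)."""
        return self.eta.sum(axis=0, dtype=np.int64)


@dataclass(frozen=True)
class PopulationPartition:
    """Grouping of neurons by identical membership vectors.

    ``vectors[k]`` is the distinct binary membership vector shared by
    ``counts[k]`` neurons; ``fractions`` are the empirical weights
    ``S_v = count / N``, which converge to ``f^|v| (1-f)^(P-|v|)`` as
    ``N -> infinity``.
    """

    vectors: np.ndarray  # (n_pop, P) uint8
    counts: np.ndarray  # (n_pop,) int64
    sparsity: float
    neuron_to_population: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vectors = np.ascontiguousarray(np.asarray(self.vectors, dtype=np.uint8))
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "counts", counts)
        if vectors.ndim != 2 or counts.ndim != 1 or len(vectors) != len(counts):
            raise ParameterError("vectors and counts must be aligned 2-D/1-D arrays")
        if (counts <= 0).any():
            raise ParameterError("population counts must be positive")

    @property
    def n_populations(self) -> int:
        return len(self.counts)

    @property
    def n_neurons(self) -> int:
        return int(self.counts.sum())

    @property
    def n_memories(self) -> int:
        return self.vectors.shape[1]

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_neurons

    @property
    def memory_fractions(self) -> np.ndarray:
        """Fraction of neurons belonging to each memory, per memory."""
        return self.fractions @ self.vectors

    def index_of(self, vector: np.ndarray) -> int:
        """Row index of a membership vector; raises ``KeyError`` if absent."""
        v = np.asarray(vector, dtype=np.uint8)
        hit = np.flatnonzero((self.vectors == v).all(axis=1))
        if hit.size == 0:
            raise KeyError(f"population {v.tolist()} not present in partition")
        return int(hit[0])


@dataclass(frozen=True)
class CouplingParams:
    """Strengths of the recurrent couplings.

    ``kappa`` scales the Hebbian excitation, ``phi`` is the (baseline)
    relative strength of uniform feedback inhibition, and ``j_plus`` /
    ``j_minus`` couple each memory to the items presented just after /
    before it (temporal contiguity; zero disables it).
    """

    kappa: float
    phi: float
    j_plus: float = 0.0
    j_minus: float = 0.0

    def __post_init__(self) -> None:
        # kappa = 0 is admitted for validation runs (pure decay dynamics)
        if self.kappa < 0:
            raise ParameterError(f"kappa must be nonnegative, got {self.kappa}")
        if self.j_plus < 0 or self.j_minus < 0:
            raise ParameterError("contiguity couplings must be nonnegative")


def generate_patterns(
    n_neurons: int,
    n_memories: int,
    sparsity: float,
    seed: int | None = None,
    max_retries: int = 100,
) -> PatternSet:
    """Draw i.i.d. Bernoulli(``sparsity``) membership bits for every neuron.

    Memories that come out with an all-zero column (no neuron recruited) are
    redrawn, so every memory has representation size >= 1; after
    ``max_retries`` failed redraws a :class:`DegeneracyError` is raised
    (pathological ``N * f``).
    """
    if not 0.0 < sparsity < 1.0:
        raise ParameterError(f"sparsity must lie in (0, 1), got {sparsity}")
    if n_neurons < 1 or n_memories < 1:
        raise ParameterError("n_neurons and n_memories must be >= 1")
    rng = np.random.default_rng(seed)
    eta = (rng.random((n_neurons, n_memories)) < sparsity).astype(np.uint8)
    for _ in range(max_retries):
        empty = np.flatnonzero(eta.sum(axis=0) == 0)
        if empty.size == 0:
            break
        eta[:, empty] = (rng.random((n_neurons, empty.size)) < sparsity).astype(np.uint8)
    else:
        raise DegeneracyError(
            f"could not obtain nonempty memories after {max_retries} retries "
            f"(N={n_neurons}, f={sparsity})"
        )
    return PatternSet(eta=eta, sparsity=sparsity, seed=seed)


def partition_populations(patterns: PatternSet) -> PopulationPartition:
    """Group neurons with identical membership vectors into populations."""
    eta = patterns.eta
    P = patterns.n_memories
    if P <= 62:
        # pack membership bits into integers for a fast exact grouping
        weights = (1 << np.arange(P, dtype=np.int64))
        codes = eta.astype(np.int64) @ weights
        uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
        vectors = ((uniq[:, None] >> np.arange(P, dtype=np.int64)) & 1).astype(np.uint8)
    else:
        vectors, inverse, counts = np.unique(
            eta, axis=0, return_inverse=True, return_counts=True
        )
    return PopulationPartition(
        vectors=vectors,
        counts=counts,
        sparsity=patterns.sparsity,
        neuron_to_population=inverse.astype(np.int64),
    )


def population_probabilities(vectors: np.ndarray, sparsity: float) -> np.ndarray:
    """Analytic large-``N`` weight of each membership vector.

    ``S_v = f^|v| * (1-f)^(P-|v|)`` where ``|v|`` is the number of memories
    the population belongs to.
    """
    v = np.asarray(vectors)
    card = v.sum(axis=1)
    P = v.shape[1]
    return sparsity**card * (1.0 - sparsity) ** (P - card)


def full_connectivity(
    patterns: PatternSet,
    coupling: CouplingParams,
    max_neurons: int = 2000,
) -> np.ndarray:
    """Materialise the full ``N x N`` weight matrix (validation scale only).

    ``J_ij = (kappa/N) * (sum_mu (eta_i^mu - f)(eta_j^mu - f) - phi)`` plus
    the contiguity terms ``(J+/N) sum eta_i^mu eta_j^(mu+1)`` and
    ``(J-/N) sum eta_i^mu eta_j^(mu-1)``.  The ``1/N`` prefactor on the
    contiguity part keeps the neuron-level system exactly equivalent to the
    population-reduced one (see :func:`reduced_coupling`).

    Raises :class:`SizeError` for ``N > max_neurons`` — use the reduced
    coupling for large networks.
    """
    N = patterns.n_neurons
    if N > max_neurons:
        raise SizeError(
            f"N={N} exceeds the materialisation guard ({max_neurons}); "
            "use reduced_coupling on the population partition instead"
        )
    f = patterns.sparsity
    centered = patterns.eta.astype(np.float64) - f
    J = (coupling.kappa / N) * (centered @ centered.T - coupling.phi)
    if coupling.j_plus or coupling.j_minus:
        eta = patterns.eta.astype(np.float64)
        J += (coupling.j_plus / N) * (eta[:, :-1] @ eta[:, 1:].T)
        J += (coupling.j_minus / N) * (eta[:, 1:] @ eta[:, :-1].T)
    return J


def reduced_coupling(
    partition: PopulationPartition, coupling: CouplingParams
) -> np.ndarray:
    """Population-level coupling matrix of the reduced dynamics.

    ``Jt_vw = kappa * (sum_mu (v^mu - f)(w^mu - f) - phi) +
    J+ sum_mu v^mu w^(mu+1) + J- sum_mu v^mu w^(mu-1)``.

    In the reduced rate equation the presynaptic weight ``S_w`` multiplies
    ``Jt_vw``, so the ``1/N`` of the neuron-level rule is already absorbed
    and the inhibition ``phi`` is subtracted once per weight.
    """
    f = partition.sparsity
    V = partition.vectors.astype(np.float64)
    centered = V - f
    Jt = coupling.kappa * (centered @ centered.T - coupling.phi)
    if coupling.j_plus or coupling.j_minus:
        Jt += coupling.j_plus * (V[:, :-1] @ V[:, 1:].T)
        Jt += coupling.j_minus * (V[:, 1:] @ V[:, :-1].T)
    return Jt


def intersection_matrix(patterns: PatternSet) -> np.ndarray:
    """``P x P`` matrix of pairwise intersection sizes.

    Entry ``(mu, nu)`` counts neurons encoding both items; the diagonal
    holds the representation sizes.
    """
    eta = patterns.eta.astype(np.int64)
    return eta.T @ eta


# ---------------------------------------------------------------------------
# serialization


def save_patterns(path, patterns: PatternSet, partition: PopulationPartition | None = None) -> None:
    """Save a pattern set (and optionally its partition) to an ``.npz`` file."""
    payload: dict[str, np.ndarray | float | int] = {
        "eta": patterns.eta,
        "sparsity": np.float64(patterns.sparsity),
        "seed": np.int64(-1 if patterns.seed is None else patterns.seed),
    }
    if partition is not None:
        payload["vectors"] = partition.vectors
        payload["counts"] = partition.counts
    np.savez_compressed(path, **payload)


def load_patterns(path) -> PatternSet:
    with np.load(path) as data:
        seed = int(data["seed"])
        return PatternSet(
            eta=data["eta"],
            sparsity=float(data["sparsity"]),
            seed=None if seed < 0 else seed,
        )


def export_intersections(path, patterns: PatternSet) -> pd.DataFrame:
    """Write the intersection-size matrix as a TSV with 1-based memory labels."""
    inter = intersection_matrix(patterns)
    labels = [f"memory_{mu}" for mu in range(1, patterns.n_memories + 1)]
    frame = pd.DataFrame(inter, index=labels, columns=labels)
    frame.index.name = "memory"
    frame.to_csv(path, sep="\t")
    return frame
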