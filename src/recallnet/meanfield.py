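"""Mean-field fixed-point theory of the sparse attractor network.

In the large-``N`` limit the network state is summarised by the overlaps
``m^mu`` and the mean activity ``m0``; populations are weighted by the
analytic probabilities ``S_v = f^|v| (1-f)^(P-|v|)`` and the fixed points
solve

    m^mu = sum_v (v^mu - f) S_v g(c_v),   m0 = sum_v S_v g(c_v),
    c_v  = kappa * (sum_nu (v^nu - f) m^nu - phi m0).

For the symmetric ``Q``-intersection ansatz (``Q`` memories share the common
overlap ``m_active``, all others zero; only populations belonging to all
``Q`` active memories fire) the system collapses to one scalar equation.
With the square-root gain (``gamma = 1/2``) it is solvable in closed form,
and the solution exists iff ``phi < (1-f)^2 Q`` at ``theta = 0`` — so an
inhibition sweep across that boundary toggles the network between
single-memory attractors and pair intersections, which is the engine of the
retrieval dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import GainSpec
from .errors import ParameterError, SizeError
from .patterns import CouplingParams, population_probabilities

__all__ = [
    "MeanfieldSolution",
    "AnsatzReport",
    "PhaseDiagram",
    "all_population_vectors",
    "fixed_point_residual",
    "closed_form_solution",
    "power_gain_solution",
    "verify_ansatz",
    "phase_diagram_scan",
]

_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class MeanfieldSolution:
    """A symmetric ``Q``-intersection fixed-point candidate.

    ``exists`` is False when the self-consistency equation admits no positive
    mean activity; ``ansatz_ok`` (set by :func:`verify_ansatz`) records
    whether the current-sign conditions defining the ansatz actually hold.
    """

    q_active: int
    m0: float
    m_active: float
    m_inactive: float = 0.0
    exists: bool = True
    ansatz_ok: bool | None = None
    f: float = 0.1
    kappa: float = 13000.0
    phi: float = 0.7
    theta: float = 0.0
    gamma: float = 0.5

    def overlap_vector(self, n_memories: int) -> np.ndarray:
        """Full ``(m^1..m^P, m0)`` vector with the first ``Q`` memories active."""
        m = np.zeros(n_memories + 1)
        m[: self.q_active] = self.m_active
        m[-1] = self.m0
        return m


@dataclass(frozen=True)
class AnsatzReport:
    ok: bool
    margin: float  # minimal signed margin over all current-sign conditions
    worst_class: int  # number of active memberships of the tightest class


def all_population_vectors(n_memories: int) -> np.ndarray:
    """All ``2^P`` membership vectors, one per row (uint8)."""
    if n_memories > _ENUMERATION_LIMIT:
        raise SizeError(
            f"P={n_memories} exceeds the exact-enumeration limit "
            f"({_ENUMERATION_LIMIT}); pass mc_samples for Monte-Carlo weighting"
        )
    codes = np.arange(2**n_memories, dtype=np.int64)
    return ((codes[:, None] >> np.arange(n_memories)) & 1).astype(np.uint8)


def fixed_point_residual(
    overlaps: np.ndarray,
    n_memories: int,
    f: float,
    coupling: CouplingParams,
    gain_spec: GainSpec,
    mc_samples: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Residual ``m - F(m)`` of the overlap fixed-point map.

    ``overlaps`` is the ``(P+1,)`` vector ``(m^1..m^P, m0)``.  ``F`` evaluates
    the mean-field map by exact enumeration over all ``2^P`` populations
    weighted by the analytic ``S_v`` (or by ``mc_samples`` Bernoulli draws
    for ``P`` beyond the enumeration limit).  Contiguity couplings are outside
    the mean-field theory and must be zero.
    """
    overlaps = np.asarray(overlaps, dtype=np.float64)
    if overlaps.shape != (n_memories + 1,):
        raise ParameterError(f"overlaps must have shape ({n_memories + 1},)")
    if coupling.j_plus or coupling.j_minus:
        raise ParameterError("mean-field theory assumes j_plus = j_minus = 0")
    if mc_samples is None:
        V = all_population_vectors(n_memories).astype(np.float64)
        S = population_probabilities(V, f)
    else:
        rng = np.random.default_rng(seed)
        V = (rng.random((mc_samples, n_memories)) < f).astype(np.float64)
        S = np.full(mc_samples, 1.0 / mc_samples)
    m, m0 = overlaps[:-1], overlaps[-1]
    centered = V - f
    c = coupling.kappa * (centered @ m - coupling.phi * m0)
    r = gain_spec(c)
    new = np.empty_like(overlaps)
    new[:-1] = centered.T @ (S * r)
    new[-1] = S @ r
    return overlaps - new


def closed_form_solution(
    q_active: int,
    f: float,
    kappa: float,
    phi: float,
    theta: float = 0.0,
) -> MeanfieldSolution:
    """Closed-form ``Q``-intersection solution for the square-root gain.

    Under the ansatz only populations inside all ``Q`` active memories fire,
    at the common current ``c_Q = kappa m0 ((1-f)^2 Q - phi)``, giving the
    scalar self-consistency ``m0 = f^Q sqrt(c_Q + theta)`` whose positive
    root is

        m0 = (A f^(2Q) + sqrt(A^2 f^(4Q) + 4 theta f^(2Q))) / 2,
        A  = kappa ((1-f)^2 Q - phi),

    with ``m_active = (1-f) m0`` for every active memory.  At ``theta = 0``
    the solution exists iff ``phi < (1-f)^2 Q``.
    """
    if q_active < 1:
        raise ParameterError(f"q_active must be >= 1, got {q_active}")
    if not 0.0 < f < 1.0:
        raise ParameterError(f"f must lie in (0, 1), got {f}")
    A = kappa * ((1.0 - f) ** 2 * q_active - phi)
    f2q = f ** (2 * q_active)
    m0 = 0.5 * (A * f2q + np.sqrt(A * A * f2q * f2q + 4.0 * theta * f2q))
    exists = bool(m0 > 0.0)
    return MeanfieldSolution(
        q_active=q_active,
        m0=float(m0) if exists else 0.0,
        m_active=float((1.0 - f) * m0) if exists else 0.0,
        exists=exists,
        f=f,
        kappa=kappa,
        phi=phi,
        theta=theta,
        gamma=0.5,
    )


def power_gain_solution(
    q_active: int,
    f: float,
    kappa: float,
    phi: float,
    gain_spec: GainSpec,
) -> MeanfieldSolution:
    """``Q``-intersection solution for a general power-law gain.

    Solves the scalar self-consistency
    ``m0 = f^Q (kappa m0 ((1-f)^2 Q - phi) + theta)^gamma`` with a bracketed
    root search; reduces to :func:`closed_form_solution` at ``gamma = 1/2``.
    """
    if q_active < 1:
        raise ParameterError(f"q_active must be >= 1, got {q_active}")
    A = kappa * ((1.0 - f) ** 2 * q_active - phi)
    fq = f**q_active
    gamma, theta = gain_spec.gamma, gain_spec.theta
    if A <= 0.0 and theta == 0.0:
        return MeanfieldSolution(
            q_active=q_active, m0=0.0, m_active=0.0, exists=False,
            f=f, kappa=kappa, phi=phi, theta=theta, gamma=gamma,
        )
    if theta == 0.0:
        # closed form for any gamma < 1 at zero threshold
        m0 = (fq * (A ** gamma)) ** (1.0 / (1.0 - gamma)) if gamma < 1.0 else np.nan
        if gamma == 1.0:
            raise ParameterError("gamma = 1 with theta = 0 has no isolated root")
    else:
        def h(m0):
            arg = A * m0 + theta
            return m0 - fq * (arg**gamma if arg > 0 else 0.0)

        # upper bracket: h(m) > 0 for large m since gain is sublinear
        hi = max(1.0, fq * (abs(A) + theta) ** gamma)
        while h(hi) <= 0:
            hi *= 2.0
        lo = 1e-300
        if h(lo) >= 0.0:  # no strictly positive root
            return MeanfieldSolution(
                q_active=q_active, m0=0.0, m_active=0.0, exists=False,
                f=f, kappa=kappa, phi=phi, theta=theta, gamma=gamma,
            )
        m0 = brentq(h, lo, hi, xtol=1e-14, rtol=1e-14)
    exists = bool(np.isfinite(m0) and m0 > 0.0)
    return MeanfieldSolution(
        q_active=q_active,
        m0=float(m0) if exists else 0.0,
        m_active=float((1.0 - f) * m0) if exists else 0.0,
        exists=exists,
        f=f,
        kappa=kappa,
        phi=phi,
        theta=theta,
        gamma=gamma,
    )


def verify_ansatz(
    solution: MeanfieldSolution,
    f: float | None = None,
    coupling: CouplingParams | None = None,
    gain_spec: GainSpec | None = None,
) -> AnsatzReport:
    """Check the current-sign conditions defining the ``Q``-intersection ansatz.

    A population's current depends only on how many of the ``Q`` active
    memories it belongs to (``n = 0..Q``):
    ``c_n = kappa (m_active (n - Q f) - phi m0)``.  The ansatz requires
    ``c_Q + theta > 0`` (populations inside all active memories fire) and
    ``c_n + theta < 0`` for ``n < Q`` (everything else silent).  Returns the
    minimal signed margin; a nonpositive margin flags the violating class.
    """
    if not solution.exists:
        raise ParameterError("cannot verify the ansatz of a non-existing solution")
    f = solution.f if f is None else f
    kappa = solution.kappa if coupling is None else coupling.kappa
    phi = solution.phi if coupling is None else coupling.phi
    theta = solution.theta if gain_spec is None else gain_spec.theta
    Q = solution.q_active
    n = np.arange(Q + 1)
    c_n = kappa * (solution.m_active * (n - Q * f) - phi * solution.m0)
    margins = np.empty(Q + 1)
    margins[:Q] = -(c_n[:Q] + theta)  # silent classes need c + theta < 0
    margins[Q] = c_n[Q] + theta  # firing class needs c + theta > 0
    worst = int(np.argmin(margins))
    return AnsatzReport(ok=bool(margins.min() > 0.0), margin=float(margins.min()), worst_class=worst)


@dataclass(frozen=True)
class PhaseDiagram:
    """Existence/validity map of ``Q``-intersection states over a (kappa, phi) grid."""

    kappa_grid: np.ndarray
    phi_grid: np.ndarray
    valid_q: np.ndarray  # (n_kappa, n_phi, q_max) bool: exists AND ansatz holds
    labels: np.ndarray = field(repr=False)  # (n_kappa, n_phi) object array of str

    def to_frame(self) -> pd.DataFrame:
        """Tidy (kappa, phi, label) table suitable for contour plotting."""
        kk, pp = np.meshgrid(self.kappa_grid, self.phi_grid, indexing="ij")
        return pd.DataFrame(
            {"kappa": kk.ravel(), "phi": pp.ravel(), "label": self.labels.ravel()}
        )


def _phase_label(valid: np.ndarray) -> str:
    qs = [q + 1 for q in range(len(valid)) if valid[q]]
    if not qs:
        return "none"
    if qs == [1]:
        return "single"
    if qs == [1, 2]:
        return "single+pair"
    return "+".join(f"Q{q}" for q in qs)


def phase_diagram_scan(
    kappa_range: np.ndarray,
    phi_range: np.ndarray,
    f: float,
    theta: float = 0.0,
    q_max: int = 3,
    gamma: float = 0.5,
) -> PhaseDiagram:
    """Evaluate solution existence + ansatz validity over a parameter grid.

    Each cell is labelled by the set of ``Q``-intersection states that both
    exist and satisfy their current-sign ansatz at that (kappa, phi).
    """
    kappa_range = np.atleast_1d(np.asarray(kappa_range, dtype=np.float64))
    phi_range = np.atleast_1d(np.asarray(phi_range, dtype=np.float64))
    if kappa_range.size == 0 or phi_range.size == 0:
        raise ParameterError("kappa and phi grids must be nonempty")
    gain_spec = GainSpec(gamma=gamma, theta=theta)
    valid = np.zeros((kappa_range.size, phi_range.size, q_max), dtype=bool)
    labels = np.empty((kappa_range.size, phi_range.size), dtype=object)
    for i, kappa in enumerate(kappa_range):
        for j, phi in enumerate(phi_range):
            for q in range(1, q_max + 1):
                if gamma == 0.5:
                    sol = closed_form_solution(q, f, kappa, phi, theta)
                else:
                    sol = power_gain_solution(q, f, kappa, phi, gain_spec)
                if sol.exists:
                    valid[i, j, q - 1] = verify_ansatz(sol).ok
            labels[i, j] = _phase_label(valid[i, j])
    return PhaseDiagram(
        kappa_grid=kappa_range, phi_grid=phi_range, valid_q=valid, labels=labels
    )
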