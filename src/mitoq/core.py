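"""Core domain types: quality distributions, process time laws, and quality metrics.

The model tracks a single mitochondrion's quality as a discrete state
``q = 0..Q`` (``q = 0`` is the inactive, depolarized state) occupied with
probability ``P(q, t)``.  Every quality-changing process ``i`` carries a
time-dependent probability following an exponential decay or growth law

    rho_i(t) = rho0_i * exp(+-t / tau_i)

with starting probability ``rho0_i`` and lifetime ``tau_i`` (in arbitrary
time units, "tu").  A process that is constant over the simulated horizon
is conventionally represented by a very large lifetime (``tau = 5e8`` tu);
an exact constant mode is also available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "LONG_LIFETIME",
    "NORM_TOL",
    "Direction",
    "ProcessTimeLaw",
    "QualityDistribution",
    "ModelParameters",
    "MetricsPoint",
    "rho_of_t",
    "hill_rate",
    "compute_metrics",
]

#: Lifetime conventionally used to freeze a process in time (tu).
LONG_LIFETIME = 5e8

#: Probability-conservation integrity tolerance: N_prob must equal 1 to at
#: least the 12th decimal, and no state may dip below -NORM_TOL.
NORM_TOL = 1e-12


class Direction(str, enum.Enum):
    """Sign of the exponential time law (or an exact constant)."""

    DECAY = "decay"
    GROWTH = "growth"
    CONSTANT = "constant"


@dataclass(frozen=True)
class ProcessTimeLaw:
    """Exponential time law ``rho(t) = rho0 * exp(+-t/tau)`` for one process.

    Parameters
    ----------
    rho0
        Starting probability of the process, in [0, 1].
    tau
        Lifetime in tu, > 0.  ``LONG_LIFETIME`` effectively freezes the
        process over any realistic horizon.
    direction
        ``decay`` for ``exp(-t/tau)``, ``growth`` for ``exp(+t/tau)``,
        ``constant`` for an exact time-independent probability.
    cap
        If True, a growth law saturates at 1 instead of raising once it
        exceeds 1 (the process then simply fires at every step).  Only
        a few strongly boosted scenario variants need this; by default
        exceeding 1 signals a parameter/horizon mismatch.
    """

    rho0: float
    tau: float = LONG_LIFETIME
    direction: Direction = Direction.CONSTANT
    cap: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho0 <= 1.0:
            raise ValueError(f"rho0 must lie in [0, 1], got {self.rho0}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        object.__setattr__(self, "direction", Direction(self.direction))

    def at(self, t: float) -> float:
        """Evaluate the law at time ``t`` (tu); alias of :func:`rho_of_t`."""
        return rho_of_t(self, t)


def rho_of_t(law: ProcessTimeLaw, t: float) -> float:
    """Evaluate a process time law at time ``t >= 0``.

    Raises
    ------
    ValueError
        If ``t`` is negative, or the evaluated probability exceeds 1
        (a parameter/horizon mismatch: the law is no longer a probability).
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if law.direction is Direction.CONSTANT:
        return law.rho0
    sign = -1.0 if law.direction is Direction.DECAY else 1.0
    value = law.rho0 * float(np.exp(sign * t / law.tau))
    if value > 1.0:
        if law.cap:
            return 1.0
        raise ValueError(
            f"time law evaluates to {value} > 1 at t={t} "
            f"(rho0={law.rho0}, tau={law.tau}, {law.direction.value}); "
            "the parameters do not support this horizon"
        )
    return value


def hill_rate(delta, ff1: float, ff2: float):
    """Hill-equation rate ``delta^FF1 / (FF2^FF1 + delta^FF1)``.

    Models the sigmoidal gain of an exchange between two mitochondria as a
    function of their (non-negative) quality difference ``delta``.  Accepts
    scalars or arrays; returns a value in [0, 1) that is 0 at ``delta = 0``
    and monotonically increasing.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("delta must be non-negative")
    if ff1 <= 0 or ff2 <= 0:
        raise ValueError("Hill coefficients FF1, FF2 must be positive")
    num = d**ff1
    out = num / (ff2**ff1 + num)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class QualityDistribution:
    """Probability mass over the discrete quality states ``0..Q``.

    Invariants: all entries >= 0 (more than 1e-12 below zero is an error)
    and the entries sum to 1 to at least the 12th decimal.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("probs must be a 1-D vector over states 0..Q, Q >= 1")
        if p.min() < -NORM_TOL:
            q_bad = int(p.argmin())
            raise ValueError(
                f"negative probability {p[q_bad]} at state q={q_bad}"
            )
        total = p.sum()
        if abs(total - 1.0) > NORM_TOL:
            raise ValueError(f"probabilities sum to {total!r}, expected 1 +- 1e-12")
        p = p.copy()
        p.flags.writeable = False
        object.__setattr__(self, "probs", p)

    @property
    def Q(self) -> int:
        """Maximal quality state."""
        return self.probs.size - 1

    @classmethod
    def uniform(cls, Q: int) -> "QualityDistribution":
        """Uniform start: each of the Q+1 states gets probability 1/(Q+1)."""
        return cls(np.full(Q + 1, 1.0 / (Q + 1)))

    @classmethod
    def delta(cls, Q: int, q: int) -> "QualityDistribution":
        """All probability mass concentrated at state ``q``."""
        p = np.zeros(Q + 1)
        p[q] = 1.0
        return cls(p)


@dataclass(frozen=True)
class ModelParameters:
    """All free parameters of the model.

    ``gamma`` balances metabolic against proteinaceous fission/fusion;
    ``ff1``/``ff2`` are the Hill coefficients shared by all networking
    rates; ``f_rd`` is the probability fraction exchanged in one external
    damage event.  The seven time laws drive the five processes (the
    proteinaceous part has separate fusion/fission laws that share
    ``rho0`` and ``tau`` but run in opposite directions).
    """

    gamma: float
    ff1: float
    ff2: float
    f_rd: float
    law_ffm: ProcessTimeLaw
    law_ffp_fusion: ProcessTimeLaw
    law_ffp_fission: ProcessTimeLaw
    law_mb: ProcessTimeLaw
    law_rep: ProcessTimeLaw
    law_ec: ProcessTimeLaw
    law_ed: ProcessTimeLaw

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.ff1 <= 0 or self.ff2 <= 0:
            raise ValueError("FF1 and FF2 must be positive")
        if not 0.0 <= self.f_rd <= 1.0:
            raise ValueError("f_rd must lie in [0, 1]")


class MetricsPoint(NamedTuple):
    """Quality metrics of one distribution at one time point.

    ``qbar`` is the average quality (first moment), ``sigma_q`` the mean
    absolute deviation of quality, ``p0`` the inactive fraction P(0, t)
    (a proxy for network fragmentation), and ``nprob`` the total
    probability mass (the integrity check, must stay at 1).
    """

    t: float
    qbar: float
    sigma_q: float
    p0: float
    nprob: float


def compute_metrics(P: QualityDistribution, t: float = 0.0) -> MetricsPoint:
    """Compute (q̄, σ_q, P(0), N_prob) for a distribution at time ``t``.

    q̄(t)   = Σ_q q·P(q,t)          (average quality, 0..Q scale)
    σ_q(t) = Σ_q |q − q̄|·P(q,t)    (mean absolute deviation)
    """
    p = P.probs
    q = np.arange(p.size, dtype=float)
    qbar = float(q @ p)
    sigma = float(np.abs(q - qbar) @ p)
    return MetricsPoint(t=t, qbar=qbar, sigma_q=sigma, p0=float(p[0]), nprob=float(p.sum()))
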