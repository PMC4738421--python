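"""The five quality-changing operators of the master equation.

Each deterministic operator returns the instantaneous probability-change
vector dP/dt (probability per tu) for its process; external damage is a
discrete stochastic map applied once per time step.  All deterministic
operators conserve total probability exactly (their DeltaP sums to 0),
which is what keeps N_prob = Σ_q P(q,t) pinned to 1 under Euler stepping.

Processes
---------
ff_metabolic   "kiss and run" outer-membrane contact: two active
               mitochondria mix metabolites and leave with the averaged
               quality; conserves the first moment (q1+q2 -> q1'+q2',
               q1' = q2', so only even-sum pairs react).
ff_protein     inner-membrane fusion raises the lower partner to the
               higher quality; fission sends one of two like-quality
               partners to the inactive state q = 0.
mb             mitophagy removes inactive-state probability, biogenesis
               re-creates it at the maximal quality Q (coupled, so mass
               is conserved).
repair         binomial restoration: each of the Q-q missing quality
               units is repaired with per-unit probability rho_rep(t).
ec             energy consumption: activity-dependent internal ROS
               damage; each of a state's q quality units is lost with
               per-unit probability rho_ec(t).
ed             external damage: with probability rho_ed(t) a random
               higher state donates a fraction f_rd of its mass to a
               random lower state.

The binomial kernels embed rho(t) inside the kernel itself; the other
processes factor out rho_i(t) as a prefactor.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np

from .core import ModelParameters, QualityDistribution, hill_rate, rho_of_t

__all__ = [
    "dP_ff_metabolic",
    "dP_ff_protein",
    "dP_mb",
    "dP_repair",
    "dP_ec",
    "repair_kernel",
    "ec_kernel",
    "apply_external_damage",
]


# ---------------------------------------------------------------------------
# Precomputed pair tables (small: Q <= 14, so at most ~200 pairs)

@lru_cache(maxsize=None)
def _ffm_tables(Q: int, ff1: float, ff2: float):
    """Ordered active pairs (q1, q2) with even sum, their Hill rates, and the
    scatter matrix mapping per-pair weights to DeltaP (+2 at the midpoint,
    -1 at each partner)."""
    i_idx, j_idx, rates = [], [], []
    scatter_cols = []
    for q1 in range(1, Q + 1):
        for q2 in range(1, Q + 1):
            if (q1 + q2) % 2:
                continue  # Kronecker deltas unsatisfiable for odd sums
            i_idx.append(q1)
            j_idx.append(q2)
            rates.append(hill_rate(abs(q1 - q2), ff1, ff2))
            col = np.zeros(Q + 1)
            col[(q1 + q2) // 2] += 2.0
            col[q1] -= 1.0
            col[q2] -= 1.0
            scatter_cols.append(col)
    scatter = np.column_stack(scatter_cols) if scatter_cols else np.zeros((Q + 1, 0))
    return (
        np.array(i_idx, dtype=np.intp),
        np.array(j_idx, dtype=np.intp),
        np.array(rates, dtype=float),
        scatter,
    )


@lru_cache(maxsize=None)
def _ffp_tables(Q: int, ff1: float, ff2: float):
    """Fusion tables over active pairs {hi > lo >= 1} plus the per-state
    fission Hill rates hill(Q - q).

    Pair encounters are counted once per ordering (either partner can play
    either role), so every weight carries a factor 2: in fusion the pair
    (hi, lo) reacts whichever member is "first", and in fission either
    member of the like-quality pair can be the one that depolarizes.  The
    metabolic operator gets the same counting for free from its ordered
    double sum.
    """
    hi_idx, lo_idx, rates, scatter_cols = [], [], [], []
    for hi in range(2, Q + 1):
        for lo in range(1, hi):
            hi_idx.append(hi)
            lo_idx.append(lo)
            rates.append(2.0 * hill_rate(hi - lo, ff1, ff2))
            col = np.zeros(Q + 1)
            col[hi] += 1.0  # the lower partner is raised to the higher quality
            col[lo] -= 1.0
            scatter_cols.append(col)
    scatter = np.column_stack(scatter_cols) if scatter_cols else np.zeros((Q + 1, 0))
    fission_rates = 2.0 * hill_rate(Q - np.arange(1, Q + 1), ff1, ff2)
    return (
        np.array(hi_idx, dtype=np.intp),
        np.array(lo_idx, dtype=np.intp),
        np.array(rates, dtype=float),
        scatter,
        np.asarray(fission_rates, dtype=float),
    )


@lru_cache(maxsize=None)
def _binomial_structure(Q: int, mirrored: bool):
    """Binomial coefficient matrix and exponent matrices for the repair
    (upper-triangular) or energy-consumption (mirrored) kernel."""
    n = Q + 1
    C = np.zeros((n, n))
    E = np.zeros((n, n))  # exponent of rho
    F = np.zeros((n, n))  # exponent of (1 - rho)
    for q_from in range(n):
        for q_to in range(n):
            if not mirrored and q_to >= q_from:
                C[q_from, q_to] = comb(Q - q_from, q_to - q_from)
                E[q_from, q_to] = q_to - q_from
                F[q_from, q_to] = Q - q_to
            elif mirrored and q_to <= q_from:
                C[q_from, q_to] = comb(q_from, q_from - q_to)
                E[q_from, q_to] = q_from - q_to
                F[q_from, q_to] = q_to
    return C, E, F


@lru_cache(maxsize=None)
def _ed_pairs(Q: int):
    """All (donor, recipient) state pairs with Q >= q' > q >= 0."""
    return [(hi, lo) for hi in range(1, Q + 1) for lo in range(hi)]


# ---------------------------------------------------------------------------
# Deterministic operators

def dP_ff_metabolic(P: QualityDistribution, t: float, params: ModelParameters) -> np.ndarray:
    """Metabolic ("kiss and run") fission/fusion rate term.

    For every ordered active pair (q1, q2) with an even sum, weight
    w = rho_FFm(t)·P(q1)·P(q2)·hill(|q1-q2|) flows out of q1 and q2 and
    into the common midpoint (q1+q2)/2 twice over.  Conserves both total
    probability and the first moment.
    """
    i_idx, j_idx, rates, scatter = _ffm_tables(P.Q, params.ff1, params.ff2)
    rho = rho_of_t(params.law_ffm, t)
    p = P.probs
    w = p[i_idx] * p[j_idx] * rates
    return rho * (scatter @ w)


def dP_ff_protein(P: QualityDistribution, t: float, params: ModelParameters) -> np.ndarray:
    """Proteinaceous (inner-membrane) fission/fusion rate term, unscaled.

    Fusion: for every active pair {hi > lo}, weight
    w = 2·rho_Fup(t)·P(hi)·P(lo)·hill(hi-lo) raises the lower partner to
    the higher quality.  Fission: a like-quality encounter at q (weight
    P(q)^2) sends one partner to the inactive state with rate
    2·rho_Fip(t)·hill(Q-q), so fission is most likely for low-quality
    states.  Encounters are counted once per pair ordering (see
    ``_ffp_tables``).  The caller scales the whole term by gamma.
    """
    hi_idx, lo_idx, fu_rates, scatter, fi_rates = _ffp_tables(P.Q, params.ff1, params.ff2)
    p = P.probs
    rho_fu = rho_of_t(params.law_ffp_fusion, t)
    rho_fi = rho_of_t(params.law_ffp_fission, t)
    dP = rho_fu * (scatter @ (p[hi_idx] * p[lo_idx] * fu_rates))
    v = rho_fi * p[1:] ** 2 * fi_rates
    dP[0] += v.sum()
    dP[1:] -= v
    return dP


def dP_mb(P: QualityDistribution, t: float, params: ModelParameters) -> np.ndarray:
    """Mitophagy/biogenesis rate term: drain the inactive state, create the
    same amount of probability at the maximal quality Q."""
    rho = rho_of_t(params.law_mb, t)
    dP = np.zeros(P.Q + 1)
    flux = rho * P.probs[0]
    dP[0] = -flux
    dP[-1] = flux
    return dP


def repair_kernel(rho: float, Q: int) -> np.ndarray:
    """Row-stochastic binomial repair kernel.

    Entry (q' -> q), q >= q', is C(Q-q', q-q')·rho^(q-q')·(1-rho)^(Q-q):
    each of the Q-q' missing quality units is independently restored with
    probability ``rho``.  rho = 0 gives the identity; rho = 1 sends every
    state to Q.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    C, E, F = _binomial_structure(Q, mirrored=False)
    return C * rho**E * (1.0 - rho) ** F


def ec_kernel(rho: float, Q: int) -> np.ndarray:
    """Row-stochastic binomial energy-consumption kernel (mirrored repair).

    Entry (q' -> q), q <= q', is C(q', q'-q)·rho^(q'-q)·(1-rho)^q: each of
    a state's q' quality units is independently lost with probability
    ``rho``, so more active (higher-q) states lose more on average.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    C, E, F = _binomial_structure(Q, mirrored=True)
    return C * rho**E * (1.0 - rho) ** F


def dP_repair(P: QualityDistribution, t: float, params: ModelParameters) -> np.ndarray:
    """Net repair flux: (repair kernel applied to P) - P.

    Conserves total mass and never decreases the average quality (the
    binomial mean adds (Q-q')·rho >= 0 per state).
    """
    K = repair_kernel(rho_of_t(params.law_rep, t), P.Q)
    return K.T @ P.probs - P.probs


def dP_ec(P: QualityDistribution, t: float, params: ModelParameters) -> np.ndarray:
    """Net energy-consumption flux: (ec kernel applied to P) - P.

    Conserves total mass and never increases the average quality."""
    K = ec_kernel(rho_of_t(params.law_ec, t), P.Q)
    return K.T @ P.probs - P.probs


# ---------------------------------------------------------------------------
# Stochastic external damage

def apply_external_damage(
    P: QualityDistribution,
    t: float,
    params: ModelParameters,
    rng: np.random.Generator,
) -> QualityDistribution:
    """One Bernoulli(rho_ed(t))-gated external-damage event.

    With probability rho_ed(t), a pair (q', q) with Q >= q' > q >= 0 is
    drawn uniformly at random and the fraction ``f_rd`` of P(q') moves to
    P(q); otherwise P is returned unchanged.  Mass is conserved exactly
    and the average quality never increases.  This is a discrete per-step
    map, not an Euler rate term.
    """
    rho = rho_of_t(params.law_ed, t)
    if rng.random() >= rho:
        return P
    pairs = _ed_pairs(P.Q)
    hi, lo = pairs[int(rng.integers(len(pairs)))]
    p = P.probs.copy()
    total = p.sum()
    moved = params.f_rd * p[hi]
    p[hi] -= moved
    p[lo] += moved
    # keep the two-bin transfer exactly mass-preserving in floating point
    p[lo] -= p.sum() - total
    return QualityDistribution(p)
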