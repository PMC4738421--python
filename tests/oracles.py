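"""Independent nested-loop transcriptions of the process operators.

These are deliberately naive: one Kronecker-style loop per target state,
binomial terms written with ``math.comb`` directly from the model's
double sums.  They share no code with the vectorized operators in
``mitoq.processes`` and serve as oracles in the equivalence tests.
"""

from math import comb

import numpy as np


def hill(delta, ff1, ff2):
    return 0.0 if delta == 0 else delta**ff1 / (ff2**ff1 + delta**ff1)


def naive_ffm(p, rho, ff1, ff2):
    """Metabolic fission/fusion over ordered active pairs with even sum."""
    Q = len(p) - 1
    d = np.zeros(Q + 1)
    for q in range(Q + 1):
        acc = 0.0
        for q1 in range(1, Q + 1):
            for q2 in range(1, Q + 1):
                if (q1 + q2) % 2:
                    continue
                m = (q1 + q2) // 2
                kron = (q == m) + (q == m) - (q == q1) - (q == q2)
                if kron:
                    acc += p[q1] * p[q2] * hill(abs(q1 - q2), ff1, ff2) * kron
        d[q] = rho * acc
    return d


def naive_ffp(p, rho_fu, rho_fi, ff1, ff2):
    """Proteinaceous fission/fusion, one event per ordering of each pair.

    Fusion: for each ordered pair of distinct active states the lower
    member is raised to the higher quality.  Fission: for each ordered
    like-quality pair one member (either of the two) drops to the
    inactive state.
    """
    Q = len(p) - 1
    d = np.zeros(Q + 1)
    for q1 in range(1, Q + 1):
        for q2 in range(1, Q + 1):
            if q1 != q2:
                hi, lo = max(q1, q2), min(q1, q2)
                w = rho_fu * p[q1] * p[q2] * hill(hi - lo, ff1, ff2)
                d[hi] += w
                d[lo] -= w
            else:
                for _member in range(2):
                    v = rho_fi * p[q1] * p[q2] * hill(Q - q1, ff1, ff2)
                    d[0] += v
                    d[q1] -= v
    return d


def naive_mb(p, rho):
    Q = len(p) - 1
    d = np.zeros(Q + 1)
    d[0] = -rho * p[0]
    d[Q] = rho * p[0]
    return d


def naive_repair(p, rho):
    """Direct transcription of the binomial repair gain/loss double sums."""
    Q = len(p) - 1
    d = np.zeros(Q + 1)
    for q in range(Q + 1):
        gain = sum(
            comb(Q - qp, q - qp) * rho ** (q - qp) * (1 - rho) ** (Q - q) * p[qp]
            for qp in range(q)
        )
        loss = sum(
            comb(Q - q, qpp - q) * rho ** (qpp - q) * (1 - rho) ** (Q - qpp) * p[q]
            for qpp in range(q + 1, Q + 1)
        )
        d[q] = gain - loss
    return d


def naive_ec(p, rho):
    """Direct transcription of the binomial energy-consumption double sums."""
    Q = len(p) - 1
    d = np.zeros(Q + 1)
    for q in range(Q + 1):
        gain = sum(
            comb(qp, qp - q) * rho ** (qp - q) * (1 - rho) ** q * p[qp]
            for qp in range(q + 1, Q + 1)
        )
        loss = sum(
            comb(q, q - qpp) * rho ** (q - qpp) * (1 - rho) ** qpp * p[q]
            for qpp in range(q)
        )
        d[q] = gain - loss
    return d
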