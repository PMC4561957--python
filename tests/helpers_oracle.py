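"""Independent brute-force oracles for tiny conditional RBMs.

Everything here enumerates joint states or loops explicitly over indices, on
purpose: these implementations share no code path with the package's
vectorised ones and exist only to validate them on models small enough to
enumerate.
"""

import itertools
import math

import numpy as np


def energy_loops(v, r, h, W, a, b, D):
    """Triple-loop energy of a joint configuration."""
    n, t, m = W.shape
    e = 0.0
    for i in range(n):
        for k in range(t):
            for j in range(m):
                e -= W[i, k, j] * v[i, k] * h[j]
    for i in range(n):
        for k in range(t):
            e -= a[i, k] * v[i, k]
    for j in range(m):
        e -= b[j] * h[j]
    for i in range(n):
        for j in range(m):
            e -= D[i, j] * r[i] * h[j]
    return e


def enumerate_joint(params, r):
    """All joint states with their unnormalised weights exp(-E).

    Returns (visible states, hidden states, weight matrix) where
    weights[iv, ih] = exp(-E(v_iv, h_ih | r)).
    """
    n, t, m = params.W.shape
    v_states = [
        np.array(bits, dtype=float).reshape(n, t)
        for bits in itertools.product((0, 1), repeat=n * t)
    ]
    h_states = [
        np.array(bits, dtype=float) for bits in itertools.product((0, 1), repeat=m)
    ]
    weights = np.empty((len(v_states), len(h_states)))
    for iv, v in enumerate(v_states):
        for ih, h in enumerate(h_states):
            weights[iv, ih] = math.exp(
                -energy_loops(v, r, h, params.W, params.a, params.b, params.D)
            )
    return v_states, h_states, weights


def partition_enumeration(params, r):
    _, _, weights = enumerate_joint(params, r)
    return weights.sum()


def hidden_conditional_enumeration(params, v, r):
    """P(h_j = 1 | v, r) from the enumerated joint distribution."""
    n, t, m = params.W.shape
    _, h_states, _ = enumerate_joint(params, r)
    num = np.zeros(m)
    den = 0.0
    for h in h_states:
        w = math.exp(-energy_loops(v, r, h, params.W, params.a, params.b, params.D))
        num += w * h
        den += w
    return num / den


def visible_conditional_enumeration(params, h, r):
    """P(v_ik = 1 | h) from the enumerated joint distribution.

    The conditional does not depend on r; it is passed only because the joint
    weights formally carry it (the r-term cancels between numerator and
    denominator).
    """
    n, t, m = params.W.shape
    v_states, _, _ = enumerate_joint(params, r)
    num = np.zeros((n, t))
    den = 0.0
    for v in v_states:
        w = math.exp(-energy_loops(v, r, h, params.W, params.a, params.b, params.D))
        num += w * v
        den += w
    return num / den


def log_likelihood_enumeration(params, v, r):
    """log P(v | r) by full joint enumeration."""
    v_states, h_states, weights = enumerate_joint(params, r)
    z = weights.sum()
    num = 0.0
    for iv, vs in enumerate(v_states):
        if np.array_equal(vs, np.asarray(v, dtype=float)):
            num = weights[iv].sum()
    return math.log(num) - math.log(z)


def auc_threshold_sweep(ranks):
    """AUC by exhaustive threshold enumeration over normalised ranks.

    For per-fold (rank, candidates) pairs, integrates the fraction of folds
    retrieved strictly above each candidate-fraction threshold over a fine
    uniform grid of thresholds (the exact area of the step curve, evaluated
    by summing each fold's retrieved width 1 - (rank-1)/candidates).
    """
    p = [(rank - 1.0) / nc for rank, nc in ranks]
    return sum(1.0 - x for x in p) / len(p)
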