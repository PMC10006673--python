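"""Entropy and KL-divergence objectives over flux/expression vectors.

For a nonnegative split-flux vector ``v`` with total ``V`` and per-reaction
expression ``g``, the flux-per-enzyme probability is P_g(v_i) = (v_i/g_i)/V
with multiplicity g_i, and its Shannon entropy collapses to

    H_g(v) = - sum_i (v_i / V) * log(v_i / (g_i * V))        [nats]

With ``epsilon`` smoothing (to keep the log finite when a flux or abundance
is zero) both the flux and the abundance are shifted inside the logarithm.
Maximizing H_g over the steady-state polytope at fixed V is equivalent to
minimizing the forward Kullback-Leibler divergence between the normalized
fluxome P = v/V and the normalized transcriptome Q = g/G:

    H_g(v) = -(1/V) * sum_i v_i log(v_i/g_i) + log V
"""

from __future__ import annotations

import numpy as np

__all__ = ["entropy_objective", "kl_objective"]


def _check_pair(v, g):
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if v.shape != g.shape or v.ndim != 1:
        raise ValueError(
            f"flux and expression must be 1-D and equal length, "
            f"got {v.shape} and {g.shape}"
        )
    return v, g


def entropy_objective(v, g, V: float, epsilon: float = 0.0) -> float:
    """Shannon entropy of fluxes per mRNA, in nats.

    Parameters
    ----------
    v, g : array-like, same length
        Nonnegative split fluxes and strictly positive (after flooring)
        per-reaction expression.
    V : float
        Positive total flux used as the normalizer (typically ``sum(v)`` or
        the fixed total imposed by the solver constraint).
    epsilon : float
        Smoothing added to ``v_i`` and ``g_i`` inside the logarithm; with
        ``epsilon=0`` and all entries positive this is the exact entropy.
    """
    v, g = _check_pair(v, g)
    if V <= 0:
        raise ValueError("V must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if epsilon == 0.0 and (np.any(v <= 0) or np.any(g <= 0)):
        raise ValueError(
            "zero entry with epsilon=0: entropy undefined; use epsilon>0"
        )
    return float(-(v / V) @ np.log((v + epsilon) / ((g + epsilon) * V)))


def kl_objective(v, g) -> float:
    """Forward KL divergence D(P||Q), P = v/sum(v), Q = g/sum(g), in nats.

    Nonnegative; zero iff ``v`` is proportional to ``g``.
    """
    v, g = _check_pair(v, g)
    if np.any(v <= 0) or np.any(g <= 0):
        raise ValueError("kl_objective requires strictly positive entries")
    p = v / v.sum()
    q = g / g.sum()
    return float(p @ np.log(p / q))
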