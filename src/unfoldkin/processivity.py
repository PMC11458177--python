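"""Processivity and single-turnover amplitude algebra.

Two equivalent descriptions of processivity are interconverted here:

* ``P`` — the per-step probability that the motor continues rather than
  dissociates, ``P = k_U / (k_U + k_d)``, where ``k_d`` is the rate
  constant for dissociation from each *intermediate* (deliberately a
  different quantity from ``k_end``, the terminal dissociation rate in the
  signal model, which contains no intermediate dissociation).
* ``N`` — the mean number of amino acids processed per binding event,
  related to ``P`` through the step-size ``m`` by ``P = exp(-m / N)``.

The expected single-turnover peak amplitude is the extent of binding
``X`` times ``P**n`` (the fraction of initially bound motors that survive
all ``n`` steps to reach the fluorophore) times a fluorescence output
factor.
"""
from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = [
    "extent_of_binding",
    "p_from_rates",
    "p_from_step_and_N",
    "N_from_p_and_step",
    "amplitude_model",
]


def extent_of_binding(bound: float, total: float) -> float:
    """Fraction of substrate in complex with the motor, in [0, 1].

    ``bound`` and ``total`` are concentrations in the same units
    (conventionally molar).
    """
    if not total > 0:
        raise DomainError(f"total concentration must be > 0, got {total}")
    if bound < 0 or bound > total:
        raise DomainError(
            f"bound concentration must lie in [0, total], got {bound}")
    return bound / total


def p_from_rates(k_U: float, k_d: float) -> float:
    """Per-step continuation probability ``P = k_U / (k_U + k_d)``."""
    if not k_U > 0:
        raise DomainError(f"k_U must be > 0, got {k_U}")
    if k_d < 0:
        raise DomainError(f"k_d must be >= 0, got {k_d}")
    return k_U / (k_U + k_d)


def p_from_step_and_N(m: float, N: float) -> float:
    """Per-step continuation probability ``P = exp(-m / N)``.

    ``m`` is the kinetic step-size and ``N`` the processivity, both in
    amino acids.
    """
    if not (m > 0 and N > 0):
        raise DomainError(f"need m > 0 and N > 0, got m={m}, N={N}")
    return float(np.exp(-m / N))


def N_from_p_and_step(P: float, m: float) -> float:
    """Processivity in amino acids, ``N = -m / ln(P)``.

    ``P = 1`` (infinite processivity) is flagged as a domain error rather
    than returning infinity.
    """
    if not 0 < P < 1:
        raise DomainError(
            f"P must lie strictly in (0, 1); P={P}"
            + (" corresponds to infinite N" if P >= 1 else ""))
    if not m > 0:
        raise DomainError(f"m must be > 0, got {m}")
    return -m / float(np.log(P))


def amplitude_model(X: float, P: float, n: float, fluor_factor: float) -> float:
    """Expected peak amplitude ``X * P**n * F``.

    Strictly decreasing in ``n`` for ``P < 1`` and increasing in the
    extent of binding ``X``: a smaller peak is consistent with less motor
    bound, lower processivity, or both.
    """
    if not 0 <= X <= 1:
        raise DomainError(f"extent of binding must be in [0, 1], got {X}")
    if not 0 < P <= 1:
        raise DomainError(f"P must be in (0, 1], got {P}")
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    if not fluor_factor > 0:
        raise DomainError(f"fluorescence factor must be > 0, got {fluor_factor}")
    return X * P**n * fluor_factor
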