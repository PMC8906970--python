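"""Time-fractional machinery for the constant proportional Caputo operator.

The CPC operator of order ``0 < alpha <= 1`` blends a Riemann-Liouville (RL)
term weighted by ``K1(alpha) = (1-alpha)*S**alpha`` with a Caputo term
weighted by ``K0(alpha) = alpha*S**(1-alpha)``; ``S`` is a kernel time scale
(we default it to the final simulation time).  At ``alpha = 1`` the operator
collapses to the classical first derivative (K0=1, K1=0).

Discretely the Caputo part uses the L1 scheme with weights
``z_k = (k+1)**(1-alpha) - k**(1-alpha)`` and the RL part a Grunwald-Letnikov
(GL) sum with binomial weights ``W_k = (-1)**k * C(beta, k)`` generated by the
recursion ``W_k = (1 - (beta+1)/k) * W_{k-1}``.

Two conventions are offered for the RL part:

* ``"as_printed"`` (default): a GL *derivative* of order ``1-alpha``,
  ``phi(dt)**-(1-alpha) * sum_k W_k^(1-alpha) u^{j-k}`` — this is what the
  assembled scheme and its stability constants are built on;
* ``"integral_consistent"``: a GL quadrature of the RL *integral*
  ``I^(1-alpha)``, ``phi(dt)**(1-alpha) * sum_k W_k^(-(1-alpha)) u^{j-k}``,
  matching the operator's integral definition.

Nonstandard (Mickens-type) denominator functions replace the raw steps dt, h
by phi(dt), psi(h) in every difference quotient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "CPCSpec",
    "DenominatorFunctions",
    "WeightTable",
    "cpc_kernels",
    "gl_weights",
    "gl_weights_binomial",
    "l1_z_weights",
    "caputo_l1_apply",
    "rl_history_apply",
    "make_denominators",
]


@dataclass(frozen=True)
class CPCSpec:
    """Fractional order, kernel scale and the two CPC kernel weights."""

    alpha: float
    S: float
    K0: float
    K1: float


@dataclass(frozen=True)
class DenominatorFunctions:
    """Mickens denominator functions for the time and space differences.

    ``phi`` maps the time step dt to the effective time denominator and
    ``psi`` maps the space step h to the effective space denominator; both
    must be strictly positive for positive arguments.  In ``standard`` mode
    they are exact identities.
    """

    phi: Callable[[float], float]
    psi: Callable[[float], float]
    mode: str


def cpc_kernels(alpha: float, S: float) -> CPCSpec:
    """Kernel weights K0 = alpha*S^(1-alpha), K1 = (1-alpha)*S^alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must satisfy 0 < alpha <= 1, got {alpha}")
    if not S > 0.0:
        raise ValueError(f"kernel time scale S must be > 0, got {S}")
    return CPCSpec(alpha=alpha, S=S, K0=alpha * S ** (1.0 - alpha), K1=(1.0 - alpha) * S**alpha)


@dataclass(frozen=True)
class WeightTable:
    """A cached family of quadrature weights of one fractional order."""

    order: float
    weights: np.ndarray


def gl_weights(beta: float, m: int) -> np.ndarray:
    """GL weights W_0..W_m of order beta via the stable recursion.

    W_0 = 1 and W_k = (1 - (beta+1)/k) W_{k-1}; equivalently
    W_k = (-1)^k * binom(beta, k).  Any real beta is accepted (negative
    orders give the weights of the corresponding fractional integral).
    """
    if m < 0:
        raise ValueError("history length m must be >= 0")
    w = np.empty(m + 1)
    w[0] = 1.0
    for k in range(1, m + 1):
        w[k] = (1.0 - (beta + 1.0) / k) * w[k - 1]
    return w


def gl_weights_binomial(beta: float, m: int) -> np.ndarray:
    """Gamma-function form of the GL weights (testing oracle).

    W_k = (-1)^k Gamma(beta+1) / (Gamma(k+1) Gamma(beta-k+1)).  Intended for
    modest k (the recursion in :func:`gl_weights` is the production path);
    Gamma poles at nonnegative integer beta with k > beta correctly yield 0.
    """
    from scipy.special import gamma as _gamma

    if beta == int(beta) and beta >= 0:
        from scipy.special import comb

        return np.array(
            [(-1.0) ** k * comb(int(beta), k, exact=True) for k in range(m + 1)], dtype=float
        )
    k = np.arange(m + 1, dtype=float)
    return (-1.0) ** k * _gamma(beta + 1.0) / (_gamma(k + 1.0) * _gamma(beta - k + 1.0))


def l1_z_weights(alpha: float, m: int) -> np.ndarray:
    """L1 weights z_k = (k+1)^(1-alpha) - k^(1-alpha), k = 0..m.

    z_0 = 1 always; for 0 < alpha < 1 the sequence is positive and strictly
    decreasing, and the partial sums telescope to m^(1-alpha).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must satisfy 0 < alpha <= 1, got {alpha}")
    if m < 0:
        raise ValueError("history length m must be >= 0")
    k = np.arange(m + 1, dtype=float)
    z = (k + 1.0) ** (1.0 - alpha) - k ** (1.0 - alpha)
    z[0] = 1.0  # 0**0 would otherwise pollute the alpha = 1 limit
    return z


def make_denominators(mode: str = "standard") -> DenominatorFunctions:
    """Named denominator-function pairs.

    ``standard``
        phi(dt) = dt, psi(h) = h (classical differences).
    ``nonstandard``
        phi(dt) = 0.001*(1 - exp(-dt)), psi(h) = 0.5*sinh(h/2) — the pair
        used for the model's nonstandard-scheme experiments.  Note this pair
        deliberately violates the consistency requirement phi(dt) = dt +
        O(dt^2) (phi ~ 0.001*dt and psi ~ h/4 for small steps).
    ``nonstandard-consistent``
        phi(dt) = 1 - exp(-dt), psi(h) = 2*sinh(h/2), a Mickens pair that
        does satisfy phi(dt) = dt + O(dt^2), psi(h) = h + O(h^3).
    """
    if mode == "standard":
        return DenominatorFunctions(phi=lambda dt: dt, psi=lambda h: h, mode=mode)
    if mode == "nonstandard":
        return DenominatorFunctions(
            phi=lambda dt: 0.001 * (1.0 - math.exp(-dt)),
            psi=lambda h: 0.5 * math.sinh(h / 2.0),
            mode=mode,
        )
    if mode == "nonstandard-consistent":
        return DenominatorFunctions(
            phi=lambda dt: 1.0 - math.exp(-dt),
            psi=lambda h: 2.0 * math.sinh(h / 2.0),
            mode=mode,
        )
    raise ValueError(f"unknown denominator mode {mode!r}")


def caputo_l1_apply(
    history: np.ndarray,
    alpha: float,
    dt: float,
    den: DenominatorFunctions | None = None,
) -> np.ndarray | float:
    """L1 approximation of the Caputo derivative at the newest time level.

    ``history`` holds the nodal values at levels 0..j+1 along its first axis
    (the last entry is the level being evaluated).  Returns

        dt^(1-alpha) / (phi(dt) * Gamma(2-alpha)) *
            sum_{k=0}^{j} (u^{j+1-k} - u^{j-k}) * z_k

    which in standard mode (phi(dt) = dt) is the classical L1 operator; it is
    exact for functions linear in t and collapses to the first difference
    quotient at alpha = 1.
    """
    history = np.asarray(history, dtype=float)
    if history.shape[0] < 2:
        raise ValueError("history must hold at least two time levels")
    if den is None:
        den = make_denominators("standard")
    j = history.shape[0] - 2
    z = l1_z_weights(alpha, j)
    diffs = np.diff(history, axis=0)  # levels (u^1-u^0) .. (u^{j+1}-u^j)
    # pair z_k with the difference ending at level j+1-k
    pref = dt ** (1.0 - alpha) / (den.phi(dt) * math.gamma(2.0 - alpha))
    acc = np.tensordot(z, diffs[::-1], axes=(0, 0))
    return pref * acc


def rl_history_apply(
    history: np.ndarray,
    alpha: float,
    dt: float,
    den: DenominatorFunctions | None = None,
    convention: str = "as_printed",
) -> np.ndarray | float:
    """GL approximation of the RL part of the CPC operator at level j.

    ``history`` holds levels 0..j along its first axis.  With the default
    ``as_printed`` convention this is a GL *derivative* of order 1-alpha,
    ``phi(dt)**-(1-alpha) * sum_k W_k^(1-alpha) u^{j-k}``; with
    ``integral_consistent`` it is a GL quadrature of the RL *integral*
    I^(1-alpha), ``phi(dt)**(1-alpha) * sum_k W_k^(-(1-alpha)) u^{j-k}``.
    """
    history = np.asarray(history, dtype=float)
    if history.shape[0] < 1:
        raise ValueError("history must hold at least one time level")
    if den is None:
        den = make_denominators("standard")
    j = history.shape[0] - 1
    mu = 1.0 - alpha
    if convention == "as_printed":
        w = gl_weights(mu, j)
        pref = den.phi(dt) ** (-mu)
    elif convention == "integral_consistent":
        w = gl_weights(-mu, j)
        pref = den.phi(dt) ** mu
    else:
        raise ValueError(f"unknown RL convention {convention!r}")
    return pref * np.tensordot(w, history[::-1], axes=(0, 0))
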