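"""Self-contained test inputs: manufactured solutions and random fields.

A manufactured case prescribes a smooth steady profile v(xi) and the source
g(xi, t) that makes v an exact solution of the modified single-field equation

    CPC_t^alpha v = D v_xx - L v + g(xi, t).

For a time-constant profile the Caputo part of the CPC operator vanishes and
the RL part has a closed form, so

    g(xi, t) = K1 * v(xi) * r(t) + L * v(xi) - D * v''(xi)

with r(t) = t^(alpha-1)/Gamma(alpha) under the RL-derivative ("as_printed")
convention and r(t) = t^(1-alpha)/Gamma(2-alpha) under the integral
convention (both reduce to 0 resp. t at alpha = 1, where K1 = 0 anyway).
Feeding g to the solver with the profile as initial and boundary data closes
the loop on solver + stencils + fractional quadrature without reference to
the erfc solutions: the numerical field should stay at v up to discretization
error.

Also provides a slow, high-accuracy quadrature of the Caputo derivative and
the RL integral (independent oracles for the discrete operators) and
reproducible random bounded fields for stability stress tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .fractional import CPCSpec
from .stencils import GridSpec

__all__ = [
    "ManufacturedCase",
    "manufactured_case",
    "random_bounded_field",
    "caputo_reference",
    "rl_integral_reference",
]


@dataclass(frozen=True)
class ManufacturedCase:
    """A steady profile, its second derivative, and the matching source."""

    profile: Callable[[np.ndarray], np.ndarray]
    profile_xx: Callable[[np.ndarray], np.ndarray]
    source: Callable[[np.ndarray, float], np.ndarray]
    diffusivity: float
    drag: float
    alpha: float


def manufactured_case(
    profile: str,
    diffusivity: float,
    drag: float,
    cpc: CPCSpec,
    *,
    l: float = 5.0,
    rl_convention: str = "as_printed",
    center: float | None = None,
    width: float | None = None,
) -> ManufacturedCase:
    """Build a manufactured steady case for one field.

    ``profile`` is ``"polynomial"`` (v = xi*(l-xi), for which both stencils
    are exact) or ``"gaussian"`` (v = exp(-(xi-c)^2 / (2 w^2)), default
    c = l/2, w = l/10, for spatial-order studies).
    """
    if profile == "polynomial":
        v = lambda xi: xi * (l - xi)  # noqa: E731
        vxx = lambda xi: -2.0 * np.ones_like(np.asarray(xi, dtype=float))  # noqa: E731
    elif profile == "gaussian":
        c = l / 2.0 if center is None else center
        w = l / 10.0 if width is None else width
        v = lambda xi: np.exp(-((xi - c) ** 2) / (2.0 * w**2))  # noqa: E731
        vxx = lambda xi: v(xi) * (((xi - c) / w**2) ** 2 - 1.0 / w**2)  # noqa: E731
    else:
        raise ValueError(f"unknown profile {profile!r}")

    alpha = cpc.alpha
    if alpha == 1.0:
        rate = lambda t: 0.0  # noqa: E731  (classical: steady => zero time term)
    elif rl_convention == "as_printed":
        # the RL-derivative rate t^(alpha-1) is singular at t = 0; there is no
        # accumulated history at the initial instant, so the rate is defined
        # as 0 there (only omega-weighted explicit evaluations ever see t = 0)
        rate = lambda t: t ** (alpha - 1.0) / math.gamma(alpha) if t > 0.0 else 0.0  # noqa: E731
    elif rl_convention == "integral_consistent":
        rate = lambda t: t ** (1.0 - alpha) / math.gamma(2.0 - alpha)  # noqa: E731
    else:
        raise ValueError(f"unknown RL convention {rl_convention!r}")

    def source(xi: np.ndarray, t: float) -> np.ndarray:
        vv = v(xi)
        return cpc.K1 * vv * rate(t) + drag * vv - diffusivity * vxx(xi)

    return ManufacturedCase(
        profile=v, profile_xx=vxx, source=source,
        diffusivity=diffusivity, drag=drag, alpha=alpha,
    )


def random_bounded_field(seed: int, grid: GridSpec) -> np.ndarray:
    """Reproducible pseudo-random nodal values in [-1, 1] (length N+1)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, grid.N + 1)


def caputo_reference(
    fprime: Callable[[float], float], t: float, alpha: float, tol: float = 1e-10
) -> float:
    """Caputo derivative by adaptive quadrature with the (t-tau)^-alpha weight."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("quadrature oracle requires 0 < alpha < 1")
    val, _ = quad(fprime, 0.0, t, weight="alg", wvar=(0.0, -alpha),
                  epsabs=tol, epsrel=tol, limit=200)
    return val / math.gamma(1.0 - alpha)


def rl_integral_reference(
    f: Callable[[float], float], t: float, order: float, tol: float = 1e-10
) -> float:
    """RL fractional integral I^order by adaptive weighted quadrature."""
    if not 0.0 < order < 1.0:
        raise ValueError("quadrature oracle requires 0 < order < 1")
    val, _ = quad(f, 0.0, t, weight="alg", wvar=(0.0, order - 1.0),
                  epsabs=tol, epsrel=tol, limit=200)
    return val / math.gamma(order)
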