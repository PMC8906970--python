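"""Closed-form erfc validation solutions for the impulsively started plate.

For the classical (integer-order) model with a non-oscillating plate
(Q t = 0), the temperature and velocity fields admit exact solutions built
from the complementary error function:

    theta(xi, t) = erfc( (xi/2) * sqrt(b0/t) ),            b0 = Pr*phi4/phi5 = 1/F
    u(xi, t)     = 1/2 [ e^{-xi sqrt(a1 L)} erfc(xi sqrt(a1)/(2 sqrt t) - sqrt(L t))
                       + e^{+xi sqrt(a1 L)} erfc(xi sqrt(a1)/(2 sqrt t) + sqrt(L t)) ]
                   (+ buoyancy blocks proportional to b1 when Gr != 0),

with a0 = gamma/(1+gamma) and a1 = a0*phi1 = 1/A.  These solve

    u_t = A u_xx - L u,     theta_t = F theta_xx

with u(0,t) = theta(0,t) = 1 and decay at infinity, and serve as the
reference for every error table.  Quantitative validation is restricted to
Gr = 0 (the buoyancy amplitude b1 of the coupled case is supplied by the
caller; its default reconstruction is not residual-asserted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.special

from .params import PhysicalParams, compute_pde_coefficients, compute_phi_constants

__all__ = ["ExactSolutionParams", "erfc", "exact_temperature", "exact_velocity"]


def erfc(x):
    """Complementary error function, 1 - erf(x)."""
    return scipy.special.erfc(x)


@dataclass(frozen=True)
class ExactSolutionParams:
    """Constants of the closed-form solutions.

    By construction a1 = 1/A and b0 = 1/F when built from the same physical
    parameter set (asserted in :meth:`from_physical`).
    """

    a0: float
    a1: float
    b0: float
    L: float
    b1: float = 0.0

    @classmethod
    def from_physical(
        cls,
        params: PhysicalParams,
        *,
        drag_form: str = "darcy",
        b1: float | None = None,
    ) -> "ExactSolutionParams":
        nf = compute_phi_constants(params)
        coef = compute_pde_coefficients(params, nf, drag_form=drag_form)
        a0 = params.gamma / (1.0 + params.gamma)
        a1 = a0 * nf.phi1
        b0 = params.Pr * nf.phi4 / nf.phi5
        assert math.isclose(a1 * coef.A, 1.0, rel_tol=1e-12)
        assert math.isclose(b0 * coef.F, 1.0, rel_tol=1e-12)
        if b1 is None:
            if params.Gr == 0.0:
                b1 = 0.0
            elif math.isclose(b0, 1.0):
                raise ValueError("default b1 reconstruction is singular at b0 = 1; supply b1")
            else:
                # literal reading of the printed buoyancy amplitude; overridable
                b1 = a1 * params.Gr * nf.phi1 * nf.phi2 / (b0 - 1.0)
        return cls(a0=a0, a1=a1, b0=b0, L=coef.L, b1=b1)


def exact_temperature(xi, t, p: ExactSolutionParams):
    """theta(xi, t) = erfc((xi/2) sqrt(b0/t)); requires t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("exact solutions are defined for t > 0 only")
    xi = np.asarray(xi, dtype=float)
    return erfc(0.5 * xi * np.sqrt(p.b0 / t))


def exact_velocity(xi, t, p: ExactSolutionParams):
    """Velocity of the impulsively started plate; requires t > 0.

    For b1 = 0 (the Gr = 0 regime, where all quantitative validation lives)
    only the drag-diffusion bracket survives; at xi = 0 the bracket collapses
    to 1 via erfc(-x) + erfc(x) = 2.  The b1 != 0 branch adds the printed
    buoyancy blocks and is exposed for qualitative use only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("exact solutions are defined for t > 0 only")
    xi = np.asarray(xi, dtype=float)
    a1, L, b0, b1 = p.a1, p.L, p.b0, p.b1

    sqrt_t = np.sqrt(t)
    arg = 0.5 * xi * math.sqrt(a1) / sqrt_t
    decay = math.sqrt(a1 * L) * xi if L > 0.0 else np.zeros_like(xi * t)
    root_Lt = np.sqrt(L * t)
    em = np.exp(-decay)
    ep = np.exp(decay)
    u = 0.5 * (em * erfc(arg - root_Lt) + ep * erfc(arg + root_Lt))

    if b1 != 0.0:
        if L <= 0.0:
            raise ValueError("the buoyancy blocks require L > 0")
        shift = 0.25 * xi * math.sqrt(a1 / L)
        u = u + b1 * (
            em * erfc(arg - root_Lt) * (0.5 * t - shift)
            + ep * erfc(arg + root_Lt) * (0.5 * t + shift)
        )
        u = u - b1 * (
            (t + 0.5 * b0 * xi**2) * erfc(0.5 * xi * np.sqrt(b0 / t))
            - xi * np.sqrt(b0 * t / math.pi) * np.exp(-b0 * xi**2 / (4.0 * t))
        )
    return u
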