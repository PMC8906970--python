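"""Von Neumann stability analysis of the weighted-average schemes.

Substituting a Fourier mode X_i^j = chi^j e^(I q i h) into the one-field
scheme and writing eta = chi^{j+1}/chi^j gives the amplification factor

          2 Z1 cos(2 q h) + 2 Z2 cos(q h) + Z3 + f H_z(chi) - s H_W(chi)
    eta = -------------------------------------------------------------
          2 A1 cos(2 q h) + 2 A2 cos(q h) + A3 + f H_z(chi)

with H_z = sum_{k>=1} z_k chi^-k (Caputo history), H_W = sum_{k>=0} W_k chi^-k
(RL history), f and s the Caputo/RL prefactors, and the A/Z constants the
Fourier symbols of the implicit and explicit stencil blocks.  The mode is
stable when |eta| <= 1 over the whole phase range.

The coupled system is lower-triangular in (theta, u) — the buoyancy term is
explicit and bounded — so stability is assessed per scalar field (Y2-entry -F
with no drag for temperature, -A with drag L for velocity).

The chi-dependence of the history sums is not constant in a genuine
multi-level scheme; two treatments are offered: ``unit_modulus`` (default)
freezes |chi| = 1 (a non-decaying-history bound) and ``fixed_point`` iterates
chi <- eta to self-consistency.

Note: the constants below are extracted to agree exactly with the Fourier
symbol of the assembled step matrices (verified by tests); the commonly
printed closed-form table for this scheme carries inconsistent signs on the
stencil blocks and omits the dt^(1-alpha) factor of f, so the assembled
scheme is taken as ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fractional import CPCSpec, gl_weights, l1_z_weights
from .params import PDECoefficients
from .solver import SchemeSpec
from .stencils import GridSpec

__all__ = [
    "StabilityCoefficients",
    "StabilityReport",
    "stability_coefficients",
    "amplification_factor",
    "stability_scan",
]

STABILITY_TOL = 1e-9


@dataclass(frozen=True)
class StabilityCoefficients:
    """Scalar-field symbol constants of one scheme configuration.

    A1..A5 multiply the unknown level (A4 = A2 and A5 = A1 by stencil
    symmetry), Z1..Z5 the old level; s and f are the RL and Caputo history
    prefactors and z/W the weight tables used in the history sums.
    """

    A1: float
    A2: float
    A3: float
    Z1: float
    Z2: float
    Z3: float
    s: float
    f: float
    z_weights: np.ndarray
    W_weights: np.ndarray
    h: float
    field: str

    @property
    def A4(self) -> float:
        return self.A2

    @property
    def A5(self) -> float:
        return self.A1

    @property
    def Z4(self) -> float:
        return self.Z2

    @property
    def Z5(self) -> float:
        return self.Z1


@dataclass(frozen=True)
class StabilityReport:
    """Result of a wavenumber scan: per-mode |eta| and the verdict."""

    q_grid: np.ndarray
    eta: np.ndarray
    max_eta: float
    stable: bool


def stability_coefficients(
    coef: PDECoefficients,
    cpc: CPCSpec,
    scheme: SchemeSpec,
    grid: GridSpec,
    field: str = "velocity",
) -> StabilityCoefficients:
    """Symbol constants for one field ('velocity': D=A, drag L; 'temperature': D=F)."""
    if field == "velocity":
        D, drag = coef.A, coef.L
    elif field == "temperature":
        D, drag = coef.F, 0.0
    else:
        raise ValueError(f"unknown field {field!r}")

    den = scheme.denominators
    dt, h = grid.dt, grid.h
    phi_dt = den.phi(dt)
    psi2 = den.psi(h) ** 2
    om = scheme.omega
    alpha = cpc.alpha

    f = cpc.K0 * dt ** (1.0 - alpha) / (phi_dt * math.gamma(2.0 - alpha))
    mu = 1.0 - alpha
    m_max = max(grid.Z + 1, 2048)  # long enough for any reasonable scan history
    if scheme.rl_convention == "as_printed":
        s = cpc.K1 * phi_dt ** (-mu)
        W = gl_weights(mu, m_max)
    else:
        s = cpc.K1 * phi_dt**mu
        W = gl_weights(-mu, m_max)
    z = l1_z_weights(alpha, m_max)

    if scheme.stencil_order == 4:
        A1 = D * (1.0 - om) / (12.0 * psi2)
        A2 = -4.0 * D * (1.0 - om) / (3.0 * psi2)
        A3 = f + 5.0 * D * (1.0 - om) / (2.0 * psi2)
        Z1 = -D * om / (12.0 * psi2)
        Z2 = 4.0 * D * om / (3.0 * psi2)
        Z3 = f - 5.0 * D * om / (2.0 * psi2) - drag
    else:
        A1 = 0.0
        A2 = -D * (1.0 - om) / psi2
        A3 = f + 2.0 * D * (1.0 - om) / psi2
        Z1 = 0.0
        Z2 = D * om / psi2
        Z3 = f - 2.0 * D * om / psi2 - drag

    return StabilityCoefficients(
        A1=A1, A2=A2, A3=A3, Z1=Z1, Z2=Z2, Z3=Z3,
        s=s, f=f, z_weights=z, W_weights=W, h=h, field=field,
    )


def _eta_given_chi(theta: float, sc: StabilityCoefficients, m: int, chi: complex) -> complex:
    k = np.arange(1, m)
    chi_pow = chi ** (-k.astype(float))
    H_z = np.sum(sc.z_weights[1:m] * chi_pow) if m > 1 else 0.0
    H_W = sc.W_weights[0] + (np.sum(sc.W_weights[1:m] * chi_pow) if m > 1 else 0.0)
    num = 2.0 * sc.Z1 * math.cos(2 * theta) + 2.0 * sc.Z2 * math.cos(theta) + sc.Z3
    den = 2.0 * sc.A1 * math.cos(2 * theta) + 2.0 * sc.A2 * math.cos(theta) + sc.A3
    num = num + sc.f * H_z - sc.s * H_W
    den = den + sc.f * H_z
    return num / den


def amplification_factor(
    q: float,
    sc: StabilityCoefficients,
    m: int = 200,
    history_model: str = "unit_modulus",
) -> complex:
    """Amplification factor eta at wavenumber q (phase theta = q*h).

    ``m`` is the history length entering the nonlocal sums.  Under
    ``unit_modulus`` the history ratio chi is frozen at modulus 1; under
    ``fixed_point`` chi is iterated to chi = eta (tolerance 1e-10, at most
    200 iterations, seeded at 1), falling back to the unit-modulus bound with
    a warning if the iteration does not converge.
    """
    if m < 1:
        raise ValueError("history length m must be >= 1")
    theta = q * sc.h
    if history_model == "unit_modulus":
        return _eta_given_chi(theta, sc, m, 1.0 + 0.0j)
    if history_model != "fixed_point":
        raise ValueError(f"unknown history model {history_model!r}")
    chi = 1.0 + 0.0j
    eta_prev = None
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(200):
            eta = _eta_given_chi(theta, sc, m, chi)
            if not np.isfinite(eta.real) or not np.isfinite(eta.imag):
                break
            if eta_prev is not None and abs(eta - eta_prev) <= 1e-10:
                return eta
            eta_prev = eta
            # chi^-k diverges for |chi| < 1; clamp the modulus from below so
            # the history sums stay finite while iterating
            chi = eta if abs(eta) > 1e-2 else eta / abs(eta) * 1e-2 if eta != 0 else 1.0 + 0.0j
    warnings.warn(
        f"fixed-point history iteration did not converge at q={q}; "
        "falling back to the unit-modulus bound",
        RuntimeWarning,
        stacklevel=2,
    )
    return _eta_given_chi(theta, sc, m, 1.0 + 0.0j)


def stability_scan(
    sc: StabilityCoefficients,
    q_count: int = 256,
    m: int = 200,
    history_model: str = "unit_modulus",
) -> StabilityReport:
    """Scan |eta| over phases q*h in (0, pi] and report the verdict.

    In a multi-level scheme the history sums at step j hold only j terms, so
    a mode must be non-amplifying at *every* history length, not just the
    final one: the Caputo sum grows like j^(1-alpha) and provides much less
    damping in the early steps (a nominally stable long-history factor can
    hide violent transient growth).  The scan therefore takes, per mode, the
    maximum of |eta| over a geometric ladder of history lengths 1..m; the
    reported ``eta`` array is that per-mode maximum.
    """
    if q_count < 16:
        raise ValueError("q_count must be >= 16")
    thetas = np.linspace(0.0, math.pi, q_count + 1)[1:]
    qs = thetas / sc.h
    ladder = np.unique(np.geomspace(1, max(m, 1), num=16).round().astype(int))
    eta = np.zeros(q_count)
    for m_val in ladder:
        cur = np.array([abs(amplification_factor(q, sc, int(m_val), history_model)) for q in qs])
        eta = np.maximum(eta, cur)
    max_eta = float(eta.max())
    return StabilityReport(q_grid=qs, eta=eta, max_eta=max_eta, stable=max_eta <= 1.0 + STABILITY_TOL)
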