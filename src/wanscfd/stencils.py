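"""Spatial second-derivative stencils with (non)standard denominators.

Two centered stencils are provided for u_xx on a uniform grid:

* 3-point: (1, -2, 1) / psi(h)^2            — second order (standard mode);
* 5-point compact: (-1/12, 4/3, -5/2, 4/3, -1/12) / psi(h)^2 — fourth order.

``psi(h)`` is the Mickens space denominator; in standard mode psi(h) = h.
Near the boundary the 5-point stencil needs a closure; the default
``fallback2`` substitutes the 3-point stencil at the first and last interior
nodes (keeps the interior operator pentadiagonal), while ``ghost`` extends the
field by one ghost node using the odd reflection u(-h) = 2 u(0) - u(h), which
is exact for fields linear through the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fractional import DenominatorFunctions, make_denominators

__all__ = [
    "GridSpec",
    "StencilWeights",
    "second_order_stencil",
    "fourth_order_compact_stencil",
    "apply_stencil",
    "interior_operator",
]

_CLOSURES = ("fallback2", "ghost")


@dataclass(frozen=True)
class GridSpec:
    """Uniform space-time grid: nodes xi_i = i*h (h = l/N), levels t_j = j*dt."""

    l: float
    N: int
    T: float
    Z: int

    def __post_init__(self) -> None:
        if not self.l > 0.0:
            raise ValueError("domain length l must be > 0")
        if self.N < 4:
            raise ValueError("need at least N = 4 space intervals")
        if not self.T > 0.0:
            raise ValueError("final time T must be > 0")
        if self.Z < 0:
            raise ValueError("number of time steps Z must be >= 0")

    @property
    def h(self) -> float:
        return self.l / self.N

    @property
    def dt(self) -> float:
        return self.T / self.Z if self.Z > 0 else self.T

    @property
    def xi(self) -> np.ndarray:
        return np.linspace(0.0, self.l, self.N + 1)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.Z + 1)


@dataclass(frozen=True)
class StencilWeights:
    """Offsets and coefficients of one second-derivative stencil.

    Coefficients already include the 1/psi(h)^2 factor; they sum to zero and
    are symmetric about offset 0.
    """

    offsets: tuple[int, ...]
    coefficients: np.ndarray
    denominator: float  # psi(h)^2 actually used


def second_order_stencil(h: float, den: DenominatorFunctions | None = None) -> StencilWeights:
    """Classical 3-point stencil with the (non)standard space denominator."""
    if not h > 0.0:
        raise ValueError("step h must be > 0")
    if den is None:
        den = make_denominators("standard")
    psi2 = den.psi(h) ** 2
    return StencilWeights(
        offsets=(-1, 0, 1),
        coefficients=np.array([1.0, -2.0, 1.0]) / psi2,
        denominator=psi2,
    )


def fourth_order_compact_stencil(
    h: float, den: DenominatorFunctions | None = None
) -> StencilWeights:
    """5-point fourth-order compact stencil; exact for quartics in standard mode."""
    if not h > 0.0:
        raise ValueError("step h must be > 0")
    if den is None:
        den = make_denominators("standard")
    psi2 = den.psi(h) ** 2
    return StencilWeights(
        offsets=(-2, -1, 0, 1, 2),
        coefficients=np.array([-1.0 / 12.0, 4.0 / 3.0, -5.0 / 2.0, 4.0 / 3.0, -1.0 / 12.0]) / psi2,
        denominator=psi2,
    )


def apply_stencil(
    field: np.ndarray, w: StencilWeights, closure: str = "fallback2"
) -> np.ndarray:
    """Second-derivative approximation at the interior nodes i = 1..N-1.

    ``field`` holds the N+1 nodal values at one time level.  For the 5-point
    stencil the rows at i = 1 and i = N-1 are closed per ``closure``.
    """
    field = np.asarray(field, dtype=float)
    n_nodes = field.shape[0]
    if closure not in _CLOSURES:
        raise ValueError(f"unknown boundary closure {closure!r}")
    if len(w.offsets) == 3:
        return (
            w.coefficients[0] * field[:-2]
            + w.coefficients[1] * field[1:-1]
            + w.coefficients[2] * field[2:]
        )
    if n_nodes < 5:
        raise ValueError("the compact stencil needs at least N = 4 intervals")
    out = np.empty(n_nodes - 2)
    c = w.coefficients
    out[1:-1] = (
        c[0] * field[:-4]
        + c[1] * field[1:-3]
        + c[2] * field[2:-2]
        + c[3] * field[3:-1]
        + c[4] * field[4:]
    )
    if closure == "fallback2":
        three = np.array([1.0, -2.0, 1.0]) / w.denominator
        out[0] = three @ field[0:3]
        out[-1] = three @ field[-3:]
    else:  # ghost: odd reflection through the boundary value
        ghost_lo = 2.0 * field[0] - field[1]
        ghost_hi = 2.0 * field[-1] - field[-2]
        out[0] = c @ np.concatenate(([ghost_lo], field[0:4]))
        out[-1] = c @ np.concatenate((field[-4:], [ghost_hi]))
    return out


def interior_operator(
    N: int, w: StencilWeights, closure: str = "fallback2"
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Matrix form of :func:`apply_stencil` on the interior unknowns.

    Returns ``(S, b_lo, b_hi)`` with S an (N-1)x(N-1) sparse matrix acting on
    the interior values and b_lo, b_hi the coefficient vectors multiplying the
    two boundary values, so that for a full nodal field u:

        apply_stencil(u, w, closure) == S @ u[1:-1] + b_lo*u[0] + b_hi*u[-1]
    """
    if closure not in _CLOSURES:
        raise ValueError(f"unknown boundary closure {closure!r}")
    n = N - 1
    S = sp.lil_matrix((n, n))
    b_lo = np.zeros(n)
    b_hi = np.zeros(n)
    c = w.coefficients
    offs = w.offsets
    three = np.array([1.0, -2.0, 1.0]) / w.denominator

    def add(row: int, node: int, coeff: float) -> None:
        if node == 0:
            b_lo[row] += coeff
        elif node == N:
            b_hi[row] += coeff
        elif 0 < node < N:
            S[row, node - 1] += coeff

    for row in range(n):
        i = row + 1  # node index
        if len(offs) == 3 or 2 <= i <= N - 2:
            for o, cc in zip(offs, c):
                add(row, i + o, cc)
        elif closure == "fallback2":
            for o, cc in zip((-1, 0, 1), three):
                add(row, i + o, cc)
        else:  # ghost closure at i = 1 or i = N-1
            for o, cc in zip(offs, c):
                node = i + o
                if node < 0:  # ghost below: u(-h) = 2u(0) - u(h)
                    add(row, 0, 2.0 * cc)
                    add(row, 1, -cc)
                elif node > N:  # ghost above
                    add(row, N, 2.0 * cc)
                    add(row, N - 1, -cc)
                else:
                    add(row, node, cc)
    return S.tocsr(), b_lo, b_hi
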