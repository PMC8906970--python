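"""Physical parameters and constant coefficients of the nanofluid model.

The model describes unsteady MHD free-convection flow of human blood carrying
carbon nanotubes (CNTs) past a vertical plate through a porous medium.  All
quantities here are dimensionless: the user supplies the solid volume fraction
``phi``, the Casson parameter ``gamma``, the magnetic parameter ``M``, the
permeability parameter ``K``, the Prandtl and Grashof numbers, and the
nanoparticle/base-fluid material property ratios.  From these the five mixture
constants ``phi1..phi5`` and the four PDE constants ``A, C, F, L`` are built:

    velocity:     CPC_t^alpha u = A u_xx - L u + C theta
    temperature:  CPC_t^alpha theta = F theta_xx

with A = (1/phi1)(1 + 1/gamma), C = Gr*phi3, F = phi5/(Pr*phi4) and
L = M*phi2 + phi1/K.

Mixture rules: Brinkman viscosity (1-phi)^-2.5 absorbed into phi1, the Maxwell
electrical-conductivity rule for phi2, linear volume-weighted mixtures for
phi3 and phi4, and the Xue logarithmic conductivity model (appropriate for
high-aspect-ratio CNTs) for phi5 = k_nf/k_f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "MaterialRatios",
    "PhysicalParams",
    "NanofluidCoefficients",
    "PDECoefficients",
    "NEUTRAL_RATIOS",
    "compute_phi_constants",
    "compute_pde_coefficients",
    "load_preset",
    "available_presets",
]

# relative tolerance below which k_c and k_f are treated as equal (the Xue
# formula is 0/0 there; its limit is exactly 1 in the matched-conductivity case)
_KC_KF_RTOL = 1e-12


@dataclass(frozen=True)
class MaterialRatios:
    """Nanoparticle-to-base-fluid material property ratios.

    Attributes
    ----------
    rho_ratio : density ratio rho_c / rho_f.
    sigma_ratio : electrical conductivity ratio sigma_c / sigma_f.
    rhobeta_ratio : thermal-expansion product ratio (rho*beta)_c / (rho*beta)_f.
    rhocp_ratio : heat-capacitance ratio (rho*Cp)_c / (rho*Cp)_f.
    k_c, k_f : nanoparticle and base-fluid thermal conductivities (W/m/K);
        only their combination enters, but both are kept because the Xue
        model is not a function of the ratio alone.
    """

    rho_ratio: float
    sigma_ratio: float
    rhobeta_ratio: float
    rhocp_ratio: float
    k_c: float
    k_f: float

    def __post_init__(self) -> None:
        for name in ("rho_ratio", "sigma_ratio", "rhobeta_ratio", "rhocp_ratio", "k_c", "k_f"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"MaterialRatios.{name} must be finite and > 0, got {value!r}")


NEUTRAL_RATIOS = MaterialRatios(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensionless physical parameters of one flow configuration."""

    phi: float
    gamma: float
    M_mag: float
    K_perm: float
    Pr: float
    Gr: float
    Q_freq: float = 0.0
    ratios: MaterialRatios = field(default=NEUTRAL_RATIOS)

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"solid volume fraction must satisfy 0 <= phi < 1, got {self.phi}")
        if not self.gamma > 0.0:
            raise ValueError(f"Casson parameter gamma must be > 0, got {self.gamma}")
        if self.M_mag < 0.0:
            raise ValueError(f"magnetic parameter M must be >= 0, got {self.M_mag}")
        if not self.K_perm > 0.0:
            raise ValueError(f"permeability parameter K must be > 0, got {self.K_perm}")
        if not self.Pr > 0.0:
            raise ValueError(f"Prandtl number must be > 0, got {self.Pr}")
        if self.Q_freq < 0.0:
            raise ValueError(f"oscillation frequency Q must be >= 0, got {self.Q_freq}")


@dataclass(frozen=True)
class NanofluidCoefficients:
    """The five mixture constants; ``knf_over_kf`` is an alias for phi5."""

    phi1: float
    phi2: float
    phi3: float
    phi4: float
    phi5: float

    @property
    def knf_over_kf(self) -> float:
        return self.phi5


@dataclass(frozen=True)
class PDECoefficients:
    """Constants of the dimensionless coupled equations.

    A: velocity diffusivity, C: buoyancy coupling, F: thermal diffusivity,
    L: drag (magnetic + Darcy).
    """

    A: float
    C: float
    F: float
    L: float


def _xue_conductivity_ratio(phi: float, k_c: float, k_f: float) -> float:
    """k_nf/k_f via the Xue logarithmic model for CNT suspensions."""
    if abs(k_c - k_f) <= _KC_KF_RTOL * max(abs(k_c), abs(k_f)):
        return 1.0
    log_term = math.log((k_c + k_f) / (2.0 * k_f))
    num = 1.0 - phi + 2.0 * phi * (k_c / (k_c - k_f)) * log_term
    den = 1.0 - phi + 2.0 * phi * (k_f / (k_c - k_f)) * log_term
    return num / den


def compute_phi_constants(params: PhysicalParams) -> NanofluidCoefficients:
    """Build the five mixture constants phi1..phi5 from one parameter set.

    All five equal 1 in the pure-fluid limit phi = 0, for any material ratios.
    """
    phi = params.phi
    r = params.ratios

    phi1 = (1.0 - phi) ** 2.5 * ((1.0 - phi) + phi * r.rho_ratio)
    # Maxwell mixture rule for the electrical conductivity
    sr = r.sigma_ratio
    phi2 = 1.0 + 3.0 * phi * (sr - 1.0) / ((sr + 2.0) - phi * (sr - 1.0))
    phi3 = ((1.0 - phi) + phi * r.rhobeta_ratio) / ((1.0 - phi) + phi * r.rho_ratio)
    phi4 = (1.0 - phi) + phi * r.rhocp_ratio
    phi5 = _xue_conductivity_ratio(phi, r.k_c, r.k_f)

    coeffs = NanofluidCoefficients(phi1, phi2, phi3, phi4, phi5)
    for name in ("phi1", "phi2", "phi3", "phi4", "phi5"):
        value = getattr(coeffs, name)
        if not (value > 0.0 and math.isfinite(value)):
            raise ValueError(f"{name} = {value!r} is not finite and positive; check parameters")
    return coeffs


def compute_pde_coefficients(
    params: PhysicalParams,
    nf: NanofluidCoefficients | None = None,
    *,
    drag_form: str = "darcy",
) -> PDECoefficients:
    """Build A, C, F, L from physical parameters and mixture constants.

    Parameters
    ----------
    drag_form : ``"darcy"`` (default) uses L = M*phi2 + phi1/K so that the
        porous drag decays with increasing permeability; ``"product"`` uses
        the literal product reading L = M*phi2 + phi1*K.
    """
    if nf is None:
        nf = compute_phi_constants(params)
    if params.gamma == 0.0:
        raise ValueError("gamma must be nonzero")
    if params.K_perm == 0.0:
        raise ValueError("K must be nonzero")
    if drag_form not in ("darcy", "product"):
        raise ValueError(f"unknown drag_form {drag_form!r}")

    A = (1.0 / nf.phi1) * (1.0 + 1.0 / params.gamma)
    C = params.Gr * nf.phi3
    F = nf.phi5 / (params.Pr * nf.phi4)
    if drag_form == "darcy":
        L = params.M_mag * nf.phi2 + nf.phi1 / params.K_perm
    else:
        L = params.M_mag * nf.phi2 + nf.phi1 * params.K_perm
    return PDECoefficients(A=A, C=C, F=F, L=L)


def _load_preset_table() -> dict:
    text = resources.files("wanscfd").joinpath("data/material_presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    """Names of the shipped material-ratio presets."""
    return sorted(_load_preset_table())


def load_preset(name: str) -> MaterialRatios:
    """Load a named nanoparticle/base-fluid preset shipped with the package."""
    table = _load_preset_table()
    try:
        entry = table[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(table)}") from None
    return MaterialRatios(
        rho_ratio=entry["rho_c"] / entry["rho_f"],
        sigma_ratio=entry["sigma_c"] / entry["sigma_f"],
        rhobeta_ratio=(entry["rho_c"] * entry["beta_c"]) / (entry["rho_f"] * entry["beta_f"]),
        rhocp_ratio=(entry["rho_c"] * entry["cp_c"]) / (entry["rho_f"] * entry["cp_f"]),
        k_c=entry["k_c"],
        k_f=entry["k_f"],
    )
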