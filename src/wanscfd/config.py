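"""TOML run-configuration parsing.

A run config has up to four tables::

    [physical]
    phi = 0.01
    gamma = 1.0
    M = 0.5
    K = 1.0
    Pr = 25.0
    Gr = 0.0
    Q = 0.0
    ratios = "SWCNT-blood"      # preset name, or an inline table of ratios

    [fractional]
    alpha = 0.8
    S = "auto"                  # kernel scale; "auto" = final time T
    rl_convention = "as_printed"

    [grid]
    l = 5.0
    N = 50
    T = 0.9
    Z = 90

    [scheme]
    omega = 0.0
    stencil_order = 4
    denominator_mode = "nonstandard"
    boundary_closure = "fallback2"
    drag_form = "darcy"

Every key is echoed back by :func:`echo` for reproducible run logs.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict
from pathlib import Path
from typing import Any

from .fractional import cpc_kernels, make_denominators
from .params import MaterialRatios, PhysicalParams, load_preset
from .solver import SchemeSpec
from .stencils import GridSpec

__all__ = ["RunConfig", "load_config", "echo"]


class RunConfig:
    """Parsed configuration bundle for one run."""

    def __init__(self, raw: dict[str, Any]) -> None:
        self.raw = raw
        phys = dict(raw.get("physical", {}))
        ratios = phys.pop("ratios", "neutral")
        if isinstance(ratios, str):
            ratios = load_preset(ratios)
        else:
            ratios = MaterialRatios(**ratios)
        self.params = PhysicalParams(
            phi=phys.get("phi", 0.0),
            gamma=phys.get("gamma", 1.0),
            M_mag=phys.get("M", 0.0),
            K_perm=phys.get("K", 1.0),
            Pr=phys.get("Pr", 1.0),
            Gr=phys.get("Gr", 0.0),
            Q_freq=phys.get("Q", 0.0),
            ratios=ratios,
        )
        g = raw.get("grid", {})
        self.grid = GridSpec(
            l=g.get("l", 5.0), N=g.get("N", 50), T=g.get("T", 1.0), Z=g.get("Z", 90)
        )
        frac = raw.get("fractional", {})
        self.alpha = frac.get("alpha", 1.0)
        S = frac.get("S", "auto")
        self.S = self.grid.T if S == "auto" else float(S)
        self.cpc = cpc_kernels(self.alpha, self.S)
        sch = raw.get("scheme", {})
        self.drag_form = sch.get("drag_form", "darcy")
        self.scheme = SchemeSpec(
            omega=sch.get("omega", 0.0),
            stencil_order=sch.get("stencil_order", 4),
            denominators=make_denominators(sch.get("denominator_mode", "standard")),
            rl_convention=frac.get("rl_convention", "as_printed"),
            boundary_closure=sch.get("boundary_closure", "fallback2"),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(raw)


def echo(cfg: RunConfig) -> dict[str, Any]:
    """Flat, serializable echo of every effective setting (for run logs)."""
    return {
        "physical": {**asdict(cfg.params)},
        "grid": asdict(cfg.grid),
        "fractional": {
            "alpha": cfg.alpha,
            "S": cfg.S,
            "K0": cfg.cpc.K0,
            "K1": cfg.cpc.K1,
            "rl_convention": cfg.scheme.rl_convention,
        },
        "scheme": {
            "omega": cfg.scheme.omega,
            "stencil_order": cfg.scheme.stencil_order,
            "denominator_mode": cfg.scheme.denominators.mode,
            "boundary_closure": cfg.scheme.boundary_closure,
            "drag_form": cfg.drag_form,
        },
    }
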