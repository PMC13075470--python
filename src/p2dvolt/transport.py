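"""Finite-volume spatial operators for the two coupled diffusion problems.

Both domains use node-centred control volumes (half cells at the
boundaries), which makes the discrete scheme conservative: the flux leaving
the first electrolyte cell is exactly the flux entering the porous layer.

Electrolyte (x): dC/dt = D d2C/dx2, Dirichlet C = C_bulk at x = L_e, a
prescribed consumption flux at x = 0 (no volumetric reaction in the bulk).

Porous layer (r): eps dC/dt = D_eff d2C/dr2 - R_vol, no-flux at the
impermeable substrate r = 0, Dirichlet C = (interface value) at r = delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import volumetric_rate
from .params import Grid1D, ModelParameters

__all__ = ["CoupledRHS", "electrolyte_rhs", "porous_rhs", "interface_flux"]


@dataclass
class CoupledRHS:
    """Per-node time derivatives of both domains plus the shared flux."""

    dC_e_dt: np.ndarray       # mol m^-3 s^-1 on the x-grid
    dC_s_dt: np.ndarray       # mol m^-3 s^-1 on the r-grid
    interface_flux: float     # mol m^-2 s^-1 into the porous layer


def _diffusive_face_flux(C: np.ndarray, D: float, h: np.ndarray) -> np.ndarray:
    """Flux D*dC/dx at every interior face, positive toward increasing x."""
    return D * np.diff(C) / h


def electrolyte_rhs(C_e: np.ndarray, interface_flux: float,
                    params: ModelParameters, x_grid: Grid1D) -> np.ndarray:
    """Electrolyte Fickian rates with a consumption flux at x = 0.

    ``interface_flux`` (mol m^-2 s^-1, positive = analyte leaving the
    electrolyte into the layer/surface) is removed from the surface cell.
    The bulk node is Dirichlet (rate 0); the caller holds it at C_bulk.
    """
    C_e = np.asarray(C_e, dtype=float)
    if C_e.shape != (x_grid.n_nodes,):
        raise ValueError("C_e length does not match the x-grid")
    face = _diffusive_face_flux(C_e, params.D_mtz, x_grid.spacing)
    vol = x_grid.cell_volumes()
    dC = np.empty_like(C_e)
    dC[0] = (face[0] - interface_flux) / vol[0]
    dC[1:-1] = np.diff(face) / vol[1:-1]
    dC[-1] = 0.0  # Dirichlet bulk node
    return dC


def porous_rhs(C_s: np.ndarray, theta: np.ndarray, boundary_value: float,
               params: ModelParameters, r_grid: Grid1D) -> np.ndarray:
    """Porous-layer rates: eps-weighted accumulation, reaction sink.

    No-flux at r = 0; the outer node is slaved to ``boundary_value``
    (concentration continuity with the electrolyte surface), so its own
    rate is reported as 0.
    """
    C_s = np.asarray(C_s, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if C_s.shape != (r_grid.n_nodes,) or theta.shape != (r_grid.n_nodes,):
        raise ValueError("C_s/theta length does not match the r-grid")
    if boundary_value < 0:
        raise ValueError("boundary_value must be non-negative")
    work = C_s.copy()
    work[-1] = boundary_value
    face = _diffusive_face_flux(work, params.D_eff, r_grid.spacing)
    vol = r_grid.cell_volumes()
    rxn = volumetric_rate(np.clip(work, 0.0, None), np.clip(theta, 0.0, 1.0), params)
    dC = np.empty_like(work)
    dC[0] = (face[0] - 0.0) / vol[0] - rxn[0]          # no-flux substrate
    dC[1:-1] = np.diff(face) / vol[1:-1] - rxn[1:-1]
    dC[-1] = 0.0                                        # Dirichlet interface node
    return dC / params.porosity


def interface_flux(C_e: np.ndarray, C_s: np.ndarray, params: ModelParameters,
                   grids: tuple[Grid1D, Grid1D],
                   coupling_tol: float = 1e-6) -> float:
    """One-sided discrete flux D_eff * dC_s/dr at r = delta, mol m^-2 s^-1.

    Positive values carry analyte from the electrolyte into the layer.  Used
    as the sink of :func:`electrolyte_rhs` so the coupled system conserves
    mass.  Raises if interface concentration continuity is violated beyond
    ``coupling_tol`` (relative), which signals solver misconfiguration.
    """
    x_grid, r_grid = grids
    C_e = np.asarray(C_e, dtype=float)
    C_s = np.asarray(C_s, dtype=float)
    scale = max(abs(C_e[0]), abs(C_s[-1]), params.C_bulk)
    if abs(C_s[-1] - C_e[0]) > coupling_tol * scale:
        raise RuntimeError(
            f"interface continuity violated: C_s(delta)={C_s[-1]!r} vs "
            f"C_e(0)={C_e[0]!r}")
    h_last = r_grid.spacing[-1]
    return float(params.D_eff * (C_s[-1] - C_s[-2]) / h_last)
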