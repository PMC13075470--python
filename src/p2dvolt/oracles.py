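"""Independent closed-form references for verifying the numerical core.

None of these share discretization code with the solver: they are direct
evaluations of classical electroanalytical results (Cottrell step current,
slab Thiele effectiveness, irreversible Randles-Sevcik peak) plus a
grid-refinement reference run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "OracleReport",
    "cottrell_current",
    "thiele_effectiveness",
    "thiele_profile",
    "randles_sevcik_irreversible_peak",
    "fine_grid_reference",
]


@dataclass
class OracleReport:
    """Outcome of one oracle comparison."""

    name: str
    parameter_point: dict
    reference: float
    computed: float
    tolerance: float

    @property
    def relative_error(self) -> float:
        scale = max(abs(self.reference), 1e-300)
        return abs(self.computed - self.reference) / scale

    @property
    def passed(self) -> bool:
        return self.relative_error <= self.tolerance

    def to_dict(self) -> dict:
        return {"name": self.name, "parameter_point": self.parameter_point,
                "reference": self.reference, "computed": self.computed,
                "relative_error": self.relative_error,
                "tolerance": self.tolerance, "passed": self.passed}


def cottrell_current(t, params: ModelParameters):
    """Diffusion-limited step current magnitude n F C sqrt(D/(pi t)), A m^-2."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    j = (params.n_electrons * params.F * params.C_bulk
         * np.sqrt(params.D_mtz / (np.pi * t)))
    return j if j.ndim else float(j)


def thiele_effectiveness(phi):
    """Slab effectiveness factor tanh(phi)/phi (1 at phi = 0)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative")
    with np.errstate(invalid="ignore"):
        eta = np.where(phi == 0, 1.0, np.tanh(phi) / np.where(phi == 0, 1.0, phi))
    return eta if eta.ndim else float(eta)


def thiele_profile(r, delta: float, phi: float, C_boundary: float):
    """Steady slab reaction-diffusion profile C(r) = C_b cosh(phi r/delta)/cosh(phi).

    No-flux face at r = 0, Dirichlet C_boundary at r = delta, first-order
    volumetric consumption with Thiele modulus phi.
    """
    r = np.asarray(r, dtype=float)
    return C_boundary * np.cosh(phi * r / delta) / np.cosh(phi)


def randles_sevcik_irreversible_peak(params: ModelParameters,
                                     scan_rate: float) -> float:
    """Irreversible linear-sweep peak current magnitude, A m^-2.

    |j_p| = 0.4958 n F C sqrt(alpha F v D / (R T)), with alpha of the
    single-electron rate-determining step and n the overall electron count.
    """
    if scan_rate <= 0:
        raise ValueError("scan_rate must be positive")
    p = params
    return (0.4958 * p.n_electrons * p.F * p.C_bulk
            * np.sqrt(p.alpha * p.F * scan_rate * p.D_mtz / (p.R_gas * p.T)))


def fine_grid_reference(params: ModelParameters, program=None,
                        nx: int = 200, nr: int = 40, rel_tol: float = 1e-4,
                        refinement: int = 4, tol_factor: float = 10.0):
    """Reference run at ``refinement``-times the node counts and a
    ``tol_factor``-times tighter tolerance, for bounding discretization
    error of a baseline run at (nx, nr, rel_tol).  Returns the reference
    :class:`~p2dvolt.simulate.Voltammogram`.
    """
    from .simulate import run_cv

    vgram, _ = run_cv(params, program, nx=refinement * nx, nr=refinement * nr,
                      rel_tol=rel_tol / tol_factor)
    return vgram
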