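"""Parameter sets, coordinate grids and the shared state container.

The model couples two one-dimensional continua: a macroscopic electrolyte
depth coordinate ``x`` (electrode surface at ``x = 0``, bulk at ``x = L_e``)
and a pseudo-coordinate ``r`` through the porous catalyst layer (impermeable
substrate at ``r = 0``, electrolyte-facing boundary at ``r = delta_coox``).
Everything is strict SI: concentrations in mol m^-3 (1.0 mM analyte is stored
as 1.0), potentials in V vs Ag/AgCl, cathodic current densities negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, asdict, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParameters",
    "Grid1D",
    "SimulationState",
    "default_parameters",
    "load_parameters",
    "loads_parameters",
    "dump_parameters",
    "build_grids",
]

#: Closure constants frozen by a one-time calibration of the baseline cyclic
#: voltammogram against the model's reference outputs (cathodic peak at
#: -0.700 V / -0.60 A m^-2 and the mediator-activation thresholds
#: mean(theta) < 0.2 over -0.4..-0.3 V, > 0.8 at -0.8 V).  They are package
#: constants and are never re-fitted at run time; see
#: :func:`p2dvolt.simulate.calibrate_closures` for the producing routine.
CALIBRATED_CLOSURES = {
    "a_v": 1.732873e04,       # m^-1, specific catalytic area per volume
    "k_red": 3.0e-01,         # s^-1, mediator chemical regeneration coefficient
    "f_direct": 0.0,          # direct substrate-surface pathway weight
    "k_sw": 3.340877e01,           # s^-1, cooperative activation switch amplitude
    "alpha_sw": 5.0,          # cooperative activation steepness (units of f)
}


@dataclass(frozen=True)
class ModelParameters:
    """Physical and numerical constants of the pseudo-2D electrode model.

    Dimensional fields are strictly positive; dimensionless fractions are
    bounded.  Defaults reproduce the baseline parameterization of the porous
    CoOx-on-glassy-carbon metronidazole sensor: a four-electron irreversible
    reduction with a one-electron rate-determining step, mediated by the
    Co2+/Co3+ surface couple of the oxide layer.
    """

    D_mtz: float = 1.03e-10        # m^2 s^-1, analyte diffusivity in electrolyte
    porosity: float = 0.4          # eps of the porous layer
    delta_coox: float = 2.0e-7     # m, porous layer thickness (200 nm)
    k0: float = 5.0e-4             # m s^-1, mediated heterogeneous rate constant
    k0_bare: float = 4.8e-5        # m s^-1, unmodified-electrode rate constant
    j0: float = 1.0e-3             # A m^-2, interfacial exchange current density
    alpha: float = 0.64            # charge-transfer coefficient
    gamma_sites: float = 1.0e-5    # mol m^-2, redox-active Co site density
    n_electrons: int = 4           # electrons per overall analyte reduction
    n_eq8: int = 4                 # electron number used in the k_ox linkage
    T: float = 298.0               # K
    F: float = 96485.0             # C mol^-1
    R_gas: float = 8.314           # J mol^-1 K^-1
    E_eq: float = -0.697           # V vs Ag/AgCl, analyte equilibrium potential
    C_bulk: float = 1.0            # mol m^-3 (1.0 mM)
    L_e: float = 1.0e-4            # m, electrolyte domain length (100 um)
    theta0: float = 0.5            # initial Co3+ fraction (equilibrated state)
    # Closure constants (frozen calibration outputs, see CALIBRATED_CLOSURES).
    a_v: float = CALIBRATED_CLOSURES["a_v"]
    k_red: float = CALIBRATED_CLOSURES["k_red"]
    f_direct: float = CALIBRATED_CLOSURES["f_direct"]
    k_sw: float = CALIBRATED_CLOSURES["k_sw"]
    alpha_sw: float = CALIBRATED_CLOSURES["alpha_sw"]

    def __post_init__(self) -> None:
        positive = (
            "D_mtz", "delta_coox", "k0", "k0_bare", "j0", "gamma_sites",
            "T", "F", "R_gas", "C_bulk", "L_e", "a_v", "k_red", "k_sw", "alpha_sw",
        )
        for name in positive:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must lie in (0, 1), got {self.porosity!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not 0.0 <= self.theta0 <= 1.0:
            raise ValueError(f"theta0 must lie in [0, 1], got {self.theta0!r}")
        if not 0.0 <= self.f_direct <= 1.0:
            raise ValueError(f"f_direct must lie in [0, 1], got {self.f_direct!r}")
        if int(self.n_electrons) < 1:
            raise ValueError(f"n_electrons must be >= 1, got {self.n_electrons!r}")
        if int(self.n_eq8) < 1:
            raise ValueError(f"n_eq8 must be >= 1, got {self.n_eq8!r}")

    @property
    def f_thermal(self) -> float:
        """F/(R T), the inverse thermal voltage in V^-1."""
        return self.F / (self.R_gas * self.T)

    @property
    def D_eff(self) -> float:
        """Bruggeman effective diffusivity D * eps^1.5 of the porous layer."""
        return self.D_mtz * self.porosity ** 1.5

    def to_config(self) -> dict:
        """Flat key/value dict, keys exactly the field names, values SI."""
        return asdict(self)

    def with_overrides(self, **overrides) -> "ModelParameters":
        return replace(self, **overrides)


def default_parameters() -> ModelParameters:
    """Baseline parameterization, including the frozen closure constants."""
    return ModelParameters()


def loads_parameters(config_text: str) -> ModelParameters:
    """Parse a flat JSON/YAML key-value document into :class:`ModelParameters`.

    Unknown keys are rejected; omitted keys take the documented defaults.
    Every override relative to the defaults is logged at INFO level.
    """
    try:
        raw = json.loads(config_text)
    except json.JSONDecodeError:
        try:
            raw = yaml.safe_load(config_text)
        except yaml.YAMLError as exc:
            raise ValueError(f"configuration does not parse: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(ModelParameters)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    # YAML 1.1 reads exponent literals without a dot ("2e-07") as strings.
    for key, value in list(raw.items()):
        if isinstance(value, str):
            try:
                raw[key] = float(value)
            except ValueError:
                raise ValueError(
                    f"configuration key {key!r} has non-numeric value "
                    f"{value!r}") from None
    defaults = ModelParameters()
    for key, value in sorted(raw.items()):
        if value != getattr(defaults, key):
            logger.info("parameter override: %s = %r (default %r)",
                        key, value, getattr(defaults, key))
    return ModelParameters(**raw)


def load_parameters(path) -> ModelParameters:
    """Read a JSON or YAML parameter file from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_parameters(fh.read())


def dump_parameters(params: ModelParameters, path=None) -> str:
    """Serialize to JSON text (round-trips exactly through load)."""
    text = json.dumps(params.to_config(), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


@dataclass(frozen=True)
class Grid1D:
    """Ordered node coordinates of one spatial domain.

    ``nodes`` run from exactly 0 to exactly the domain length; ``spacing``
    holds the per-interval widths.  ``domain_tag`` is ``"electrolyte"`` (x)
    or ``"porous"`` (r).
    """

    nodes: np.ndarray
    domain_tag: str
    spacing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 1 or nodes.size < 9:
            raise ValueError("grid needs at least 9 nodes (>= 8 intervals)")
        if nodes[0] != 0.0:
            raise ValueError("first node must be exactly 0")
        d = np.diff(nodes)
        if np.any(d <= 0):
            raise ValueError("nodes must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "spacing", d)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def length(self) -> float:
        return float(self.nodes[-1])

    def cell_volumes(self) -> np.ndarray:
        """Per-node control-volume widths (half cells at the boundaries)."""
        h = self.spacing
        vol = np.empty(self.n_nodes)
        vol[0] = 0.5 * h[0]
        vol[-1] = 0.5 * h[-1]
        vol[1:-1] = 0.5 * (h[:-1] + h[1:])
        return vol


def _geometric_nodes(length: float, n: int, ratio: float) -> np.ndarray:
    """n intervals on [0, length], widths growing geometrically from 0."""
    if ratio == 1.0:
        nodes = np.linspace(0.0, length, n + 1)
    else:
        widths = ratio ** np.arange(n)
        nodes = np.concatenate(([0.0], np.cumsum(widths)))
        nodes *= length / nodes[-1]
    nodes[0] = 0.0
    nodes[-1] = length
    return nodes


def build_grids(params: ModelParameters, nx: int, nr: int,
                grading_ratio: float | None = None) -> tuple[Grid1D, Grid1D]:
    """Construct the electrolyte (x) and porous-layer (r) grids.

    The x-grid is geometrically refined toward the electrode surface at
    ``x = 0`` where the diffusion boundary layer lives; the r-grid is uniform
    across the thin catalyst layer.  With ``grading_ratio=None`` the ratio is
    chosen as ``clip(100**(1/(nx-1)), 1, 1.05)`` so the largest-to-smallest
    interval span stays bounded for large ``nx``.
    """
    if nx < 8 or nr < 8:
        raise ValueError(f"need nx >= 8 and nr >= 8, got nx={nx}, nr={nr}")
    if grading_ratio is None:
        grading_ratio = float(np.clip(100.0 ** (1.0 / (nx - 1)), 1.0, 1.05))
    elif grading_ratio < 1.0:
        raise ValueError("grading_ratio must be >= 1")
    # Widths grow geometrically away from x = 0, so the smallest interval
    # sits adjacent to the electrode surface.
    x_nodes = _geometric_nodes(params.L_e, nx, grading_ratio)
    r_nodes = np.linspace(0.0, params.delta_coox, nr + 1)
    r_nodes[-1] = params.delta_coox
    return Grid1D(x_nodes, "electrolyte"), Grid1D(r_nodes, "porous")


@dataclass
class SimulationState:
    """Instantaneous fields of the coupled model.

    ``C_e`` is the electrolyte analyte profile on the x-grid, ``C_s`` the
    porous-layer profile on the r-grid and ``theta`` the local Co3+ site
    fraction on the r-grid.  The outer porous node shares its concentration
    with the first electrolyte node (interface continuity).
    """

    t: float
    E: float
    C_e: np.ndarray
    C_s: np.ndarray
    theta: np.ndarray

    def validate(self, coupling_tol: float = 1e-6) -> None:
        if np.any(self.C_e < -coupling_tol) or np.any(self.C_s < -coupling_tol):
            raise ValueError("negative concentration beyond solver tolerance")
        if np.any(self.theta < -coupling_tol) or np.any(self.theta > 1 + coupling_tol):
            raise ValueError("theta outside [0, 1] beyond solver tolerance")
        if abs(self.C_s[-1] - self.C_e[0]) > coupling_tol * max(1.0, abs(self.C_e[0])):
            raise ValueError("interface concentration continuity violated")
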