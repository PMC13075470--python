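"""Derived electroanalytical quantities.

Peak extraction, Tafel fitting with rate-constant recovery, mediator-state
and reaction-rate curves, surface-concentration transients, catalyst
utilization versus layer thickness, sensing calibration metrics and the
scan-rate study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ModelParameters
from .simulate import (PotentialProgram, StateHistory, Voltammogram,
                       run_chronoamperometry, run_cv)

__all__ = [
    "PeakNotFoundError",
    "TafelFit",
    "UtilizationCurve",
    "CalibrationResult",
    "find_cathodic_peak",
    "tafel_analysis",
    "mean_theta_curve",
    "mean_rate_curve",
    "utilization_vs_thickness",
    "surface_concentration_transient",
    "concentration_calibration",
    "scan_rate_study",
]


class PeakNotFoundError(ValueError):
    """The trace has no interior cathodic minimum."""


@dataclass
class TafelFit:
    """Result of a Tafel-region regression of log10|j| on overpotential."""

    slope: float           # mV per decade (positive magnitude)
    alpha_est: float       # recovered charge-transfer coefficient
    k0_eff: float          # m s^-1, recovered heterogeneous rate constant
    window: tuple          # (|eta| low, |eta| high), V
    r_squared: float
    n_points: int
    intercept_j: float     # A m^-2, extrapolated |j| at eta = 0
    convention: str = ""   # k0 extraction convention used
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("Tafel slope must be positive")
        if not 0.0 < self.alpha_est < 1.0:
            raise ValueError("alpha_est must lie in (0, 1)")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 5:
            raise ValueError("Tafel fit needs at least 5 points")


@dataclass
class UtilizationCurve:
    """Effectiveness factor of the catalyst layer versus its thickness."""

    thicknesses: np.ndarray     # m
    utilization: np.ndarray     # dimensionless, in (0, 1]
    reference_rate: np.ndarray  # mol m^-2 s^-1 at the outer boundary

    def __post_init__(self) -> None:
        u = np.asarray(self.utilization)
        if np.any(u <= 0) or np.any(u > 1.0 + 1e-9):
            raise ValueError("utilization must lie in (0, 1]")


@dataclass
class CalibrationResult:
    """Peak-current calibration against analyte concentration."""

    concentrations: np.ndarray  # mol m^-3
    peak_currents: np.ndarray   # A m^-2 (cathodic, negative)
    slope: float                # A m^-2 per mol m^-3
    intercept: float
    r_squared: float
    linear_range: tuple         # (low, high), mol m^-3
    lod: float                  # mol m^-3 (S/N = 3 convention)
    noise_sigma: float          # A m^-2

    def __post_init__(self) -> None:
        low, high = self.linear_range
        if not low < high:
            raise ValueError("linear_range must satisfy low < high")
        if self.lod <= 0:
            raise ValueError("lod must be positive")


def find_cathodic_peak(vgram: Voltammogram) -> tuple[float, float]:
    """Locate the forward-sweep cathodic peak with quadratic refinement.

    Returns ``(E_peak, j_peak)``.  Raises :class:`PeakNotFoundError` when the
    forward trace has no interior minimum.
    """
    fwd = vgram.forward_mask()
    if not fwd.any():
        raise PeakNotFoundError("no forward-sweep samples")
    E = np.asarray(vgram.E)[fwd]
    j = np.asarray(vgram.j_total)[fwd]
    i = int(np.argmin(j))
    if i == 0 or i == len(j) - 1:
        raise PeakNotFoundError("no interior cathodic minimum on the forward sweep")
    if j[i] >= min(j[0], j[-1]) and np.all(np.diff(j) <= 0):
        raise PeakNotFoundError("forward trace is monotone")
    # Quadratic through (E, j) at i-1, i, i+1.
    x0, x1, x2 = E[i - 1], E[i], E[i + 1]
    y0, y1, y2 = j[i - 1], j[i], j[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:  # flat or degenerate vertex; fall back to the sample
        return float(x1), float(y1)
    E_pk = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    j_pk = a * E_pk**2 + b * E_pk + c
    return float(E_pk), float(j_pk)


def tafel_analysis(vgram: Voltammogram, params: ModelParameters,
                   window_low: float = 0.10, window_high: float = 0.15,
                   mass_transfer_correction: bool = True) -> TafelFit:
    """Tafel regression over the kinetically controlled rising branch.

    Selects forward-sweep samples with ``window_low < |eta| < window_high``
    that lie *before* the cathodic peak (the post-peak side is transport
    limited and carries no kinetic information), and regresses
    ``log10|j|`` on ``eta = E - E_eq`` by ordinary least squares.  When the
    voltammogram carries a surface-concentration trace the current is first
    divided by the normalized surface concentration (mass-transfer-corrected
    Tafel analysis), which removes the depletion bend from the fit.

    The recovered rate constant uses the convention matching the electrode
    configuration: for an interfacial (bare) trace the extrapolated
    intercept satisfies ``|j|(eta=0) = n F k0_eff C_bulk``; for a mediated
    trace the intercept is inverted through the rising-branch asymptotics of
    the mediator activation (theta ~ k_ox / (alpha f v + k_red)), i.e.

        k0_eff = J0 * n_eq8 * Gamma * (alpha f v + k_red)
                 / (n * a_v * delta * C_bulk * j0 / F)

    (the kinetic branch is seeded by the cathodic partial current of the
    interfacial law, so the intercept is linear in j0 and k0).
    """
    if not window_low < window_high:
        raise ValueError("window_low must be smaller than window_high")
    fwd = vgram.forward_mask()
    E = np.asarray(vgram.E)[fwd]
    j = np.asarray(vgram.j_total)[fwd]
    csurf = (np.asarray(vgram.c_surface)[fwd]
             if (vgram.c_surface is not None and mass_transfer_correction)
             else None)
    # Pre-peak restriction (kinetic regime).
    try:
        E_pk, _ = find_cathodic_peak(vgram)
    except PeakNotFoundError:
        E_pk = None
    eta = E - params.E_eq
    sel = (np.abs(eta) > window_low) & (np.abs(eta) < window_high) & (j < 0)
    if E_pk is not None:
        sel &= E > E_pk
    jmag = np.abs(j[sel])
    floor = 1e-12
    ok = jmag > floor
    eta_w = eta[sel][ok]
    jmag = jmag[ok]
    if csurf is not None:
        corr = np.clip(csurf[sel][ok], 1e-9, None)
        jmag = jmag / corr
    n_pts = int(jmag.size)
    if n_pts < 5:
        raise ValueError(
            f"only {n_pts} forward-sweep samples in the Tafel window "
            f"({window_low}, {window_high}) V")
    warnings = []
    order = np.argsort(eta_w)
    if np.any(np.diff(np.log10(jmag[order])) > 0):
        warnings.append("non-monotone |j| inside the Tafel window")
    y = np.log10(jmag)
    m, b = np.polyfit(eta_w, y, 1)
    yhat = m * eta_w + b
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    slope_mv = 1000.0 / abs(m)
    alpha_est = float(np.log(10.0) * params.R_gas * params.T * abs(m) / params.F)
    J0 = float(10.0 ** b)
    nF = params.n_electrons * params.F
    if vgram.kind == "coox":
        v = vgram.scan_rate
        if v is None:
            raise ValueError("mediated-trace k0 extraction needs the scan rate")
        gamma_rate = params.alpha * params.f_thermal * v + params.k_red
        k0_eff = (J0 * params.n_eq8 * params.F * params.gamma_sites * gamma_rate
                  / (params.n_electrons * params.F * params.a_v
                     * params.delta_coox * params.C_bulk * params.j0))
        convention = "mediated-activation-asymptote"
    else:
        k0_eff = J0 / (nF * params.C_bulk)
        convention = "interfacial-intercept"
    return TafelFit(slope=float(slope_mv), alpha_est=alpha_est,
                    k0_eff=float(k0_eff),
                    window=(float(window_low), float(window_high)),
                    r_squared=float(np.clip(r2, 0.0, 1.0)), n_points=n_pts,
                    intercept_j=J0, convention=convention, warnings=warnings)


def _forward_curve(history: StateHistory, values: np.ndarray):
    fwd = history.direction == 1
    return history.E[fwd], values[fwd]


def mean_theta_curve(history: StateHistory):
    """(E, layer-mean Co3+ fraction) on the forward sweep."""
    E, th = _forward_curve(history, history.mean_theta())
    if E.size == 0:
        raise ValueError("history has no forward-sweep snapshots")
    return E, th


def mean_rate_curve(history: StateHistory, params: ModelParameters):
    """(E, layer-mean mediated volumetric rate) on the forward sweep."""
    E, r = _forward_curve(history, history.mean_rate(params))
    if E.size == 0:
        raise ValueError("history has no forward-sweep snapshots")
    return E, r


def surface_concentration_transient(history: StateHistory,
                                    plateau_band: float = 0.05):
    """Outer-boundary analyte concentration trace of a potential-step run.

    Returns ``(times, C_surface, plateau, t_plateau)`` where ``plateau`` is
    the final value and ``t_plateau`` the first time after which the trace
    stays within ``plateau_band`` (relative) of it.
    """
    times = history.times
    trace = history.C_s[:, -1]
    plateau = float(trace[-1])
    tol = plateau_band * max(abs(plateau), 1e-30)
    outside = np.abs(trace - plateau) > tol
    t_plateau = float(times[int(np.max(np.nonzero(outside)[0])) + 1]) \
        if outside.any() else float(times[0])
    return times, trace, plateau, t_plateau


def utilization_vs_thickness(params: ModelParameters, thicknesses,
                             E_hold: float = -0.9, hold_time: float = 20.0,
                             nx: int = 400, nr: int = 60,
                             mediator_dynamic: bool = True,
                             rel_tol: float = 1e-4) -> UtilizationCurve:
    """Effectiveness factor versus catalyst-layer thickness.

    For each thickness the potential is held at ``E_hold`` until a
    quasi-steady state and the utilization is the achieved layer-integrated
    rate relative to the rate if the whole layer saw the outer-boundary
    concentration and local theta:

        utilization = (integral R_vol dr) / (delta * R_vol(r = delta))
    """
    thicknesses = np.asarray(thicknesses, dtype=float)
    if np.any(thicknesses <= 0) or np.any(np.diff(thicknesses) <= 0):
        raise ValueError("thicknesses must be positive and sorted ascending")
    program = PotentialProgram.step(E_step=E_hold, duration=hold_time)
    util = np.empty_like(thicknesses)
    ref = np.empty_like(thicknesses)
    for i, delta in enumerate(thicknesses):
        trial = replace(params, delta_coox=float(delta))
        _, history = run_chronoamperometry(trial, program, nx=nx, nr=nr,
                                           rel_tol=rel_tol,
                                           mediator_dynamic=mediator_dynamic)
        r_nodes = history.r_nodes
        R = trial.a_v * trial.k0 * np.clip(history.C_s, 0.0, None) \
            * np.clip(history.theta, 0.0, 1.0)
        u_last = float(np.trapezoid(R[-1], r_nodes) / (delta * R[-1][-1]))
        u_prev = float(np.trapezoid(R[-2], r_nodes) / (delta * R[-2][-1]))
        if abs(u_last - u_prev) > 0.01 * max(u_last, 1e-12):
            raise RuntimeError(
                f"quasi-steady state not reached for thickness {delta:g} m")
        util[i] = u_last
        ref[i] = R[-1][-1] * delta
    return UtilizationCurve(thicknesses=thicknesses,
                            utilization=np.clip(util, None, 1.0),
                            reference_rate=ref)


def concentration_calibration(params: ModelParameters, concentrations,
                              noise_sigma: float = 0.0, seed: int = 0,
                              nx: int = 300, nr: int = 60,
                              rel_tol: float = 1e-4,
                              linearity_tol: float = 0.05) -> CalibrationResult:
    """Peak-current calibration over an analyte concentration series.

    Simulates the baseline CV at each concentration, regresses cathodic peak
    current on concentration and reports the widest contiguous linear range
    (per-point deviation from the global fit below ``linearity_tol``) and the
    detection limit ``3 * noise_sigma / |slope|`` (signal-to-noise-of-three
    convention; the result inherits whatever noise level is supplied).
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 5:
        raise ValueError("need at least 5 concentrations")
    if conc.max() / conc.min() < 100.0:
        raise ValueError("concentrations must span at least two decades")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    peaks = np.empty_like(conc)
    for i, c in enumerate(conc):
        trial = replace(params, C_bulk=float(c))
        vgram, _ = run_cv(trial, nx=nx, nr=nr, rel_tol=rel_tol)
        _, j_pk = find_cathodic_peak(vgram)
        peaks[i] = j_pk
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        peaks = peaks + rng.normal(0.0, noise_sigma, size=peaks.shape)
    m, b = np.polyfit(conc, peaks, 1)
    if abs(m) < 1e-30:
        raise ValueError("singular calibration regression (zero slope)")
    fitted = m * conc + b
    dev = np.abs(peaks - fitted) / np.abs(fitted)
    within = dev < linearity_tol
    # Widest contiguous run of in-tolerance points.
    best, cur, best_span = (0, 0), 0, -1
    i = 0
    while i < conc.size:
        if within[i]:
            jx = i
            while jx + 1 < conc.size and within[jx + 1]:
                jx += 1
            if jx - i > best_span:
                best_span, best = jx - i, (i, jx)
            i = jx + 1
        else:
            i += 1
    if best_span < 1:
        raise ValueError("no contiguous linear range found")
    yhat = fitted
    ss_res = float(np.sum((peaks - yhat) ** 2))
    ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    lod = 3.0 * noise_sigma / abs(m) if noise_sigma > 0 else 3.0 * 1e-12 / abs(m)
    return CalibrationResult(
        concentrations=conc, peak_currents=peaks, slope=float(m),
        intercept=float(b), r_squared=float(np.clip(r2, 0.0, 1.0)),
        linear_range=(float(conc[best[0]]), float(conc[best[1]])),
        lod=float(lod), noise_sigma=float(noise_sigma))


def scan_rate_study(params: ModelParameters, rates, nx: int = 300,
                    nr: int = 60, rel_tol: float = 1e-4) -> dict:
    """Cathodic peak current versus the square root of the scan rate.

    Returns a dict with per-rate peaks and the OLS regression of |j_peak| on
    sqrt(rate): slope, intercept and R^2.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 3 or np.any(rates <= 0):
        raise ValueError("need at least 3 positive scan rates")
    peaks = np.empty_like(rates)
    E_peaks = np.empty_like(rates)
    for i, v in enumerate(rates):
        program = PotentialProgram.cv(scan_rate=float(v))
        vgram, _ = run_cv(params, program, nx=nx, nr=nr, rel_tol=rel_tol)
        E_pk, j_pk = find_cathodic_peak(vgram)
        peaks[i] = abs(j_pk)
        E_peaks[i] = E_pk
    x = np.sqrt(rates)
    if np.ptp(x) == 0.0:  # degenerate (repeated rates): flat fit
        m, b = 0.0, float(peaks.mean())
    else:
        m, b = np.polyfit(x, peaks, 1)
    yhat = m * x + b
    ss_res = float(np.sum((peaks - yhat) ** 2))
    ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"rates": rates, "peak_currents": peaks, "peak_potentials": E_peaks,
            "slope": float(m), "intercept": float(b),
            "r_squared": float(np.clip(r2, 0.0, 1.0))}
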