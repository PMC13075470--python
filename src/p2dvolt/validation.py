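"""Reference-output validation suite.

Recomputes, from scratch, the headline quantities of the baseline model
(voltammetric peak, Tafel kinetics, mediator-state thresholds, mean reaction
rate, bare-electrode comparison) and compares them against the published
reference values with their tolerances.  Used by the ``p2dvolt validate``
command and the repository acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis
from .params import ModelParameters, default_parameters
from .simulate import run_bare_cv, run_cv

__all__ = ["TargetResult", "compute_targets", "REFERENCES"]

#: Published reference values and comparison rules, keyed by target id.
#: kind: "eq" two-sided relative tolerance; "ge"/"le" one-sided bound.
REFERENCES = {
    "t1": {"value": 92.2, "tol": 1.0, "kind": "abs",
           "label": "Tafel slope, CoOx forward sweep (mV/dec)"},
    "t3": {"value": -0.700, "tol": 0.010, "kind": "abs",
           "label": "CoOx cathodic peak potential (V)"},
    "t4": {"value": -0.60, "tol": 0.05, "kind": "rel",
           "label": "CoOx cathodic peak current density (A/m2)"},
    "t5": {"value": -0.25, "tol": 0.10, "kind": "rel",
           "label": "bare cathodic peak current density (A/m2)"},
    "t8": {"value": 0.8, "kind": "ge",
           "label": "mean Co3+ fraction at -0.8 V"},
    "t9": {"value": 0.2, "kind": "le",
           "label": "mean Co3+ fraction over -0.4..-0.3 V"},
    "t10": {"value": 1.2e-3, "tol": 0.15, "kind": "rel",
            "label": "mean volumetric rate at -0.7 V (mol/m3/s)"},
    "t11": {"value": 5.0e-4, "tol": 0.10, "kind": "rel",
            "label": "recovered k0, CoOx (m/s)"},
    "t12": {"value": 4.8e-5, "tol": 0.15, "kind": "rel",
            "label": "recovered k0, bare (m/s)"},
}


@dataclass
class TargetResult:
    target_id: str
    value: float
    n: int
    reference: float
    passed: bool
    label: str


def _passes(target_id: str, value: float) -> bool:
    ref = REFERENCES[target_id]
    if ref["kind"] == "ge":
        return value >= ref["value"]
    if ref["kind"] == "le":
        return value <= ref["value"]
    if ref["kind"] == "abs":
        return abs(value - ref["value"]) <= ref["tol"]
    return abs(value - ref["value"]) <= ref["tol"] * abs(ref["value"])


def compute_targets(params: ModelParameters | None = None, seed: int = 0,
                    nx: int = 1000, nr: int = 200,
                    rel_tol: float = 1e-4) -> dict[str, TargetResult]:
    """Run the baseline protocols and evaluate every validation target.

    ``seed`` feeds any stochastic component (none of the reference targets
    is stochastic, but the seed is threaded through for reproducibility of
    optional noisy analyses).
    """
    params = params or default_parameters()
    rng_seed = int(seed) % (2 ** 31)
    del rng_seed  # deterministic targets; seed kept for interface stability

    vgram, history = run_cv(params, nx=nx, nr=nr, rel_tol=rel_tol)
    n_cv = len(vgram.t)
    E_pk, j_pk = analysis.find_cathodic_peak(vgram)
    tafel = analysis.tafel_analysis(vgram, params)

    mean_theta = history.mean_theta()
    mean_rate = history.mean_rate(params)
    fwd = history.direction == 1
    E_snap = history.E
    i_08 = np.nonzero(fwd)[0][np.argmin(np.abs(E_snap[fwd] + 0.8))]
    low_win = fwd & (E_snap >= -0.4) & (E_snap <= -0.3)
    i_07 = np.nonzero(fwd)[0][np.argmin(np.abs(E_snap[fwd] + 0.7))]

    bare = run_bare_cv(params, nx=nx, rel_tol=rel_tol)
    _, j_pk_bare = analysis.find_cathodic_peak(bare)
    tafel_bare = analysis.tafel_analysis(bare, params)

    values = {
        "t1": (tafel.slope, tafel.n_points),
        "t3": (E_pk, n_cv),
        "t4": (j_pk, n_cv),
        "t5": (j_pk_bare, len(bare.t)),
        "t8": (float(mean_theta[i_08]), history.n_snapshots),
        "t9": (float(mean_theta[low_win].max()), int(low_win.sum())),
        "t10": (float(mean_rate[i_07]), history.n_snapshots),
        "t11": (tafel.k0_eff, tafel.n_points),
        "t12": (tafel_bare.k0_eff, tafel_bare.n_points),
    }
    results = {}
    for tid, (value, n) in values.items():
        results[tid] = TargetResult(
            target_id=tid, value=float(value), n=int(n),
            reference=REFERENCES[tid]["value"],
            passed=_passes(tid, float(value)),
            label=REFERENCES[tid]["label"])
    return results
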